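"""Spike-train and micro-ECoG response metrics for ultrasound stimulation.

Per-cell metrics follow the standard electrophysiology toolbox: a Gaussian
kernel spike density function (SDF), response latency as the time from
stimulus onset to the maximum of the SDF derivative, response duration as
the interval between the outermost crossings of peak/e, and the Fano factor
(variance over mean of per-trial spike counts).  Cells split into
short-latency (SL, < 45 ms: direct mechanosensitive activation) and
long-latency (LL: network-mediated) classes.

Spatial metrics quantify how confined the activated population is:
rate-weighted pairwise dispersion, the rate-weighted response centre and its
displacement, activated-cell density, and — for surface ECoG arrays — a
linearly interpolated activation map thresholded at twice the baseline noise
standard deviation.

All times are in seconds, positions in metres, rates in Hz, voltages in
volts.  Stimulus onset defines t = 0 within each trial; response windows are
half-open ``[onset, onset + w)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpikeTrainSet",
    "StimulusEvents",
    "CellResponse",
    "EcogRecording",
    "EvokedPotentials",
    "ActivationMap",
    "SL_LL_THRESHOLD",
    "spike_density_function",
    "response_latency",
    "response_duration",
    "fano_factor",
    "spatial_dispersion",
    "response_centre",
    "centre_displacement",
    "activated_density",
    "evoked_potential",
    "ecog_activation_map",
    "response_dominance_index",
    "analyze_spike_trains",
]

#: Latency threshold (s) separating short-latency (direct) from long-latency
#: (network-mediated) ultrasound responses.
SL_LL_THRESHOLD = 0.045


@dataclass
class SpikeTrainSet:
    """Sorted spike times per cell and trial, with electrode positions.

    ``spikes`` has columns ``cell``, ``trial``, ``time`` (s, relative to the
    trial's recording start); ``positions`` has ``cell``, ``x``, ``y`` (m).
    """

    spikes: pd.DataFrame
    positions: pd.DataFrame
    n_trials: int

    def __post_init__(self) -> None:
        need = {"cell", "trial", "time"}
        if not need.issubset(self.spikes.columns):
            raise ValueError(f"spikes table needs columns {sorted(need)}")
        if not {"cell", "x", "y"}.issubset(self.positions.columns):
            raise ValueError("positions table needs columns cell, x, y")
        self.spikes = self.spikes.sort_values(["cell", "trial", "time"]).reset_index(
            drop=True
        )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def cells(self) -> np.ndarray:
        return np.asarray(sorted(self.positions["cell"].unique()))

    def trains(self, cell) -> list[np.ndarray]:
        """Per-trial spike-time arrays for one cell."""
        sub = self.spikes[self.spikes["cell"] == cell]
        return [
            sub.loc[sub["trial"] == t, "time"].to_numpy()
            for t in range(self.n_trials)
        ]

    def position(self, cell) -> np.ndarray:
        row = self.positions.loc[self.positions["cell"] == cell].iloc[0]
        return np.array([row["x"], row["y"]], dtype=float)


@dataclass(frozen=True)
class StimulusEvents:
    """Stimulus onsets (s), a common duration (s), and free-form labels."""

    onsets: np.ndarray
    duration: float
    label: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class CellResponse:
    """Summary metrics of one cell's ultrasound response."""

    cell: int
    latency: float  # s; NaN when undefined
    max_rate: float  # Hz
    duration: float  # s; NaN when censored/undefined
    fano: float  # dimensionless; NaN when undefined
    latency_class: str  # "SL" | "LL" | "none"
    responsive: bool


def spike_density_function(
    trains: Sequence[np.ndarray],
    *,
    t_start: float,
    t_stop: float,
    dt: float = 1e-3,
    kernel_sigma: float = 3e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged Gaussian-kernel firing-rate estimate.

    Returns ``(t, rate)`` with ``rate`` in Hz; the time integral of the rate
    equals the mean spike count per trial up to edge truncation (unit-mass
    kernel).  An empty train yields a zero trace.
    """
    if kernel_sigma <= 0 or dt <= 0:
        raise ValueError("kernel_sigma and dt must be positive")
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    edges = np.arange(t_start, t_stop + dt, dt)
    t = 0.5 * (edges[:-1] + edges[1:])
    n_trials = max(len(trains), 1)
    counts = np.zeros(t.size)
    for train in trains:
        train = np.asarray(train, dtype=float)
        if train.size:
            counts += np.histogram(train, bins=edges)[0]
    rate = gaussian_filter1d(counts, sigma=kernel_sigma / dt, mode="constant")
    return t, rate / (n_trials * dt)


def response_latency(
    t: np.ndarray, sdf: np.ndarray, onset: float, *, window: float | None = None
) -> float:
    """Time (s) from ``onset`` to the maximum of the SDF derivative.

    The search runs over ``[onset, onset + window)`` (window defaults to the
    end of the trace).  A flat trace has no defined latency and returns NaN.
    """
    t = np.asarray(t, float)
    sdf = np.asarray(sdf, float)
    stop = t[-1] if window is None else onset + window
    mask = (t >= onset) & (t < stop)
    if mask.sum() < 3:
        raise ValueError("SDF must cover a post-onset window")
    seg_t = t[mask]
    seg = sdf[mask]
    if np.ptp(seg) == 0:
        return float("nan")
    deriv = np.gradient(seg, seg_t)
    return float(seg_t[np.argmax(deriv)] - onset)


def response_duration(
    t: np.ndarray, sdf: np.ndarray, *, baseline: float = 0.0
) -> tuple[float, bool]:
    """Interval between the outermost peak/e crossings around the SDF peak.

    ``A`` is the trace maximum; crossings of ``A/e`` are located by linear
    interpolation walking outward from the peak.  Returns ``(duration,
    censored)``; a trace that never falls below ``A/e`` on one side is
    censored (duration then spans to the window edge).  Scaling the trace
    leaves the duration unchanged.
    """
    t = np.asarray(t, float)
    y = np.asarray(sdf, float)
    i = int(np.argmax(y))
    peak = y[i]
    if peak <= baseline:
        raise ValueError("SDF peak must lie strictly above baseline")
    level = peak / np.e
    censored = False

    def _walk(indices: range, edge: int) -> float:
        nonlocal censored
        for j in indices:
            if y[j] < level:
                j_in = j + (1 if j < i else -1)
                return float(t[j] + (level - y[j]) * (t[j_in] - t[j]) / (y[j_in] - y[j]))
        censored = True
        return float(t[edge])

    left = _walk(range(i - 1, -1, -1), 0)
    right = _walk(range(i + 1, t.size), t.size - 1)
    return right - left, censored


def fano_factor(counts: Sequence[float]) -> float:
    """Variance-to-mean ratio of per-trial spike counts (unbiased variance).

    Needs at least two trials; a zero mean count has no defined Fano factor
    and returns NaN with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("fano_factor needs spike counts from >= 2 trials")
    mean = counts.mean()
    if mean == 0:
        warnings.warn("mean spike count is zero; Fano factor undefined", stacklevel=2)
        return float("nan")
    return float(counts.var(ddof=1) / mean)


def _as_weights(weights: Sequence[float], n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must match the number of positions")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with a positive sum")
    return w / w.max()  # normalise to the population max (cancels in ratios)


def spatial_dispersion(
    positions: np.ndarray, weights: Sequence[float] | None = None
) -> float:
    """Rate-weighted mean pairwise distance of activated cells (m).

    ``sum_{i<j} w_i w_j d_ij / sum_{i<j} w_i w_j`` with weights the maximum
    firing rates normalised to the population maximum.  A single cell (or
    coincident cells) has zero dispersion.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if n < 2:
        return 0.0
    w = np.ones(n) if weights is None else _as_weights(weights, n)
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    ww = np.outer(w, w)
    iu = np.triu_indices(n, k=1)
    denom = ww[iu].sum()
    if denom == 0:
        return 0.0
    return float((ww[iu] * d[iu]).sum() / denom)


def response_centre(
    positions: np.ndarray, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Amplitude-weighted centroid of the responding units (m)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if n == 0:
        raise ValueError("response_centre needs at least one active unit")
    w = np.ones(n) if weights is None else _as_weights(weights, n)
    return np.asarray((w[:, None] * pos).sum(axis=0) / w.sum())


def centre_displacement(centre_a: np.ndarray, centre_b: np.ndarray) -> float:
    """Euclidean distance (m) between two centre-of-response positions."""
    a = np.asarray(centre_a, dtype=float)
    b = np.asarray(centre_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("centres must have matching dimensions")
    return float(np.linalg.norm(a - b))


def activated_density(
    n_responding: int, frequency: float, focal_area: float, mea_area: float
) -> float:
    """Responding cells per unit stimulated area (cells/m^2).

    High-frequency beams (>= 2.25 MHz) are narrower than the array, so the
    focal-spot area is the stimulated area; at 0.5 MHz the focal spot
    engulfs the array and the array area is used instead.
    """
    if focal_area <= 0 or mea_area <= 0:
        raise ValueError("areas must be positive")
    if n_responding < 0:
        raise ValueError("n_responding must be >= 0")
    area = focal_area if frequency >= 2.25e6 else mea_area
    return n_responding / area


def response_dominance_index(on_rate: float, off_rate: float) -> float:
    """(ON - OFF)/(ON + OFF) in [-1, 1]; NaN when both rates are zero."""
    if on_rate < 0 or off_rate < 0:
        raise ValueError("rates must be non-negative")
    total = on_rate + off_rate
    if total == 0:
        return float("nan")
    return (on_rate - off_rate) / total


# --------------------------------------------------------------------------
# micro-ECoG


@dataclass
class EcogRecording:
    """Multi-channel surface ECoG voltages with electrode coordinates.

    ``data`` is (n_channels, n_samples) in volts at ``fs`` Hz;
    ``positions`` has columns ``channel``, ``x``, ``y`` (m, unique);
    ``trial_onsets`` are stimulus times (s).
    """

    data: np.ndarray
    fs: float
    positions: pd.DataFrame
    trial_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if not {"channel", "x", "y"}.issubset(self.positions.columns):
            raise ValueError("positions table needs columns channel, x, y")
        if len(self.positions) != self.data.shape[0]:
            raise ValueError("positions rows must match channel count")
        xy = self.positions[["x", "y"]].to_numpy()
        if len(np.unique(xy, axis=0)) != len(xy):
            raise ValueError("electrode coordinates must be unique")
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)


@dataclass
class EvokedPotentials:
    """Trial-averaged evoked potentials and their N1 summary."""

    t: np.ndarray  # s relative to onset
    traces: np.ndarray  # (n_channels, n_window) volts
    n1_amplitude: np.ndarray  # (n_channels,) volts, magnitude of N1
    noise_sd: float  # pooled baseline s.d. of the mean traces, volts


def evoked_potential(
    recording: EcogRecording,
    *,
    baseline_window: float = 0.2,
    response_window: float = 0.3,
    n1_search_window: float = 0.1,
) -> EvokedPotentials:
    """Trial-aligned mean traces and per-channel N1 amplitudes.

    N1 is the magnitude of the most negative deflection of the mean trace in
    the first ``n1_search_window`` seconds after onset, measured against the
    pre-onset baseline mean.  The background-noise s.d. is that of the raw
    (single-trial) signal over the pre-onset baselines, pooled across
    channels — the level against which the activation threshold of
    :func:`ecog_activation_map` is set.
    """
    if recording.trial_onsets.size == 0:
        raise ValueError("recording has no trial markers")
    fs = recording.fs
    pre = int(round(baseline_window * fs))
    post = int(round(response_window * fs))
    traces = np.zeros((recording.data.shape[0], pre + post))
    raw_baseline_var = []
    n_used = 0
    for onset in recording.trial_onsets:
        i0 = int(round(onset * fs)) - pre
        i1 = i0 + pre + post
        if i0 < 0 or i1 > recording.data.shape[1]:
            continue
        seg = recording.data[:, i0:i1]
        traces += seg
        base = seg[:, :pre]
        raw_baseline_var.append(base.var(axis=1).mean())
        n_used += 1
    if n_used == 0:
        raise ValueError("no trial fits inside the recording")
    traces /= n_used
    t = (np.arange(pre + post) - pre) / fs
    base = traces[:, :pre]
    base_mean = base.mean(axis=1, keepdims=True)
    noise_sd = float(np.sqrt(np.mean(raw_baseline_var)))
    search = (t >= 0) & (t < n1_search_window)
    n1 = -(traces[:, search] - base_mean).min(axis=1)
    return EvokedPotentials(
        t=t, traces=traces, n1_amplitude=np.maximum(n1, 0.0), noise_sd=noise_sd
    )


@dataclass
class ActivationMap:
    """Interpolated activation map over the electrode hull."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # (nx, ny), NaN outside the hull
    threshold: float
    activated_area: float  # m^2
    centre: np.ndarray | None  # m; None when all nodes are subthreshold


def ecog_activation_map(
    amplitudes: Sequence[float],
    coordinates: np.ndarray,
    noise_sd: float,
    *,
    grid_step: float | None = None,
) -> ActivationMap:
    """Piecewise-linear activation map with a 2 x s.d. activation threshold.

    Amplitudes (e.g. N1 peak magnitudes) are linearly interpolated on the
    Delaunay triangulation of the electrode layout; the activated area is
    the hull area where the interpolant exceeds ``2 * noise_sd`` and the
    centre is the amplitude-weighted centroid of that suprathreshold region.
    """
    from scipy.interpolate import LinearNDInterpolator
    from scipy.spatial import QhullError

    amps = np.asarray(amplitudes, dtype=float)
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] != amps.size:
        raise ValueError("coordinates must be (n, 2) matching amplitudes")
    if amps.size < 3:
        raise ValueError("need >= 3 electrodes for interpolation")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    try:
        interp = LinearNDInterpolator(coords, amps)
    except QhullError as err:  # collinear layout
        raise ValueError("electrode layout is degenerate (collinear)") from err

    if grid_step is None:
        pitch = np.median(np.diff(np.unique(coords[:, 0])))
        grid_step = float(pitch) / 12.0 if np.isfinite(pitch) and pitch > 0 else None
    if grid_step is None or grid_step <= 0:
        span = coords.max(axis=0) - coords.min(axis=0)
        grid_step = float(span.max()) / 120.0
    gx = np.arange(coords[:, 0].min(), coords[:, 0].max() + grid_step, grid_step)
    gy = np.arange(coords[:, 1].min(), coords[:, 1].max() + grid_step, grid_step)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    vals = interp(X, Y)
    cell = grid_step**2
    threshold = 2.0 * noise_sd
    above = vals > threshold
    area = float(np.count_nonzero(above) * cell)
    if area == 0.0:
        centre = None
    else:
        w = vals[above]
        centre = np.array(
            [(w * X[above]).sum() / w.sum(), (w * Y[above]).sum() / w.sum()]
        )
    return ActivationMap(
        grid_x=gx,
        grid_y=gy,
        values=vals,
        threshold=threshold,
        activated_area=area,
        centre=centre,
    )


# --------------------------------------------------------------------------
# per-cell pipeline


def analyze_spike_trains(
    spikes: SpikeTrainSet,
    events: StimulusEvents,
    *,
    kernel_sigma: float = 3e-3,
    dt: float = 1e-3,
    baseline_window: float = 0.2,
    response_extra: float = 0.05,
    responsiveness_z: float = 3.0,
) -> pd.DataFrame:
    """Per-cell response table (latency, rate, duration, Fano, class).

    Spike times are re-referenced to each stimulus onset, pooling all
    events as trials of one condition.  A cell is responsive when its mean
    rate in the half-open window ``[0, stimulus duration + response_extra)``
    exceeds the pre-onset baseline mean by ``responsiveness_z`` baseline
    standard deviations (computed across trials).
    """
    window = events.duration + response_extra
    rows = []
    for cell in spikes.cells:
        trains = spikes.trains(cell)
        aligned = [
            tr[(tr >= onset - baseline_window) & (tr < onset + window + 0.1)] - onset
            for tr in trains
            for onset in events.onsets
        ]
        resp_counts = np.array(
            [np.count_nonzero((a >= 0) & (a < window)) for a in aligned], dtype=float
        )
        base_counts = np.array(
            [
                np.count_nonzero((a >= -baseline_window) & (a < 0))
                for a in aligned
            ],
            dtype=float,
        )
        base_rates = base_counts / baseline_window
        resp_rates = resp_counts / window
        base_sd = base_rates.std(ddof=1) if base_rates.size > 1 else 0.0
        responsive = bool(
            resp_rates.mean() > base_rates.mean() + responsiveness_z * max(base_sd, 1e-9)
        )
        t, sdf = spike_density_function(
            aligned,
            t_start=-baseline_window,
            t_stop=window + 0.05,
            dt=dt,
            kernel_sigma=kernel_sigma,
        )
        max_rate = float(sdf[(t >= 0) & (t < window)].max()) if responsive else float(
            sdf.max()
        )
        if responsive:
            latency = response_latency(t, sdf, 0.0, window=window)
            duration, censored = response_duration(t, sdf)
            if censored:
                duration = float("nan")
            fano = (
                fano_factor(resp_counts) if resp_counts.size >= 2 else float("nan")
            )
            if np.isnan(latency):
                klass = "none"
            else:
                klass = "SL" if latency < SL_LL_THRESHOLD else "LL"
        else:
            latency, duration, fano, klass = (
                float("nan"),
                float("nan"),
                float("nan"),
                "none",
            )
        pos = spikes.position(cell)
        rows.append(
            {
                "cell": cell,
                "x": pos[0],
                "y": pos[1],
                "latency": latency,
                "max_rate": max_rate,
                "duration": duration,
                "fano": fano,
                "latency_class": klass,
                "responsive": responsive,
            }
        )
    return pd.DataFrame(rows)
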