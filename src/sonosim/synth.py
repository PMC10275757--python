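"""Synthetic data generators with ground-truth sidecars.

Every analysis stage in this package can be exercised without recordings:
these generators emulate the statistical structure the metrics assume —

* :func:`gen_retina_mea` — retinal ganglion cells on a 16 x 16, 200 um pitch
  multielectrode array.  Mechanosensitised ("transfected") cells inside the
  Gaussian beam footprint respond with short latencies (~12 ms); a smaller
  network-mediated population responds with long latencies (~50 ms); spike
  trains are inhomogeneous Poisson.
* :func:`gen_ecog` — 32-channel surface ECoG (6 x 6 grid minus corners,
  300 um pitch) with an N1-like negative deflection whose amplitude follows
  the beam footprint, plus white noise.
* :func:`gen_licks` — behavioural sessions with spontaneous Poisson licking,
  pressure-dependent anticipatory licks, and optional compulsive-licker
  sessions.

All generators are deterministic under a fixed seed: each draws from
``numpy.random.default_rng([seed, stream])`` with a fixed per-generator
stream id, so adding a generator never perturbs the others.  Each returns
its data plus a ground-truth table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import LickSession
from .neural import EcogRecording, SpikeTrainSet, StimulusEvents

__all__ = ["GeneratorConfig", "gen_retina_mea", "gen_ecog", "gen_licks"]

_STREAM_RETINA = 1
_STREAM_ECOG = 2
_STREAM_LICKS = 3


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_normal(rng, mean, sd, low, high, size=None):
    """Rejection-sampled normal truncated to [low, high]."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = (out < low) | (out > high)
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions shared by the synthetic generators.

    Latency moments and lick latencies are the measured population values;
    beam footprints are the simulated focal-spot widths per frequency.  The
    rate-vs-pressure curves are logistic (the measured counts are monotone
    in pressure without a stated functional form).  All times s, lengths m,
    rates Hz, pressures Pa.
    """

    seed: int = 0

    # multielectrode array geometry (retina)
    mea_pitch: float = 200e-6
    mea_shape: tuple[int, int] = (16, 16)

    # beam footprint FWHM per carrier frequency (m)
    footprint_fwhm: Mapping[float, float] = field(
        default_factory=lambda: {0.5e6: 4.36e-3, 2.25e6: 1.61e-3, 15e6: 0.276e-3}
    )
    #: ratio of the neural response footprint to the acoustic FWHM (activity
    #: spreads slightly beyond the beam via cell size and network coupling)
    response_footprint_scale: float = 2.0

    transfected_fraction: float = 0.46  # G22S-expressing fraction of cells

    # response latency distributions (s), truncated > 0
    sl_latency_mean: float = 12.2e-3
    sl_latency_sd: float = 2.5e-3
    ll_latency_mean: float = 50.4e-3
    ll_latency_sd: float = 4.2e-3

    # firing-rate model
    baseline_rate: float = 2.0
    peak_rate_max: float = 60.0
    rate_pressure_threshold: float = 0.5e6  # Pa at half-max recruitment
    rate_pressure_slope: float = 0.15e6  # Pa
    ll_response_fraction: float = 0.25  # network-driven responders
    response_decay_tau: float = 0.02  # s, post-stimulus rate decay

    # surface ECoG
    ecog_pitch: float = 300e-6
    ecog_noise_sd: float = 3e-6  # V
    n1_amplitude_max: float = 40e-6  # V
    n1_latency: float = 25e-3  # s
    n1_width: float = 8e-3  # s (Gaussian sigma)
    ecog_footprint_sigma: float = 0.35e-3  # m

    # licking behaviour
    lick_spontaneous_rate: float = 1.0
    lick_compulsive_rate: float = 6.0
    lick_success_max: float = 0.75
    lick_pressure_threshold: float = 0.45e6
    lick_pressure_slope: float = 0.2e6
    light_success_prob: float = 0.85
    us_lick_latency_mean: float = 187.1e-3
    us_lick_latency_sd: float = 37.3e-3
    light_lick_latency_mean: float = 265.9e-3
    light_lick_latency_sd: float = 46.5e-3
    n_trials_per_session: int = 35
    reward_delay: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "baseline_rate",
            "peak_rate_max",
            "lick_spontaneous_rate",
            "lick_compulsive_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.transfected_fraction <= 1:
            raise ValueError("transfected_fraction must lie in [0, 1]")
        for name in ("sl_latency_sd", "ll_latency_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def recruitment(self, pressure: float) -> float:
        """Logistic response probability vs peak pressure, in [0, 1]."""
        return float(
            _sigmoid(
                (pressure - self.rate_pressure_threshold) / self.rate_pressure_slope
            )
        )

    def footprint_sigma(self, frequency: float) -> float:
        """Gaussian sigma (m) of the neural response footprint."""
        fwhm = self.footprint_fwhm[frequency]
        return self.response_footprint_scale * fwhm / (2.0 * np.sqrt(2 * np.log(2)))


def gen_retina_mea(
    config: GeneratorConfig,
    *,
    frequency: float = 15e6,
    pressure: float = 1.27e6,
    n_cells: int = 200,
    n_trials: int = 30,
    stimulus_duration: float = 0.05,
    trial_length: float = 1.0,
    onset: float = 0.3,
    beam_centre: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> tuple[SpikeTrainSet, StimulusEvents, pd.DataFrame]:
    """Synthetic retinal MEA recording under focused ultrasound.

    Cells are scattered uniformly over the array; transfected cells inside
    the beam footprint fire short-latency responses whose probability and
    peak rate follow the logistic recruitment curve; a network-mediated
    subset responds at long latency.  Returns the spike set, the stimulus
    events (one onset per trial at ``onset``) and a ground-truth table with
    one row per cell (class, true latency, true peak rate).
    """
    rng = rng or np.random.default_rng([config.seed, _STREAM_RETINA])
    ny, nx = config.mea_shape
    half_x = (nx - 1) * config.mea_pitch / 2.0
    half_y = (ny - 1) * config.mea_pitch / 2.0
    x = rng.uniform(-half_x, half_x, n_cells)
    y = rng.uniform(-half_y, half_y, n_cells)
    d2 = (x - beam_centre[0]) ** 2 + (y - beam_centre[1]) ** 2
    sigma = config.footprint_sigma(frequency)
    footprint = np.exp(-d2 / (2.0 * sigma**2))

    transfected = rng.random(n_cells) < config.transfected_fraction
    recruit = config.recruitment(pressure)
    p_sl = recruit * footprint
    sl = transfected & (rng.random(n_cells) < p_sl)
    sigma_ll = 1.5 * sigma  # network responses spread wider
    p_ll = config.ll_response_fraction * recruit * np.exp(-d2 / (2.0 * sigma_ll**2))
    ll = ~sl & (rng.random(n_cells) < p_ll)

    latency = np.full(n_cells, np.nan)
    latency[sl] = _truncated_normal(
        rng, config.sl_latency_mean, config.sl_latency_sd, 1e-4, np.inf, int(sl.sum())
    )
    latency[ll] = _truncated_normal(
        rng, config.ll_latency_mean, config.ll_latency_sd, 1e-4, np.inf, int(ll.sum())
    )
    peak_rate = np.zeros(n_cells)
    responders = sl | ll
    peak_rate[responders] = (
        config.peak_rate_max * recruit * rng.uniform(0.7, 1.0, int(responders.sum()))
    )
    peak_rate[ll] *= 0.5  # network responses are weaker and less sustained

    dt = 1e-3
    n_bins = int(round(trial_length / dt))
    t_bins = (np.arange(n_bins) + 0.5) * dt
    records = []
    for c in range(n_cells):
        rate = np.full(n_bins, config.baseline_rate)
        if responders[c]:
            t0 = onset + latency[c]
            t1 = t0 + stimulus_duration
            plateau = (t_bins >= t0) & (t_bins < t1)
            tail = t_bins >= t1
            rate = rate + peak_rate[c] * (
                plateau
                + tail * np.exp(-(t_bins - t1) / config.response_decay_tau)
            )
        counts = rng.poisson(rate[None, :] * dt, size=(n_trials, n_bins))
        trials, bins = np.nonzero(counts)
        reps = counts[trials, bins]
        trials = np.repeat(trials, reps)
        bins = np.repeat(bins, reps)
        times = (bins + rng.random(bins.size)) * dt
        records.append(
            pd.DataFrame({"cell": c, "trial": trials, "time": times})
        )
    spikes = pd.concat(records, ignore_index=True)
    positions = pd.DataFrame({"cell": np.arange(n_cells), "x": x, "y": y})
    truth = positions.assign(
        transfected=transfected,
        latency_class=np.where(sl, "SL", np.where(ll, "LL", "none")),
        latency_true=latency,
        peak_rate_true=peak_rate,
        footprint=footprint,
        frequency=frequency,
        pressure=pressure,
    )
    spike_set = SpikeTrainSet(spikes=spikes, positions=positions, n_trials=n_trials)
    events = StimulusEvents(
        onsets=np.array([onset]),
        duration=stimulus_duration,
        label={"pressure": pressure, "frequency": frequency},
    )
    return spike_set, events, truth


def _flexmea_layout(pitch: float) -> np.ndarray:
    """6 x 6 grid minus the four corners: 32 electrode coordinates (m)."""
    idx = np.arange(6) - 2.5
    coords = [
        (i * pitch, j * pitch)
        for j in idx
        for i in idx
        if not (abs(i) == 2.5 and abs(j) == 2.5)
    ]
    return np.asarray(coords)


def gen_ecog(
    config: GeneratorConfig,
    *,
    pressure: float = 1.27e6,
    footprint_centre: tuple[float, float] = (0.0, 0.0),
    n_trials: int = 100,
    fs: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> tuple[EcogRecording, pd.DataFrame]:
    """Synthetic 32-channel surface ECoG with an evoked N1 deflection.

    Each channel's mean response is a negative Gaussian deflection at
    ``n1_latency`` whose amplitude follows the beam footprint around
    ``footprint_centre`` and the logistic recruitment curve; white Gaussian
    noise of ``ecog_noise_sd`` is added per sample.  Returns the recording
    and a per-channel ground-truth table of true N1 amplitudes.
    """
    rng = rng or np.random.default_rng([config.seed, _STREAM_ECOG])
    coords = _flexmea_layout(config.ecog_pitch)
    n_ch = coords.shape[0]
    d2 = (coords[:, 0] - footprint_centre[0]) ** 2 + (
        coords[:, 1] - footprint_centre[1]
    ) ** 2
    amp = (
        config.n1_amplitude_max
        * config.recruitment(pressure)
        * np.exp(-d2 / (2.0 * config.ecog_footprint_sigma**2))
    )

    trial_period = 1.0
    onsets = 1.0 + trial_period * np.arange(n_trials)
    n_samp = int(round((onsets[-1] + trial_period) * fs))
    data = rng.normal(0.0, config.ecog_noise_sd, size=(n_ch, n_samp))
    t_rel = np.arange(int(0.2 * fs)) / fs  # 200 ms template support
    template = -np.exp(
        -((t_rel - config.n1_latency) ** 2) / (2.0 * config.n1_width**2)
    )
    for onset in onsets:
        i0 = int(round(onset * fs))
        data[:, i0 : i0 + t_rel.size] += amp[:, None] * template[None, :]
    positions = pd.DataFrame(
        {"channel": np.arange(n_ch), "x": coords[:, 0], "y": coords[:, 1]}
    )
    rec = EcogRecording(data=data, fs=fs, positions=positions, trial_onsets=onsets)
    truth = positions.assign(
        n1_true=amp,
        pressure=pressure,
        centre_x=footprint_centre[0],
        centre_y=footprint_centre[1],
    )
    return rec, truth


def gen_licks(
    config: GeneratorConfig,
    *,
    pressures: Sequence[float] = (0.2e6, 0.7e6, 1.2e6),
    n_sessions_per: int = 4,
    n_compulsive: int = 0,
    stimulus_type: str = "US",
    rng: np.random.Generator | None = None,
) -> tuple[list[LickSession], pd.DataFrame]:
    """Synthetic behavioural sessions across stimulus pressures.

    Each session has ``n_trials_per_session`` trials with inter-trial
    intervals uniform on [10, 30] s.  Licks are a homogeneous Poisson
    process at the spontaneous rate; on success trials (Bernoulli with the
    pressure-dependent probability; always ``light_success_prob`` for light)
    one anticipatory lick is added at the configured latency.  Compulsive
    sessions lick at ``lick_compulsive_rate`` with no anticipation.  Returns
    the sessions and a ground-truth table (one row per session).
    """
    rng = rng or np.random.default_rng([config.seed, _STREAM_LICKS])
    sessions: list[LickSession] = []
    rows = []
    specs = [(p, False) for p in pressures for _ in range(n_sessions_per)]
    specs += [(max(pressures), True) for _ in range(n_compulsive)]
    if stimulus_type == "US":
        lat_mu, lat_sd = config.us_lick_latency_mean, config.us_lick_latency_sd
    else:
        lat_mu, lat_sd = config.light_lick_latency_mean, config.light_lick_latency_sd
    for idx, (pressure, compulsive) in enumerate(specs):
        itis = rng.uniform(10.0, 30.0, config.n_trials_per_session)
        onsets = 10.0 + np.cumsum(itis)
        t_end = onsets[-1] + 5.0
        rate = (
            config.lick_compulsive_rate if compulsive else config.lick_spontaneous_rate
        )
        n_spont = rng.poisson(rate * t_end)
        licks = rng.uniform(0.0, t_end, n_spont)
        if compulsive:
            p_success = 0.0
        elif stimulus_type == "US":
            p_success = config.lick_success_max * _sigmoid(
                (pressure - config.lick_pressure_threshold)
                / config.lick_pressure_slope
            )
        else:
            p_success = config.light_success_prob
        hits = rng.random(config.n_trials_per_session) < p_success
        if np.any(hits):
            lat = _truncated_normal(
                rng, lat_mu, lat_sd, 1e-3, config.reward_delay - 1e-3, int(hits.sum())
            )
            licks = np.concatenate([licks, onsets[hits] + lat])
        session = LickSession(
            animal_id=f"synthetic-{idx:02d}",
            day=5,
            stimulus_type=stimulus_type,
            pressure=pressure,
            trial_onsets=onsets,
            lick_times=np.sort(licks),
            reward_delay=config.reward_delay,
        )
        sessions.append(session)
        rows.append(
            {
                "session": idx,
                "pressure": pressure,
                "compulsive": compulsive,
                "success_prob_true": p_success,
                "spontaneous_rate_true": rate,
                "lick_latency_mean_true": lat_mu,
            }
        )
    return sessions, pd.DataFrame(rows)
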