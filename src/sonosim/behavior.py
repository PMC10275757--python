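"""Associative licking-task metrics for go/no-go style training sessions.

A head-fixed, water-restricted mouse learns to associate a brief stimulus
(light flash, or focused ultrasound on the visual cortex) with a water
reward dispensed ``reward_delay`` seconds after stimulus onset.  A trial is
*successful* when the animal performs an anticipatory lick between stimulus
onset and valve opening.  Session-level metrics:

* success rate — percentage of successful trials;
* spontaneous rate — mean lick count in the 1 s window before each onset;
* anticipatory rate — anticipatory-window lick rate minus the spontaneous
  rate, multiplied by the success rate (as a fraction, keeping Hz units);
* first-lick latency — mean time to the first anticipatory lick over
  successful trials.

Sessions with compulsive licking are excluded on their spontaneous rate by
a robust outlier analog of the ROUT procedure: median/MAD z-scores converted
to two-sided normal tail probabilities under Benjamini-Hochberg FDR control
at Q (an analog of the proprietary method, not a clone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LickSession",
    "SessionMetrics",
    "trial_success",
    "success_rate",
    "spontaneous_rate",
    "anticipatory_rate",
    "first_lick_latency",
    "session_metrics",
    "rout_exclude",
    "retention_filter",
]


@dataclass
class LickSession:
    """One training session: trial onsets and lick timestamps (s)."""

    animal_id: str
    day: int
    stimulus_type: str  # "light" | "US"
    pressure: float  # Pa (0 for light)
    trial_onsets: np.ndarray
    lick_times: np.ndarray
    reward_delay: float = 0.5

    def __post_init__(self) -> None:
        self.trial_onsets = np.sort(np.asarray(self.trial_onsets, dtype=float))
        self.lick_times = np.sort(np.asarray(self.lick_times, dtype=float))
        if self.reward_delay <= 0:
            raise ValueError("reward_delay must be positive")
        if self.trial_onsets.size == 0:
            raise ValueError("session has no trials")

    @property
    def n_trials(self) -> int:
        return self.trial_onsets.size


@dataclass(frozen=True)
class SessionMetrics:
    """Derived per-session statistics."""

    success_rate: float  # percent
    anticipatory_rate: float  # Hz
    spontaneous_rate: float  # Hz
    first_lick_latency: float  # s; NaN when no successful trial
    excluded: bool = False


def trial_success(onset: float, licks: np.ndarray, reward_delay: float = 0.5) -> bool:
    """True iff at least one lick falls in ``[onset, onset + reward_delay)``."""
    licks = np.asarray(licks, dtype=float)
    return bool(np.any((licks >= onset) & (licks < onset + reward_delay)))


def success_rate(session: LickSession) -> float:
    """Percentage of trials with an anticipatory lick."""
    wins = sum(
        trial_success(onset, session.lick_times, session.reward_delay)
        for onset in session.trial_onsets
    )
    return 100.0 * wins / session.n_trials


def spontaneous_rate(session: LickSession) -> float:
    """Mean lick count (Hz) in the 1 s windows before each stimulus onset."""
    licks = session.lick_times
    counts = [
        np.count_nonzero((licks >= onset - 1.0) & (licks < onset))
        for onset in session.trial_onsets
    ]
    return float(np.mean(counts))


def _anticipatory_window_rate(session: LickSession) -> float:
    """Mean lick rate (Hz) in the pre-reward anticipation window."""
    licks = session.lick_times
    counts = [
        np.count_nonzero((licks >= onset) & (licks < onset + session.reward_delay))
        for onset in session.trial_onsets
    ]
    return float(np.mean(counts)) / session.reward_delay


def anticipatory_rate(session: LickSession) -> float:
    """Spontaneous-corrected anticipatory lick rate scaled by success (Hz).

    ``(anticipatory-window rate - spontaneous rate) * success fraction``;
    the success rate enters as a fraction so the result stays in Hz.
    """
    return (
        _anticipatory_window_rate(session) - spontaneous_rate(session)
    ) * (success_rate(session) / 100.0)


def first_lick_latency(session: LickSession) -> float:
    """Mean time (s) to the first anticipatory lick over successful trials."""
    latencies = []
    for onset in session.trial_onsets:
        in_win = session.lick_times[
            (session.lick_times >= onset)
            & (session.lick_times < onset + session.reward_delay)
        ]
        if in_win.size:
            latencies.append(in_win[0] - onset)
    if not latencies:
        return float("nan")
    return float(np.mean(latencies))


def session_metrics(session: LickSession, *, excluded: bool = False) -> SessionMetrics:
    """All session-level metrics in one pass."""
    return SessionMetrics(
        success_rate=success_rate(session),
        anticipatory_rate=anticipatory_rate(session),
        spontaneous_rate=spontaneous_rate(session),
        first_lick_latency=first_lick_latency(session),
        excluded=excluded,
    )


def rout_exclude(
    spontaneous_rates: np.ndarray, q: float = 0.01, *, min_sessions: int = 4
) -> np.ndarray:
    """Robust outlier exclusion on session spontaneous lick rates.

    A one-dimensional analog of the ROUT procedure for a constant model:
    deviations from the median are scaled by the normal-consistent MAD
    (1.4826 x MAD), converted to two-sided normal tail probabilities and
    subjected to Benjamini-Hochberg FDR control at ``q``.  Returns a boolean
    exclusion mask.  With fewer than ``min_sessions`` sessions no exclusion
    is attempted (a warning is issued).
    """
    rates = np.asarray(spontaneous_rates, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    n = rates.size
    if n < min_sessions:
        warnings.warn(
            f"only {n} sessions; need >= {min_sessions} for outlier exclusion",
            stacklevel=2,
        )
        return np.zeros(n, dtype=bool)
    med = np.median(rates)
    mad = stats.median_abs_deviation(rates, scale="normal")
    dev = np.abs(rates - med)
    if mad == 0:
        # all-but-outlier ties: anything strictly off the median is extreme
        return dev > 0
    z = dev / mad
    pvals = 2.0 * stats.norm.sf(z)
    # Benjamini-Hochberg step-up
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresh = q * (np.arange(1, n + 1)) / n
    passing = ranked <= thresh
    mask = np.zeros(n, dtype=bool)
    if np.any(passing):
        k = np.max(np.nonzero(passing)[0])
        mask[order[: k + 1]] = True
    return mask


def retention_filter(day4_success_rate: float, threshold: float = 60.0) -> bool:
    """Keep an animal whose day-4 success rate reaches the threshold (%)."""
    if not 0 <= day4_success_rate <= 100:
        raise ValueError("success rate must be a percentage in [0, 100]")
    return day4_success_rate >= threshold
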