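"""Analyse synthetic lick-training sessions across stimulus pressures.

A trial succeeds when the animal licks between stimulus onset and reward
delivery 500 ms later.  The session metrics are the success rate, the
spontaneous-corrected anticipatory lick rate, and the first-lick latency;
compulsive-licking sessions are excluded on their spontaneous rate with a
robust median/MAD + FDR outlier rule.
"""

import numpy as np

from sonosim import GeneratorConfig, gen_licks, session_metrics
from sonosim.behavior import rout_exclude

cfg = GeneratorConfig(seed=3)
sessions, truth = gen_licks(cfg, n_sessions_per=4, n_compulsive=1)
metrics = [session_metrics(s) for s in sessions]
excluded = rout_exclude(np.array([m.spontaneous_rate for m in metrics]))

for pressure in (0.2e6, 0.7e6, 1.2e6):
    keep = [
        m
        for m, s, e in zip(metrics, sessions, excluded)
        if s.pressure == pressure and not e
    ]
    print(
        f"{pressure / 1e6:.1f} MPa: success {np.mean([m.success_rate for m in keep]):5.1f}% | "
        f"anticipatory rate {np.mean([m.anticipatory_rate for m in keep]):.2f} Hz | "
        f"first lick {np.mean([m.first_lick_latency for m in keep]) * 1e3:.0f} ms"
    )
n_comp = int(truth.compulsive.sum())
print(f"excluded sessions: {int(excluded.sum())} (generated compulsive: {n_comp})")
print(
    "\nSuccess and anticipation climb with pressure — the behavioural "
    "signature that cortical\nultrasound stimulation is perceived — while "
    "the outlier rule removes compulsive lickers."
)
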