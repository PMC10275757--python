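"""Generate a synthetic retinal MEA recording and recover its structure.

Mechanosensitised ganglion cells inside the 15 MHz beam footprint respond
with ~12 ms latencies; network-mediated responses arrive after ~50 ms.  The
analysis classifies cells as short-latency (SL, < 45 ms) or long-latency
(LL) from the spike density function and localises the activated patch.
"""

import numpy as np

from sonosim import GeneratorConfig, gen_retina_mea
from sonosim.neural import analyze_spike_trains, response_centre, spatial_dispersion

cfg = GeneratorConfig(seed=42)
spikes, events, truth = gen_retina_mea(cfg, n_cells=400, n_trials=40)
table = analyze_spike_trains(spikes, events)
resp = table[table.responsive]

n_sl = (resp.latency_class == "SL").sum()
n_ll = (resp.latency_class == "LL").sum()
true_sl = (truth.latency_class == "SL").sum()
true_ll = (truth.latency_class == "LL").sum()
print(f"responders found: {n_sl} SL + {n_ll} LL (ground truth {true_sl} + {true_ll})")

sl = resp[resp.latency_class == "SL"]
print(
    f"median SL latency {sl.latency.median() * 1e3:.1f} ms "
    f"(generator draws from 12.2 +/- 2.5 ms)"
)
centre = response_centre(resp[["x", "y"]].to_numpy(), resp.max_rate.to_numpy())
disp = spatial_dispersion(resp[["x", "y"]].to_numpy(), resp.max_rate.to_numpy())
print(
    f"response centre ({centre[0] * 1e3:+.2f}, {centre[1] * 1e3:+.2f}) mm, "
    f"dispersion {disp * 1e3:.2f} mm"
)
print(
    "\nThe rate-weighted dispersion tracks the beam footprint: at 15 MHz the "
    "activated patch\nis sub-millimetre, the basis of the claimed spatial "
    "resolution."
)
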