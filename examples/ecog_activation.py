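"""Map cortical activation from synthetic surface-ECoG recordings.

Each channel's evoked potential is averaged over trials; the N1 amplitude
(most negative deflection after onset) is interpolated across the 32-site
array, thresholded at twice the baseline noise s.d., and summarised as an
activated area and an amplitude-weighted centre.  Moving the simulated beam
moves the recovered centre.
"""

from sonosim import GeneratorConfig, gen_ecog
from sonosim.neural import centre_displacement, ecog_activation_map, evoked_potential

cfg = GeneratorConfig(seed=7)


def analyse(shift_m):
    rec, _ = gen_ecog(cfg, footprint_centre=(shift_m, 0.0))
    ev = evoked_potential(rec)
    amap = ecog_activation_map(
        ev.n1_amplitude, rec.positions[["x", "y"]].to_numpy(), ev.noise_sd
    )
    return ev, amap


ev0, map0 = analyse(0.0)
ev1, map1 = analyse(0.4e-3)
print(f"peak N1 amplitude: {ev0.n1_amplitude.max() * 1e6:.1f} uV")
print(f"activated area: {map0.activated_area * 1e6:.2f} mm^2")
moved = centre_displacement(map0.centre, map1.centre)
print(f"centre displacement for a 0.4 mm beam shift: {moved * 1e3:.2f} mm")
print(
    "\nThe recovered displacement undershoots the beam shift slightly — the "
    "300 um electrode\npitch and the finite array clip the activation "
    "footprint, as in real recordings."
)
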