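"""Characterise the focal spots of the three built-in transducers.

For each spherical-cap transducer the on-axis profile comes from the
closed-form focusing-bowl solution and the transverse profile from the
numerical Rayleigh integral; the printed numbers are the focal-spot widths
(full width at half maximum) and the depth of the pressure maximum measured
from the apex of the concave surface.
"""

from sonosim import WATER, characterize_beam, get_preset

for name in ("0.5MHz", "2.25MHz", "15MHz"):
    metrics, _ = characterize_beam(get_preset(name), WATER)
    print(
        f"{name:>8}: lateral FWHM {metrics.lateral_fwhm * 1e3:6.3f} mm | "
        f"axial FWHM {metrics.axial_fwhm * 1e3:6.2f} mm | "
        f"peak depth {metrics.peak_depth * 1e3:6.2f} mm"
    )

print(
    "\nRaising the carrier from 0.5 to 15 MHz shrinks the focal spot from "
    "millimetres to ~0.28 mm,\nwhich is what makes single-cortical-column "
    "ultrasound stimulation conceivable."
)
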