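"""Acoustic exposure intensities for typical stimulation settings.

Intensities follow the plane-wave convention I = p^2 / (2 rho c): Isppa is
the pulse average over the on portion of the burst, Isptp the temporal
peak (water sound speed convention), Ispta the average over the burst
repetition period.  Values are non-derated (no tissue attenuation applied),
i.e. worst case, and printed in W/cm^2 for comparison with diagnostic
imaging safety limits.
"""

from sonosim import USStimulus, attenuation_np, exposure_metrics

# a 10 ms imaging-level burst: 0.6 MPa, 1 kHz PRF, 50% duty, every 0.5 s
stim = USStimulus(peak_pressure=0.6e6, burst_duration=0.01)
m = exposure_metrics(stim, isppa_sound_speed=1500.0, averaging_period=0.5)
print(
    f"0.6 MPa, 10 ms burst: Isptp {m['isptp']:.2f} W/cm^2, "
    f"Ispta {m['ispta']:.2f} W/cm^2"
)

# the strongest 15 MHz stimulation setting
strong = USStimulus(peak_pressure=1.27e6, burst_duration=0.02)
print(
    f"1.27 MPa, 20 ms burst: Isppa "
    f"{exposure_metrics(strong)['isppa']:.2f} W/cm^2"
)

alpha = attenuation_np(0.21, 1.18, 15e6)
print(f"brain amplitude absorption at 15 MHz: {alpha:.2f} Np/m")
print(
    "\nThese levels sit inside the envelope long used for diagnostic "
    "ultrasound imaging,\nwhich is the core of the safety argument for "
    "high-frequency sonogenetic stimulation."
)
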