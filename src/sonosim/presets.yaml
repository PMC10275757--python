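# Built-in transducer presets: the three spherical-cap geometries used for
# sonogenetic stimulation, with the peak-pressure ranges they were driven at.
# Units: Hz, m, Pa.
transducers:
  "0.5MHz":
    center_frequency: 0.5e6
    aperture_diameter: 25.4e-3
    radius_of_curvature: 31.75e-3
    pressure_range: [0.11e6, 0.88e6]
  "2.25MHz":
    center_frequency: 2.25e6
    aperture_diameter: 12.7e-3
    radius_of_curvature: 25.4e-3
    pressure_range: [0.30e6, 1.60e6]
  "15MHz":
    center_frequency: 15.0e6
    aperture_diameter: 12.7e-3
    radius_of_curvature: 25.4e-3
    pressure_range: [0.20e6, 1.27e6]
media:
  water:
    sound_speed: 1500.0
    density: 1000.0
    attenuation_prefactor: 2.2e-3
    attenuation_exponent: 2.0
    nonlinearity_ba: 5.0
stimulus_defaults:
  pulse_repetition_frequency: 1000.0
  duty_cycle: 0.5
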