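# sonosim

Tools for the physics and analysis behind **high-frequency sonogenetic
neurostimulation**: focused ultrasound delivered to neurons that have been
genetically sensitised with the bacterial mechanosensitive channel MscL
(G22S), so that millisecond ultrasound bursts evoke spiking at
sub-millimetre spatial resolution — a candidate route to cortical visual
prostheses.

The package is for researchers who need to (a) predict what a spherical-cap
focused transducer does to tissue — focal-spot geometry, acoustic exposure,
worst-case heating — and (b) quantify evoked neural and behavioural
responses with the field's standard metrics, on real or synthetic data.

## What it computes

**Acoustic field** (`sonosim.acoustics`). Linear monochromatic pressure
fields of a concave spherical cap with uniform surface velocity. On the
beam axis the closed-form focusing-bowl solution is used,

```
p(z) = p0 / (1 - z/R) * (e^{ikz} - e^{ik r_b(z)}),   k = ω/c + iα_np,
```

with `R` the radius of curvature, `r_b` the distance to the rim, and the
removable singularity at the geometric focus replaced by its limit
`p0·k·h` (`h` the cap depth). Off axis, the cap is tiled into point sources
at ≤ λ/6 pitch and summed (Rayleigh integral). Beam metrics — lateral and
axial FWHM, peak depth — come from interpolated half-maximum crossings.
Exposure intensities use the plane-wave convention `I = p²/(2ρc)`
(Isppa / Ispta / Isptp, non-derated).

**Tissue heating** (`sonosim.thermal`). The absorbed-power source
`Q_us = α_np · p_max² / (ρ_b c_b)` drives the Pennes bioheat equation

```
ρC ∂T/∂t = ∇·(K∇T) − ρ_bl C_bl P_bl (T − T_a) + Q_us(t) + ρ γ,
```

solved with explicit finite differences on a focal subdomain, Dirichlet
boundaries at the arterial temperature, and exact burst-envelope gating.
The ultrasound-attributable rise is the max over space and time of the
difference between runs with and without `Q_us`.

**Neural responses** (`sonosim.neural`). Gaussian-kernel spike density
functions; latency as the post-onset maximum of the SDF derivative, with
the 45 ms short/long-latency split; response duration between the outermost
peak/e crossings; Fano factor; rate-weighted spatial dispersion and centre;
evoked-potential N1 amplitudes and interpolated ECoG activation maps
thresholded at 2× the baseline noise s.d.

**Behaviour** (`sonosim.behavior`). Anticipatory-lick trial success,
session success rate, spontaneous-corrected anticipatory lick rate,
first-lick latency, a robust median/MAD + FDR analog of ROUT outlier
exclusion, and the 60% day-4 retention filter.

**Synthetic data** (`sonosim.synth`). Deterministic, seeded generators for
retinal MEA spike trains, 32-channel surface ECoG, and lick sessions, each
with a ground-truth sidecar so every estimator is testable by parameter
recovery.

## Worked example

```
$ python examples/beam_characterization.py
  0.5MHz: lateral FWHM  4.278 mm | axial FWHM  31.21 mm | peak depth  24.78 mm
 2.25MHz: lateral FWHM  1.629 mm | axial FWHM  20.87 mm | peak depth  21.70 mm
   15MHz: lateral FWHM  0.280 mm | axial FWHM   3.78 mm | peak depth  25.27 mm
```

Raising the carrier frequency from 0.5 to 15 MHz shrinks the focal spot
from 4.3 mm to 0.28 mm — the resolution gain that makes patterned cortical
stimulation plausible — while the peak moves close to the geometric focus
(25.27 vs 25.4 mm) as the focusing gain grows.

```
$ python examples/thermal_safety.py
single 20 ms burst at 1.27 MPa: peak rise 0.120 degC
```

Even the strongest stimulus heats the focus by only ~0.12 °C under
worst-case assumptions (water propagation, brain absorption), far below
thermal-damage thresholds: evoked responses are mechanically, not
thermally, driven.

The other scripts in `examples/` walk through exposure metrics, a retinal
MEA round trip, ECoG activation mapping, and behavioural session analysis,
each printing the numbers it computes and what they mean. A thin CLI wraps
the same calls (`sonosim presets`, `sonosim beam-metrics`, `sonosim
exposure`, `sonosim heat`, `sonosim generate`, `sonosim analyze-*`,
`sonosim run`).

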