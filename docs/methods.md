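# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `sonosim`, and what the synthetic-data tests do and do not
establish about real recordings.

## Acoustic field model

The transducers are concave spherical caps (aperture diameter Ø, radius of
curvature R) vibrating with uniform normal velocity at a single frequency.
Propagation is linear in a homogeneous lossy fluid; the B/A nonlinearity
parameter is stored on `AcousticMedium` but deliberately unused — at the
pressures involved the second harmonic carries ~1% of the energy, so linear
fields are adequate for geometry and heating estimates. Nonlinear
propagation, skull aberration and standing waves are out of scope.

Conventions that matter when comparing numbers:

* **Axial origin at the apex** of the concave surface (its deepest point);
  the geometric focus sits at `z = R`. The rim plane lies at the cap depth
  `h = R − √(R² − a²)` (2.65 mm for the 0.5 MHz geometry, 0.81 mm at
  15 MHz), so apex- vs rim-referenced depths differ by that much.
* **Attenuation is an amplitude convention**: the power-law coefficient
  `α[dB/cm/MHz^y]` converts to Np/m as `α·(f/MHz)^y·100·ln10/20` and enters
  the field as `exp(−α_np r)` per ray (complex wavenumber). Water uses
  `2.2×10⁻³ dB/cm/MHz²`; brain absorption uses `0.21 dB/cm/MHz^1.18`
  (59.05 Np/m at 15 MHz).
* The source strength `p0 = ρ c u0` (Pa) makes every field quantity exactly
  linear in the drive, so calibration to a target focal pressure is a
  single rescale, never an iteration.

On the beam axis the closed-form focusing-bowl solution is exact for this
model, including the removable singularity at the focus (`p → p0 k h`).
Off axis, the cap is tiled into rings split azimuthally so the element
pitch never exceeds λ/6 by default (λ/4 for heating maps, where the field
enters squared and spatially averaged; pitches above λ/2 are refused as
aliased). The numeric integral agrees with the closed form to <0.15% near
the focus at λ/6 and to <0.4% over 0.2–1.5 R at λ/12.

Beam metrics: FWHM crossings are linearly interpolated between samples,
walking outward from the peak so that flat runs exactly at the half level
resolve to the outermost crossing; the peak depth is refined with a
three-point parabola. `characterize_beam` samples the axial profile with
the closed form (4001 points over 0.05–2 R) and the transverse profile with
the Rayleigh integral on the axisymmetric fast path (241 radii spanning
~3× the diffraction-limited width). Doubling either sampling changes the
reported metrics by well under 0.5%.

A note on the 0.5 MHz geometry: with the apex origin and the nominal
31.75 mm radius of curvature, the low focusing gain (ka²/2R ≈ 5) puts the
on-axis maximum at 24.78 mm. Referencing the nominal focal distance to the
rim plane instead (R = 34.2 mm) would move the maximum to 25.9 mm but
widens both FWHMs by 5–7% and misplaces the 15 MHz peak; no single
convention reconciles every published characterisation of such transducers,
and the apex/nominal convention used here is the one that reproduces the
focal-spot widths and the high-frequency peak depth.

## Exposure metrics

Plane-wave intensities `I = p²/(2ρc)` in W/cm²: Isppa averages over the on
portion of the burst; Isptp is the temporal peak; Ispta multiplies Isppa by
the intra-burst duty cycle and the burst on-fraction of an averaging
period. Two sound speeds are deliberately independent parameters because
reported values back-calculate with different conventions: Isppa defaults
to 1540 m/s (soft tissue), Isptp to 1500 m/s (water). The Ispta time base
is explicit (default: the stimulus burst period) since a 10 ms burst
averaged over 0.5 s with 50% duty gives 0.12 W/cm², but other windows are
defensible; a non-repeating stimulus with no window has no Ispta (NaN).

## Bioheat model

Pennes equation with brain parameters ρ=1046 kg/m³, C=3630 J/kg/°C,
K=0.51 W/m/°C, blood ρ=1050, C=3617, perfusion 9.7×10⁻³ s⁻¹, arterial
temperature 37 °C, metabolic heat 11.37 W/kg. The brain sound speed used in
the source term is 1546 m/s. The source is `Q_us = α_np p_max²/(ρ_b c_b)`
with the *water-simulated* maximum-pressure field and *brain* absorption —
a deliberate worst case on both counts (the field is overestimated, the
absorption is overestimated).

Numerical choices:

* The 1 kHz intra-burst pulsing is not time-resolved: its period is ~50×
  shorter than the conduction time constant of even the 0.28 mm spot, so
  the duty cycle multiplies `Q_us` during bursts. An exact pulse-gated
  envelope (`time_resolve_prf=True`) exists for validation.
* Explicit finite differences on a rectilinear focal subdomain with
  Dirichlet `T = T_a` faces; the stability bound
  `dt ≤ ρC/(2K Σ 1/dx_i²)` is enforced with an informative refusal, and
  NaNs abort. Burst envelopes are integrated exactly over each step, so
  time steps need not divide the burst timing.
* The default single-burst scenario uses a 3×3×12 mm domain at
  50 µm lateral / 250 µm axial spacing; the pressure map feeding it is
  sampled radially at ~1/15 of the focal FWHM near the axis. Refining the
  grid changes the peak rise by <5%; the single-burst result is insensitive
  to the domain because heat barely moves in 20 ms.
* The ultrasound-attributable rise is computed as the difference between a
  driven and a silent run tracked at the heated node every step (plus all
  stored snapshot pairs); metabolic heating and perfusion cancel exactly by
  linearity.
* Repeated stimulation is integrated ≥10 s on a 6×6×12 mm domain and a
  plateau is declared when the trailing 4 s relative slope of the running
  peak rise falls below 1%/s.

With these conventions a single 20 ms, 1.27 MPa, 15 MHz burst yields a peak
rise of ~0.12 °C. Sustained 13 Hz repetition of that same burst, run to
plateau, accumulates further: the inter-burst envelope settles near
0.33–0.35 °C and the within-burst peak near 0.40–0.45 °C, values that grow
slightly (not shrink) when the domain is doubled. Short trains behave
differently — a ~2 s train stays under 0.30 °C — so bounded-heating claims
for repeated stimulation depend critically on train duration; the package
reports the conservative to-plateau number.

## Neural response metrics

Seconds, metres, Hz and volts internally; stimulus onset defines t = 0 per
trial; response windows are half-open `[onset, onset+w)`.

* **SDF**: spike histograms at 1 ms bins smoothed with a Gaussian kernel,
  σ = 3 ms by default — wide enough to suppress bin noise, narrow enough to
  resolve ~12 ms latencies. Latency is the post-onset argmax of the SDF
  derivative and is quoted to ±1 kernel σ; at low spike counts (weak cells,
  few trials) this estimator is noisy, so population comparisons should use
  medians or pooled cells. Short vs long latency splits at 45 ms.
* **Duration**: outermost crossings of peak/e around the SDF peak,
  interpolated; traces that never fall below peak/e are flagged censored.
* **Fano factor**: variance/mean of per-trial response-window counts with
  the unbiased (ddof=1) variance; undefined (NaN) at zero mean.
* **Responsiveness** (the criterion is a package choice): mean response-
  window rate above baseline mean + 3 baseline s.d. across trials, window =
  stimulus duration + 50 ms.
* **Dispersion** is the weighted mean pairwise distance
  `Σᵢ<ⱼ wᵢwⱼdᵢⱼ / Σᵢ<ⱼ wᵢwⱼ` and the **centre** the weighted centroid
  `Σwᵢxᵢ/Σwᵢ`, with w the maximum firing rate (or N1 amplitude) normalised
  to the population maximum. Among the variants consistent with a verbal
  definition of "rate-weighted distance", the centroid is the only one that
  is symmetric, shift-equivariant and recovers a known displacement.
* **ECoG**: trial-mean evoked potentials; N1 is the magnitude of the most
  negative deflection within 100 ms of onset relative to the pre-onset
  baseline mean. The noise s.d. is that of the *raw single-trial* baseline
  (200 ms pre-onset, pooled over channels), and the activation threshold is
  2× that value: thresholding the trial-mean noise instead would let the
  max-of-noise bias of N1 push silent channels over threshold. Maps are
  piecewise-linear interpolations on the electrode Delaunay triangulation,
  evaluated at 1/12 pitch; the activated area counts suprathreshold nodes
  and the centre is their amplitude-weighted centroid.

## Behavioural metrics

Success = any lick in `[onset, onset+0.5 s)`. The anticipatory rate
subtracts the spontaneous rate (mean count in the 1 s pre-onset windows)
from the anticipation-window rate and multiplies by the success rate *as a
fraction*, keeping the result in Hz. First-lick latency averages over
successful trials only. Session exclusion is a 1-D robust analog of the
ROUT procedure — median/MAD(×1.4826) z-scores, two-sided normal tails,
Benjamini–Hochberg at Q=1% — documented as an analog, not a clone of the
proprietary method; on clean Gaussian sessions its false-exclusion rate
measures ~0.1–1%, and it requires ≥4 sessions.

## Synthetic-data generators

The generators emulate the statistical structure the estimators assume, not
the biophysics. Conditions fixed by the emulated experiments: 16×16 MEA at
200 µm pitch; 32-channel 6×6-minus-corners surface array at 300 µm pitch
(the exact commercial layout is not public; the layout is overridable);
short-latency responses N(12.2, 2.5²) ms and long-latency N(50.4, 4.2²) ms,
truncated positive; 46% transfected fraction; 35-trial sessions with
10–30 s inter-trial intervals and a 500 ms reward delay; anticipatory lick
latencies N(187, 37²) ms (ultrasound) and N(266, 46²) ms (light).

Modelling choices (made once, documented here): recruitment versus pressure
is logistic (threshold 0.5 MPa, slope 0.15 MPa) because measured recruitment
is monotone with no published functional form; baseline retinal firing is
2 Hz and peak evoked rates 60 Hz with ±30% per-cell jitter; the neural
response footprint is twice the acoustic FWHM (activity spreads via cell
size and coupling); spike trains are inhomogeneous Poisson with a
rectangular evoked plateau and a 20 ms exponential tail; the ECoG N1
template is a negative Gaussian (25 ms latency, 8 ms width, ≤40 µV) on
3 µV white noise, with a 0.35 mm footprint σ chosen so the full-pressure
activated area lands near the measured ~1.4 mm²; lick success combines a
logistic genuine-anticipation term (max 0.75) with the spontaneous
coincidence floor `1 − e^{−0.5 r}`; compulsive lickers run at 6 Hz.

Each generator draws from `default_rng([seed, stream])` with a fixed
per-generator stream id, so outputs are reproducible and mutually
independent, and each emits a ground-truth table.

What passing the round-trip tests shows: the estimators are unbiased and
appropriately precise *under the generative assumptions* — Poisson spiking,
Gaussian footprints, stationary noise, no artifacts. Real recordings add
spike-sorting errors, correlated noise, drifting baselines and
non-stationary behaviour that these tests do not probe; filtering and
artifact rejection are out of scope.

## Known limitations

* Acoustics: linear, homogeneous media only; no skull, no standing waves,
  no cavitation or mechanical-index reporting.
* Thermal: constant parameters (no temperature dependence), no thermal
  dose (CEM43) accumulation; the Dirichlet focal subdomain slightly
  underestimates long-train plateaus (doubling the domain raises the 13 Hz
  plateau by a few percent).
* Latency estimation degrades gracefully but noticeably at low spike
  counts; durations are right-censored for sustained responses that do not
  return to peak/e within the analysis window.
* The displaced-footprint centre systematically under-recovers beam shifts
  when the footprint is clipped by the array edge — on the 1.5 mm surface
  array a 0.4 mm shift reads as ~0.3 mm — mirroring the same effect in real
  recordings; the larger retinal array recovers 0.4/0.8 mm shifts within
  half an electrode pitch on average.
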