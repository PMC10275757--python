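"""Linear monochromatic acoustics of spherical-cap focused transducers.

The model is the classic single-frequency Rayleigh picture of a concave
spherical cap vibrating with uniform normal velocity in a lossy fluid.
Two routes to the radiated field are provided:

* :func:`onaxis_pressure` — the closed-form on-axis solution for a focusing
  bowl (O'Neil's result), valid anywhere on the beam axis including the
  geometric focus, with attenuation entering through a complex wavenumber.
* :func:`rayleigh_field` — a numerical surface integral over the cap,
  discretised into point sources at a configurable sub-wavelength pitch,
  usable at arbitrary field points.

Beam metrics (lateral/axial full width at half maximum, peak depth, peak
pressure) are extracted from amplitude profiles with linear interpolation of
the half-maximum crossings.

Conventions
-----------
* SI units throughout (metres, Pa, Hz, seconds).
* The axial origin ``z = 0`` sits at the *apex* of the concave surface (the
  deepest point of the bowl); the geometric focus is at
  ``z = radius_of_curvature``.
* ``source_amplitude`` is the uniform-velocity equivalent surface pressure
  ``rho * c * u0`` in Pa; every field quantity is homogeneous of degree one
  in it.
* Attenuation is an amplitude convention: each ray of length ``r`` carries
  ``exp(-alpha_np * r)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ._rayleigh import cap_point_sources, field_at_points

__all__ = [
    "TransducerSpec",
    "AcousticMedium",
    "FieldGrid",
    "PressureField",
    "BeamMetrics",
    "USStimulus",
    "WATER",
    "attenuation_np",
    "onaxis_pressure",
    "rayleigh_field",
    "axisymmetric_pressure_map",
    "revolve_pressure_map",
    "beam_metrics",
    "characterize_beam",
    "calibrate_amplitude",
    "exposure_metrics",
    "profile_fwhm",
    "ISPPA_SOUND_SPEED",
    "ISPTP_SOUND_SPEED",
]

#: Sound speeds used by the exposure-metric conventions (m/s).  Isppa is
#: back-calculated with soft-tissue sound speed, Isptp with water.  Both are
#: explicit parameters of :func:`exposure_metrics`; these are only defaults.
ISPPA_SOUND_SPEED = 1540.0
ISPTP_SOUND_SPEED = 1500.0


def attenuation_np(prefactor: float, exponent: float, frequency: float) -> float:
    """Convert a power-law attenuation coefficient to Np/m at ``frequency``.

    Parameters
    ----------
    prefactor:
        Attenuation prefactor in dB cm^-1 MHz^-y.
    exponent:
        Frequency power-law exponent ``y`` (dimensionless).
    frequency:
        Frequency in Hz.

    Returns
    -------
    float
        Amplitude attenuation coefficient in Np m^-1:
        ``prefactor * (f/MHz)**y * 100 * ln(10)/20``.
    """
    if prefactor < 0 or frequency <= 0:
        raise ValueError("prefactor must be >= 0 and frequency > 0")
    return prefactor * (frequency / 1e6) ** exponent * 100.0 * np.log(10.0) / 20.0


@dataclass(frozen=True)
class AcousticMedium:
    """Homogeneous lossy fluid medium for linear propagation.

    ``nonlinearity_ba`` (B/A) is carried for bookkeeping only; no linear
    operation reads it.
    """

    sound_speed: float = 1500.0  # m/s
    density: float = 1000.0  # kg/m^3
    attenuation_prefactor: float = 2.2e-3  # dB/cm/MHz^y
    attenuation_exponent: float = 2.0  # y
    nonlinearity_ba: float = 5.0  # B/A, stored only

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound_speed and density must be positive")
        if self.attenuation_prefactor < 0:
            raise ValueError("attenuation_prefactor must be >= 0")

    def attenuation_np(self, frequency: float) -> float:
        """Amplitude attenuation (Np/m) of this medium at ``frequency``."""
        return attenuation_np(
            self.attenuation_prefactor, self.attenuation_exponent, frequency
        )

    def wavenumber(self, frequency: float) -> complex:
        """Complex wavenumber ``omega/c + i*alpha_np`` (amplitude convention)."""
        return 2.0 * np.pi * frequency / self.sound_speed + 1j * self.attenuation_np(
            frequency
        )


#: Degassed water at room temperature, the coupling/propagation medium.
WATER = AcousticMedium()


@dataclass(frozen=True)
class TransducerSpec:
    """Spherical-cap focused transducer (geometric focus at the centre of
    curvature).

    ``source_amplitude`` is the uniform surface pressure ``rho*c*u0`` (Pa).
    """

    center_frequency: float  # Hz
    aperture_diameter: float  # m
    radius_of_curvature: float  # m
    source_amplitude: float = 1.0  # Pa

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.source_amplitude < 0:
            raise ValueError("source_amplitude must be >= 0")
        if not 0 < self.aperture_diameter < 2 * self.radius_of_curvature:
            raise ValueError(
                "aperture_diameter must lie in (0, 2*radius_of_curvature)"
            )

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def cap_depth(self) -> float:
        """Axial depth of the concave bowl (apex to rim plane), m."""
        return self.radius_of_curvature - np.sqrt(
            self.radius_of_curvature**2 - self.aperture_radius**2
        )

    @property
    def f_number(self) -> float:
        return self.radius_of_curvature / self.aperture_diameter

    def wavelength(self, medium: AcousticMedium) -> float:
        return medium.sound_speed / self.center_frequency

    def with_amplitude(self, source_amplitude: float) -> "TransducerSpec":
        return replace(self, source_amplitude=source_amplitude)


@dataclass(frozen=True)
class USStimulus:
    """Pulsed ultrasound stimulus: intra-burst gating plus burst repetition.

    A *burst* of ``burst_duration`` seconds is internally gated at
    ``pulse_repetition_frequency`` with on-fraction ``duty_cycle``; bursts
    repeat either at ``repetition_frequency`` or after
    ``inter_stimulus_interval`` of silence, ``n_repeats`` times.
    """

    peak_pressure: float  # Pa at the focus
    burst_duration: float  # s
    pulse_repetition_frequency: float = 1000.0  # Hz
    duty_cycle: float = 0.5  # fraction of each PRF period that is on
    inter_stimulus_interval: float = 0.0  # s of silence between bursts
    repetition_frequency: float | None = None  # Hz; overrides ISI if set
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.peak_pressure < 0:
            raise ValueError("peak_pressure must be >= 0")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must lie in (0, 1]")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        if self.pulse_repetition_frequency > 0 and (
            self.burst_duration < 1.0 / self.pulse_repetition_frequency
        ):
            raise ValueError(
                "burst_duration must cover at least one pulse-repetition period"
            )
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def burst_period(self) -> float | None:
        """Burst-to-burst period in s, or None for a single burst."""
        if self.repetition_frequency:
            return 1.0 / self.repetition_frequency
        if self.inter_stimulus_interval > 0:
            return self.burst_duration + self.inter_stimulus_interval
        return None


@dataclass(frozen=True)
class FieldGrid:
    """Rectilinear grid of field points; axes in metres, strictly increasing.

    Axes may be singletons, e.g. a lateral line ``(x, [0], [z0])`` or the
    beam axis ``([0], [0], z)``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"axis {name} must be a non-empty 1-D array")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"axis {name} must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    def spacing(self, axis: str) -> float:
        ax = getattr(self, axis)
        if ax.size < 2:
            raise ValueError(f"axis {axis} is a singleton; spacing undefined")
        return float(ax[1] - ax[0])

    def points(self) -> np.ndarray:
        """All grid nodes as an (N, 3) array in x-fastest-last C order."""
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass
class PressureField:
    """Complex monochromatic pressure amplitude on a :class:`FieldGrid`."""

    grid: FieldGrid
    amplitude: np.ndarray  # complex, shape grid.shape, Pa
    frequency: float  # Hz

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude)
        if self.amplitude.shape != self.grid.shape:
            raise ValueError(
                f"amplitude shape {self.amplitude.shape} does not match grid "
                f"shape {self.grid.shape}"
            )

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude)

    @property
    def max_pressure(self) -> float:
        return float(np.nanmax(self.magnitude))

    def scaled(self, factor: float) -> "PressureField":
        """Linearly rescaled copy (fields scale with source amplitude)."""
        return PressureField(self.grid, self.amplitude * factor, self.frequency)


@dataclass(frozen=True)
class BeamMetrics:
    """Focal-spot summary of a pressure field."""

    lateral_fwhm: float  # m
    axial_fwhm: float  # m
    peak_depth: float  # m from the apex of the cap
    peak_pressure: float  # Pa


def _onaxis_complex(
    transducer: TransducerSpec, medium: AcousticMedium, depths: np.ndarray
) -> np.ndarray:
    """Complex on-axis pressure (apex origin) for a focusing bowl.

    O'Neil's closed form ``p0/(1 - z/R) * (e^{ikz} - e^{ik r_b})`` where
    ``r_b`` is the distance from the axial point to the rim of the bowl; the
    removable singularity at the geometric focus is replaced by its limit
    ``i k h p0 e^{ikR}`` (``h`` the cap depth).
    """
    z = np.asarray(depths, dtype=float)
    R = transducer.radius_of_curvature
    a = transducer.aperture_radius
    h = transducer.cap_depth
    k = medium.wavenumber(transducer.center_frequency)
    p0 = transducer.source_amplitude

    rb = np.sqrt(a**2 + (z - h) ** 2)
    u = 1.0 - z / R
    with np.errstate(divide="ignore", invalid="ignore"):
        p = p0 / u * (np.exp(1j * k * z) - np.exp(1j * k * rb))
    near_focus = np.abs(u) < 1e-12
    if np.any(near_focus):
        p = np.where(near_focus, p0 * 1j * k * h * np.exp(1j * k * R), p)
    return p


def onaxis_pressure(
    transducer: TransducerSpec,
    medium: AcousticMedium,
    depths: np.ndarray | list[float],
) -> np.ndarray:
    """On-axis pressure amplitude (Pa) at ``depths`` (m from the apex).

    Exact in the lossless limit; with attenuation, each interfering ray is
    damped over its own path length (complex wavenumber).  The geometric
    focus is handled by the closed form's limit value.
    """
    z = np.asarray(depths, dtype=float)
    if np.any(z <= 0):
        raise ValueError("depths must be positive (z=0 is the apex of the cap)")
    return np.abs(_onaxis_complex(transducer, medium, z))


def _check_pitch(transducer: TransducerSpec, medium: AcousticMedium, pitch: float) -> None:
    lam = transducer.wavelength(medium)
    if pitch > lam / 2:
        raise ValueError(
            f"cap element pitch {pitch:.3g} m exceeds lambda/2 = {lam / 2:.3g} m; "
            "the discretised integral would alias"
        )


def _inside_cap_mask(transducer: TransducerSpec, pts: np.ndarray) -> np.ndarray:
    """True for points lying inside the concave bowl volume (invalid nodes)."""
    R = transducer.radius_of_curvature
    rlat = np.hypot(pts[:, 0], pts[:, 1])
    inside_aperture = rlat < transducer.aperture_radius
    zcap = np.where(inside_aperture, R - np.sqrt(np.maximum(R**2 - rlat**2, 0.0)), -np.inf)
    return inside_aperture & (pts[:, 2] < zcap)


def rayleigh_field(
    transducer: TransducerSpec,
    medium: AcousticMedium,
    grid: FieldGrid,
    *,
    element_pitch: float | None = None,
) -> PressureField:
    """Numerical Rayleigh surface integral of the cap on a grid.

    The cap is tiled into point sources at ``element_pitch`` (default
    lambda/6; refused above lambda/2).  Grid nodes inside the bowl volume are
    flagged invalid (NaN) with a warning.

    On the beam axis this agrees with :func:`onaxis_pressure` to well under
    1% near the focus once the pitch is sub-wavelength.
    """
    lam = transducer.wavelength(medium)
    pitch = lam / 6.0 if element_pitch is None else float(element_pitch)
    _check_pitch(transducer, medium, pitch)

    sources, areas = cap_point_sources(
        transducer.radius_of_curvature, transducer.aperture_radius, pitch
    )
    pts = grid.points()
    invalid = _inside_cap_mask(transducer, pts)
    k = medium.wavenumber(transducer.center_frequency)
    k_real = 2.0 * np.pi * transducer.center_frequency / medium.sound_speed
    prefactor = -1j * k_real * transducer.source_amplitude / (2.0 * np.pi)
    amp = field_at_points(pts, sources, areas, k) * prefactor
    if np.any(invalid):
        warnings.warn(
            f"{int(invalid.sum())} grid node(s) lie inside the transducer cap; "
            "flagged as NaN",
            stacklevel=2,
        )
        amp[invalid] = np.nan
    return PressureField(grid, amp.reshape(grid.shape), transducer.center_frequency)


def axisymmetric_pressure_map(
    transducer: TransducerSpec,
    medium: AcousticMedium,
    r: np.ndarray,
    z: np.ndarray,
    *,
    element_pitch: float | None = None,
) -> np.ndarray:
    """|p| (Pa) on an axisymmetric half-plane grid, shape ``(r.size, z.size)``.

    Fast path for transverse profiles and heating maps: the source is
    axisymmetric, so the field only depends on (radial distance, depth).
    ``r`` need not be uniformly spaced — sample finely near the axis where
    the focal spot lives and coarsely outside.
    """
    lam = transducer.wavelength(medium)
    pitch = lam / 6.0 if element_pitch is None else float(element_pitch)
    _check_pitch(transducer, medium, pitch)
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    sources, areas = cap_point_sources(
        transducer.radius_of_curvature, transducer.aperture_radius, pitch
    )
    R, Z = np.meshgrid(r, z, indexing="ij")
    pts = np.column_stack([R.ravel(), np.zeros(R.size), Z.ravel()])
    k = medium.wavenumber(transducer.center_frequency)
    k_real = 2.0 * np.pi * transducer.center_frequency / medium.sound_speed
    prefactor = -1j * k_real * transducer.source_amplitude / (2.0 * np.pi)
    amp = field_at_points(pts, sources, areas, k) * prefactor
    return np.abs(amp).reshape(r.size, z.size)


def revolve_pressure_map(
    r: np.ndarray,
    z: np.ndarray,
    pmap: np.ndarray,
    grid: FieldGrid,
    *,
    frequency: float = float("nan"),
) -> PressureField:
    """Revolve an axisymmetric |p|(r, z) map onto a 3-D Cartesian grid.

    Linear interpolation in (r, z); points beyond the sampled radius are
    zero-filled.  The returned field is real-valued (magnitude only), which
    is what the thermal source term consumes.
    """
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator(
        (np.asarray(r, float), np.asarray(z, float)),
        np.asarray(pmap, float),
        bounds_error=False,
        fill_value=0.0,
    )
    X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    rad = np.hypot(X, Y)
    vals = itp(np.column_stack([rad.ravel(), Z.ravel()])).reshape(grid.shape)
    return PressureField(grid, vals.astype(complex), frequency=frequency)


def profile_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled profile.

    Crossings are located by linear interpolation between the grid nodes;
    walking outward from the peak through any flat run exactly at the half
    level resolves plateau ties to the outermost crossing.  Raises if the
    profile does not fall below half maximum on both sides.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("profile needs matching 1-D arrays of length >= 3")
    i = int(np.nanargmax(y))
    half = y[i] / 2.0

    def _cross(indices: range) -> float:
        for j in indices:
            if y[j] < half:
                j_in = j + (1 if j < i else -1)  # neighbour toward the peak
                return float(
                    x[j] + (half - y[j]) * (x[j_in] - x[j]) / (y[j_in] - y[j])
                )
        raise ValueError("profile does not fall below half maximum; widen the grid")

    left = _cross(range(i - 1, -1, -1))
    right = _cross(range(i + 1, x.size))
    return right - left


def _refined_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Parabolic refinement of the sampled argmax (position, value)."""
    i = int(np.nanargmax(y))
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dx = x[i + 1] - x[i]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def beam_metrics(field: PressureField) -> BeamMetrics:
    """Extract :class:`BeamMetrics` from a simulated field.

    The lateral profile is taken along ``x`` through the global peak, the
    axial profile along ``z``; the peak must lie strictly inside the grid
    along both axes (otherwise the grid is too small and an error is raised).
    """
    mag = field.magnitude
    if np.any(np.isnan(mag)):
        raise ValueError("field contains invalid (NaN) nodes")
    idx = np.unravel_index(np.argmax(mag), mag.shape)
    g = field.grid
    for axis, i in zip("xyz", idx):
        ax = getattr(g, axis)
        if ax.size > 1 and (i == 0 or i == ax.size - 1):
            raise ValueError(
                f"field maximum lies on the {axis} boundary; enlarge the grid"
            )
    lateral = mag[:, idx[1], idx[2]]
    axial = mag[idx[0], idx[1], :]
    if g.x.size < 3 or g.z.size < 3:
        raise ValueError("grid needs >= 3 points along x and z for beam metrics")
    peak_depth, peak_p = _refined_peak(g.z, axial)
    return BeamMetrics(
        lateral_fwhm=profile_fwhm(g.x, lateral),
        axial_fwhm=profile_fwhm(g.z, axial),
        peak_depth=peak_depth,
        peak_pressure=peak_p,
    )


def characterize_beam(
    transducer: TransducerSpec,
    medium: AcousticMedium = WATER,
    *,
    element_pitch: float | None = None,
    axial_span: tuple[float, float] | None = None,
    n_axial: int = 4001,
    lateral_halfwidth: float | None = None,
    n_lateral: int = 481,
) -> tuple[BeamMetrics, dict[str, np.ndarray]]:
    """Beam metrics of a focused transducer, resolved about its focal spot.

    Axial quantities (peak depth, axial FWHM, peak pressure) come from the
    closed-form on-axis solution sampled densely over ``axial_span`` (default
    5% to 200% of the radius of curvature); the lateral FWHM comes from a
    Rayleigh-integral transverse profile through the axial peak, computed on
    the axisymmetric fast path.  Returns the metrics and the raw profiles.
    """
    R = transducer.radius_of_curvature
    lam = transducer.wavelength(medium)
    lo, hi = axial_span if axial_span is not None else (0.05 * R, 2.0 * R)
    z = np.linspace(lo, hi, n_axial)
    pax = onaxis_pressure(transducer, medium, z)
    peak_depth, peak_p = _refined_peak(z, pax)
    axial_fwhm = profile_fwhm(z, pax)

    if lateral_halfwidth is None:
        # ~3x the diffraction-limited FWHM estimate 1.41 * lambda * F#
        lateral_halfwidth = 3.0 * 1.41 * lam * transducer.f_number
    x = np.linspace(0.0, lateral_halfwidth, (n_lateral + 1) // 2)
    prof_half = axisymmetric_pressure_map(
        transducer, medium, x, np.array([peak_depth]), element_pitch=element_pitch
    )[:, 0]
    x_full = np.concatenate([-x[:0:-1], x])
    prof_full = np.concatenate([prof_half[:0:-1], prof_half])
    lateral_fwhm = profile_fwhm(x_full, prof_full)
    metrics = BeamMetrics(
        lateral_fwhm=lateral_fwhm,
        axial_fwhm=axial_fwhm,
        peak_depth=peak_depth,
        peak_pressure=peak_p,
    )
    profiles = {
        "z": z,
        "onaxis_pressure": pax,
        "x": x_full,
        "lateral_pressure": prof_full,
    }
    return metrics, profiles


def calibrate_amplitude(
    transducer: TransducerSpec,
    medium: AcousticMedium,
    target_focal_pressure: float,
) -> float:
    """Source amplitude (Pa) whose simulated peak pressure equals the target.

    Exact by linearity: the field is simulated once at unit amplitude and the
    ratio returned; no iteration.
    """
    if target_focal_pressure < 0:
        raise ValueError("target_focal_pressure must be >= 0")
    if target_focal_pressure == 0:
        return 0.0
    unit = transducer.with_amplitude(1.0)
    R = unit.radius_of_curvature
    z = np.linspace(0.05 * R, 2.0 * R, 4001)
    peak = float(np.max(onaxis_pressure(unit, medium, z)))
    return target_focal_pressure / peak


def exposure_metrics(
    stimulus: USStimulus,
    medium: AcousticMedium | None = None,
    *,
    density: float | None = None,
    isppa_sound_speed: float | None = None,
    isptp_sound_speed: float | None = None,
    averaging_period: float | None = None,
) -> Mapping[str, float]:
    """Plane-wave exposure intensities (W/cm^2) for a pulsed stimulus.

    ``isppa`` is the pulse-average intensity ``p^2/(2 rho c)`` over the on
    portion of the burst; ``isptp`` the temporal-peak intensity (same plane
    wave formula, conventionally back-calculated with the water sound speed);
    ``ispta`` the temporal average ``isppa * duty * burst/period`` over
    ``averaging_period`` (default: the stimulus burst period).  A
    non-repeating stimulus with no explicit averaging period has no time
    base, so its ispta is NaN; an explicit non-positive period raises.

    The two sound-speed conventions are deliberately independent parameters;
    when a ``medium`` is passed its sound speed is used for both unless
    overridden.
    """
    rho = density if density is not None else (medium.density if medium else 1000.0)
    c_ppa = (
        isppa_sound_speed
        if isppa_sound_speed is not None
        else (medium.sound_speed if medium else ISPPA_SOUND_SPEED)
    )
    c_ptp = (
        isptp_sound_speed
        if isptp_sound_speed is not None
        else (medium.sound_speed if medium else ISPTP_SOUND_SPEED)
    )
    p = stimulus.peak_pressure
    isppa = p**2 / (2.0 * rho * c_ppa) / 1e4
    isptp = p**2 / (2.0 * rho * c_ptp) / 1e4

    period = averaging_period
    if period is None:
        period = stimulus.burst_period
    if period is not None and period <= 0:
        raise ValueError("averaging period must be positive")
    if period is None:
        ispta = float("nan")  # single burst, no time base given
    else:
        on_fraction = min(stimulus.burst_duration, period) / period
        ispta = isppa * stimulus.duty_cycle * on_fraction
    return {"isppa": isppa, "ispta": ispta, "isptp": isptp}
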