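"""Point-source discretisation of a spherical cap and the field summation.

The cap (radius of curvature R, aperture radius a, apex at the origin,
axis along +z) is tiled into rings of constant polar angle, each ring split
azimuthally so that the element pitch never exceeds the requested value.
Element areas are exact spherical band areas, so they sum to the true cap
area 2*pi*R*h.

The O(N_points x N_sources) summation is the hot loop of the package; it is
compiled with numba when available and falls back to chunked numpy.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def cap_point_sources(
    radius_of_curvature: float, aperture_radius: float, pitch: float
) -> tuple[np.ndarray, np.ndarray]:
    """Tile the cap into point sources at most ``pitch`` apart.

    Returns ``(sources, areas)``: an (N, 3) array of element centres (m) and
    the (N,) element areas (m^2).
    """
    R = float(radius_of_curvature)
    a = float(aperture_radius)
    if not 0 < a < R:
        raise ValueError("aperture radius must lie in (0, radius_of_curvature)")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    theta_max = np.arcsin(a / R)
    n_rings = max(1, int(np.ceil(R * theta_max / pitch)))
    edges = np.linspace(0.0, theta_max, n_rings + 1)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        tm = 0.5 * (t0 + t1)
        ring_r = R * np.sin(tm)
        ring_z = R * (1.0 - np.cos(tm))
        band_area = 2.0 * np.pi * R**2 * (np.cos(t0) - np.cos(t1))
        n_phi = max(1, int(np.ceil(2.0 * np.pi * ring_r / pitch)))
        phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
        xs.append(ring_r * np.cos(phi))
        ys.append(ring_r * np.sin(phi))
        zs.append(np.full(n_phi, ring_z))
        areas.append(np.full(n_phi, band_area / n_phi))
    sources = np.column_stack(
        [np.concatenate(xs), np.concatenate(ys), np.concatenate(zs)]
    )
    return sources, np.concatenate(areas)


def _field_numpy(
    points: np.ndarray, sources: np.ndarray, areas: np.ndarray, k: complex
) -> np.ndarray:
    out = np.empty(points.shape[0], dtype=complex)
    # chunk over field points to bound the (chunk x sources) temporaries
    chunk = max(1, int(4e6 // max(sources.shape[0], 1)) or 1)
    for i0 in range(0, points.shape[0], chunk):
        p = points[i0 : i0 + chunk]
        d = p[:, None, :] - sources[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        out[i0 : i0 + chunk] = np.sum(areas * np.exp(1j * k * r) / r, axis=1)
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _field_numba(points, sx, sy, sz, areas, k_re, k_im):  # pragma: no cover
        n = points.shape[0]
        m = sx.shape[0]
        out = np.empty(n, dtype=np.complex128)
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            acc_re = 0.0
            acc_im = 0.0
            for j in range(m):
                dx = px - sx[j]
                dy = py - sy[j]
                dz = pz - sz[j]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                amp = areas[j] * np.exp(-k_im * r) / r
                ph = k_re * r
                acc_re += amp * np.cos(ph)
                acc_im += amp * np.sin(ph)
            out[i] = complex(acc_re, acc_im)
        return out


def field_at_points(
    points: np.ndarray, sources: np.ndarray, areas: np.ndarray, k: complex
) -> np.ndarray:
    """``sum_j area_j * exp(i k r_ij) / r_ij`` for every field point i."""
    points = np.ascontiguousarray(points, dtype=float)
    if _HAVE_NUMBA:
        return _field_numba(
            points,
            np.ascontiguousarray(sources[:, 0]),
            np.ascontiguousarray(sources[:, 1]),
            np.ascontiguousarray(sources[:, 2]),
            np.ascontiguousarray(areas),
            float(np.real(k)),
            float(np.imag(k)),
        )
    return _field_numpy(points, sources, areas, complex(k))
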