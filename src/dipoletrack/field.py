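"""Forward model: 2-D ideal-dipole potentials and differential responses.

A fish in shallow water is modeled as a pair of opposite current sources in
two dimensions (vertical electrodes average the field over depth, so the
problem is effectively planar). In 2-D a line source has a logarithmic
potential, so the exact two-source potential is

    V(P) = c * ln(r_minus / r_plus),

with r_plus/r_minus the distances from P to the positive/negative source and
c the source-strength constant. When the source separation d is small
compared to the distance R from the dipole center, this reduces to the ideal
2-D dipole form

    V(P) ≈ m * cos(phi) / R,      m = c * d,

where phi is the angle between the dipole axis and the vector to P. The
circular tank wall adds an image dipole outside the boundary which, for
electrodes placed on the wall, simply rescales every differential voltage by
a common factor (1 + k); k depends only on the permittivity contrast and
therefore cancels under the normalization used by the inverse search.

The 3-D image-charge machinery for the air/water and water/glass interfaces
(`image_series_potential`, `vertical_electrode_potential`) is a validation
utility only; the localization path always uses the 2-D model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import DipoleState, ElectrodeArray, RSIVector, TankGeometry

__all__ = [
    "boundary_scale",
    "potential_exact",
    "potential_ideal",
    "channel_response",
    "response_matrix",
    "image_series_potential",
    "vertical_electrode_potential",
    "SingularPointError",
]

#: Default source separation for the exact two-source form, cm (about half a
#: fish body length). Only the approximation-error study depends on it.
DEFAULT_SEPARATION = 10.0


class SingularPointError(ValueError):
    """Raised when a potential is evaluated at a source location."""


def boundary_scale(tank: TankGeometry) -> float:
    """Dimensionless factor k of the circular side boundary.

    The image dipole induced by the wall contributes k times the direct
    dipole potential at every wall electrode, so differential voltages are
    rescaled by (1 + k). With permittivity ratio rho = eps_water / eps_wall,

        k = (rho - 1) / (rho + 1).

    k = 0 when the wall is electrically identical to water, and its sign
    follows the sign of (rho - 1).
    """
    rho = tank.boundary_contrast
    return (rho - 1.0) / (rho + 1.0)


def potential_exact(
    dipole: DipoleState,
    point: Sequence[float],
    d: float = DEFAULT_SEPARATION,
) -> float:
    """Exact 2-D two-source potential at ``point``.

    The positive and negative sources sit at ±d/2 along the heading; the
    proportionality constant is c = moment / d so that the far field matches
    `potential_ideal` with the same moment.
    """
    p = np.asarray(point, dtype=float)
    half = dipole.heading * (d / 2.0)
    r_plus = np.linalg.norm(p - (dipole.position + half))
    r_minus = np.linalg.norm(p - (dipole.position - half))
    if r_plus == 0.0 or r_minus == 0.0:
        raise SingularPointError("field point coincides with a source")
    c = dipole.moment / d
    return float(c * np.log(r_minus / r_plus))


def potential_ideal(dipole: DipoleState, point: Sequence[float]) -> float:
    """Ideal 2-D dipole potential m * cos(phi) / R at ``point``."""
    p = np.asarray(point, dtype=float)
    rvec = p - dipole.position
    r2 = rvec @ rvec
    if r2 == 0.0:
        raise SingularPointError("field point coincides with the dipole center")
    return float(dipole.moment * (dipole.heading @ rvec) / r2)


def response_matrix(
    states: np.ndarray,
    array: ElectrodeArray,
    tank: TankGeometry,
    moment: float = 1.0,
    on_singular: str = "raise",
) -> np.ndarray:
    """Vectorized differential responses for many dipole states.

    Parameters
    ----------
    states : (n, 3) array
        Columns x (cm), y (cm), theta (deg).
    on_singular : {"raise", "zero"}
        A state whose center coincides with an electrode is singular;
        "zero" silently returns an all-zero row for it (used by grid
        builders, which treat zero rows as invalid candidates).

    Returns
    -------
    (n, n_channels) array of boundary-rescaled differential voltages
    (1 + k) * (V_ideal(pos electrode) - V_ideal(neg electrode)).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    x = states[:, 0:1]
    y = states[:, 1:2]
    t = np.radians(states[:, 2:3])
    ux, uy = np.cos(t), np.sin(t)

    out = np.empty((states.shape[0], array.n_channels), dtype=float)
    singular = np.zeros(states.shape[0], dtype=bool)
    scale = (1.0 + boundary_scale(tank)) * moment
    for electrodes, sign in ((array.pos, 1.0), (array.neg, -1.0)):
        dx = electrodes[None, :, 0] - x
        dy = electrodes[None, :, 1] - y
        r2 = dx * dx + dy * dy
        bad = r2 == 0.0
        if np.any(bad):
            if on_singular == "raise":
                raise SingularPointError(
                    "dipole center coincides with an electrode"
                )
            singular |= bad.any(axis=1)
            r2 = np.where(bad, 1.0, r2)
        v = (ux * dx + uy * dy) / r2
        if sign > 0:
            out[:] = v
        else:
            out -= v
    out *= scale
    if singular.any():
        out[singular] = 0.0
    return out


def channel_response(
    dipole: DipoleState, array: ElectrodeArray, tank: TankGeometry
) -> RSIVector:
    """Predicted RSI vector (one value per differential channel)."""
    vals = response_matrix(
        dipole.as_array()[None, :], array, tank, moment=dipole.moment
    )[0]
    return RSIVector(values=vals, pulse_time=dipole.time)


# ---------------------------------------------------------------------------
# 3-D shallow-water validation utilities (method of image charges)
# ---------------------------------------------------------------------------


def _image_stack(z0: float, depth: float, k_top: float, k_bottom: float,
                 n_reflections: int) -> tuple[np.ndarray, np.ndarray]:
    """Image-source heights and strengths for a point source between the
    bottom (z=0, water/glass) and top (z=depth, air/water) interfaces.

    Reflection order n contributes two images; each successive reflection is
    weaker (factor k) and farther away, so the series converges for |k| < 1.
    """
    if n_reflections == 0:
        return np.array([z0]), np.array([1.0])
    zs = [z0]
    ss = [1.0]
    # Two reflection chains, one starting at each interface. A chain
    # alternates interfaces; `at_top` marks where the last reflection was.
    for k_first, z_first, at_top in (
        (k_bottom, -z0, False),
        (k_top, 2.0 * depth - z0, True),
    ):
        z, s = z_first, k_first
        zs.append(z)
        ss.append(s)
        for _ in range(n_reflections - 1):
            if at_top:
                z, s = -z, s * k_bottom
            else:
                z, s = 2.0 * depth - z, s * k_top
            at_top = not at_top
            zs.append(z)
            ss.append(s)
    return np.asarray(zs), np.asarray(ss)


def image_series_potential(
    source: Sequence[float],
    tank: TankGeometry,
    point: Sequence[float],
    n_reflections: int,
    strength: float = 1.0,
    eps_water: float = 80.0,
    eps_air: float = 1.0,
    eps_bottom: float = 4.7,
) -> float:
    """Partial sum of the image-current series for a 3-D point source.

    ``source`` and ``point`` are (x, y, z) with 0 < z < water_depth for the
    source. Reflection coefficients at the top (air/water) and bottom
    (water/glass) interfaces follow the permittivity contrasts,
    k = (eps_water - eps_other) / (eps_water + eps_other).
    """
    sx, sy, sz = (float(v) for v in source)
    px, py, pz = (float(v) for v in point)
    depth = tank.water_depth
    if not (0.0 < sz < depth):
        raise ValueError("source height must lie strictly inside the water column")
    if n_reflections < 0:
        raise ValueError("n_reflections must be >= 0")
    k_top = (eps_water - eps_air) / (eps_water + eps_air)
    k_bottom = (eps_water - eps_bottom) / (eps_water + eps_bottom)
    zs, ss = _image_stack(sz, depth, k_top, k_bottom, n_reflections)
    r = np.sqrt((px - sx) ** 2 + (py - sy) ** 2 + (pz - zs) ** 2)
    if np.any(r == 0.0):
        raise SingularPointError("field point coincides with a source or image")
    return float(strength * np.sum(ss / r))


def vertical_electrode_potential(
    source: Sequence[float],
    tank: TankGeometry,
    point_xy: Sequence[float],
    n_reflections: int = 60,
    n_z: int = 21,
    **kwargs,
) -> float:
    """Depth-averaged potential seen by a vertical electrode.

    Averages the image-series potential over ``n_z`` heights spanning the
    water column at the lateral electrode location. In the far field this
    is linear in 1/R, i.e. it recovers the distance scaling assumed by the
    2-D model.
    """
    heights = np.linspace(0.0, tank.water_depth, n_z)
    # Keep evaluation points strictly inside the column to avoid grazing an
    # interface image exactly.
    heights = np.clip(heights, 1e-6, tank.water_depth - 1e-6)
    px, py = (float(v) for v in point_xy)
    vals = [
        image_series_potential(source, tank, (px, py, h), n_reflections, **kwargs)
        for h in heights
    ]
    return float(np.mean(vals))
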