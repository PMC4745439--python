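"""Tapered overlapping-stenosis wall geometry.

The arterial wall is a rigid surface of revolution ``r = h(z)`` around the
axis of a coaxial catheter of radius ``rc``.  Axial distance is measured in
units of the stenosis length ``L1`` and radii in units of the healthy
nontapered lumen radius ``r0``, so the artery occupies ``0 <= z <= 1/Gamma``
(``Gamma = L1/L``) and the stenosed segment ``gamma <= z <= gamma + 1``
(``gamma = L0/L1``).  Inside the stenosed segment

    h(z) = 1 + zeta*z - (3*eps/2) * (11*u - 47*u**2 + 72*u**3 - 36*u**4),

with ``u = z - gamma``, ``zeta = tan(phi)`` the taper slope and ``eps`` the
stenosis height parameter; outside it ``h(z) = 1 + zeta*z``.  The quartic
bracket vanishes at ``u = 0`` and ``u = 1`` (11 - 47 + 72 - 36 = 0), so the
profile joins the tapered tube continuously.  The two depth maxima and the
central saddle of the overlapping constriction sit at the real roots of

    144*u**3 - 216*u**2 + 94*u - 11 + 2*zeta/(3*eps) = 0.

Note on naming: ``eps`` is conventionally called the "maximum height" of the
stenosis, but the profile's actual depth at the two extremum points is
(3*eps/2) * S(u_L) ~ 1.2605*eps (and 3*eps/4 at the saddle when zeta = 0).
The formula, not the name, is authoritative here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GeometryError",
    "NoStenosisError",
    "DegenerateGeometryError",
    "GeometryParams",
    "ExtremaReport",
    "artery_radius",
    "wall_slope",
    "stenosis_extrema",
]

#: closed-interval tolerance for axial-domain membership checks
_Z_TOL = 1e-12
#: tolerance for accepting a cubic root as lying inside (0, 1)
_ROOT_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid or inconsistent artery/catheter geometry."""


class NoStenosisError(GeometryError):
    """Extrema were requested for a stenosis-free (eps = 0) geometry."""


class DegenerateGeometryError(GeometryError):
    """The taper is too steep for the given stenosis height: the extremum
    cubic no longer has three real roots inside the stenosed segment."""


def _shape(u):
    """Quartic shape factor S(u) = 11u - 47u^2 + 72u^3 - 36u^4 on [0, 1]."""
    return u * (11.0 + u * (-47.0 + u * (72.0 - 36.0 * u)))


def _shape_d1(u):
    return 11.0 + u * (-94.0 + u * (216.0 - 144.0 * u))


def _shape_d2(u):
    return -94.0 + u * (432.0 - 432.0 * u)


@dataclass(frozen=True)
class GeometryParams:
    """Nondimensional geometry of the catheterized, tapered, stenosed artery.

    Parameters
    ----------
    zeta
        Taper slope ``tan(phi)``; negative for a converging artery, positive
        for a diverging one, zero for no taper.
    eps
        Stenosis height parameter (fraction of the healthy radius); ``eps = 0``
        is a plain (tapered) tube.
    gamma
        Axial onset of the stenosed segment, ``L0/L1``.
    Gamma
        Stenosis length fraction ``L1/L`` in ``(0, 1]``; the artery spans
        ``[0, 1/Gamma]``.
    rc
        Catheter radius (fraction of the healthy radius); must stay strictly
        below ``h(z)`` everywhere.
    """

    zeta: float = 0.0
    eps: float = 0.1
    gamma: float = 0.5
    Gamma: float = 0.5
    rc: float = 0.1

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise GeometryError(f"eps must be >= 0, got {self.eps}")
        if not 0.0 < self.Gamma <= 1.0:
            raise GeometryError(f"Gamma must lie in (0, 1], got {self.Gamma}")
        if self.gamma < 0:
            raise GeometryError(f"gamma must be >= 0, got {self.gamma}")
        if self.gamma + 1.0 > 1.0 / self.Gamma + _Z_TOL:
            raise GeometryError(
                "stenosis does not fit inside the artery: "
                f"gamma + 1 = {self.gamma + 1.0} > 1/Gamma = {1.0 / self.Gamma}"
            )
        if self.rc <= 0:
            raise GeometryError(f"rc must be > 0, got {self.rc}")
        hmin = self.min_radius()
        if self.rc >= hmin:
            raise GeometryError(
                f"catheter radius rc = {self.rc} closes the annulus "
                f"(min h = {hmin:.6g})"
            )

    @classmethod
    def from_taper_angle(cls, phi: float, **kwargs) -> "GeometryParams":
        """Build from the taper angle ``phi`` in radians (``zeta = tan(phi)``)."""
        return cls(zeta=math.tan(phi), **kwargs)

    @property
    def length(self) -> float:
        """Total artery length ``1/Gamma`` in units of the stenosis length."""
        return 1.0 / self.Gamma

    def replace(self, **changes) -> "GeometryParams":
        return replace(self, **changes)

    def min_radius(self) -> float:
        """Smallest wall radius over the whole artery.

        The candidates are the domain endpoints, the segment joins, and the
        interior critical points of the stenosed segment (evaluated on a fine
        grid plus the analytic extrema when they exist).
        """
        zs = [0.0, self.gamma, self.gamma + 1.0, 1.0 / self.Gamma]
        grid = np.linspace(self.gamma, self.gamma + 1.0, 513)
        h_grid = _radius_unchecked(grid, self)
        h_cands = [_radius_unchecked(np.asarray(z), self).item() for z in zs]
        return min(min(h_cands), float(h_grid.min()))


def _radius_unchecked(z: np.ndarray, geom: GeometryParams) -> np.ndarray:
    u = z - geom.gamma
    inside = (u >= -_Z_TOL) & (u <= 1.0 + _Z_TOL)
    h = 1.0 + geom.zeta * z
    return np.where(inside, h - 1.5 * geom.eps * _shape(np.clip(u, 0.0, 1.0)), h)


def artery_radius(z, geom: GeometryParams, *, check_annulus: bool = True):
    """Annular (wall) radius ``h(z)``.

    Parameters
    ----------
    z
        Axial position(s) in ``[0, 1/Gamma]``; scalar or array.
    geom
        Geometry parameters.
    check_annulus
        If true (default), raise :class:`GeometryError` when the returned
        radius does not exceed the catheter radius.

    Returns
    -------
    float or ndarray
        ``h(z)``, matching the shape of ``z``.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < -_Z_TOL) or np.any(z_arr > geom.length + _Z_TOL):
        raise GeometryError(
            f"axial position outside [0, {geom.length}]: z = {z}"
        )
    h = _radius_unchecked(z_arr, geom)
    if check_annulus and np.any(h <= geom.rc):
        bad = z_arr[np.atleast_1d(h <= geom.rc)]
        raise GeometryError(
            f"wall meets catheter (h <= rc = {geom.rc}) at z = {bad}"
        )
    return h if z_arr.ndim else float(h)


def wall_slope(z, geom: GeometryParams):
    """Analytic ``dh/dz``; the shape-factor derivative switches off outside
    the stenosed segment."""
    z_arr = np.asarray(z, dtype=float)
    u = z_arr - geom.gamma
    inside = (u >= -_Z_TOL) & (u <= 1.0 + _Z_TOL)
    dh = np.full_like(z_arr, geom.zeta, dtype=float)
    dh = np.where(
        inside, geom.zeta - 1.5 * geom.eps * _shape_d1(np.clip(u, 0.0, 1.0)), dh
    )
    return dh if z_arr.ndim else float(dh)


@dataclass(frozen=True)
class ExtremaReport:
    """Locations and radii of the two depth maxima and the central saddle.

    ``gamma < zL < zC < zR < gamma + 1`` always; for a nontapered artery the
    report is symmetric: ``zL + zR = 2 zC`` and ``hL = hR``.
    """

    zL: float
    zC: float
    zR: float
    hL: float
    hC: float
    hR: float

    @property
    def locations(self) -> tuple[float, float, float]:
        return (self.zL, self.zC, self.zR)

    @property
    def radii(self) -> tuple[float, float, float]:
        return (self.hL, self.hC, self.hR)

    def as_dict(self) -> dict[str, float]:
        return {
            "zL": self.zL, "zC": self.zC, "zR": self.zR,
            "hL": self.hL, "hC": self.hC, "hR": self.hR,
        }


def stenosis_extrema(geom: GeometryParams) -> ExtremaReport:
    """Locate the stenosis extrema by solving the extremum cubic.

    Solves ``144 u^3 - 216 u^2 + 94 u - 11 + 2*zeta/(3*eps) = 0`` via the
    companion-matrix eigenvalues of ``numpy.roots`` and polishes each real
    root with Newton iterations on the analytic ``dh/dz``.

    Raises
    ------
    NoStenosisError
        If ``eps == 0`` (the cubic's constant term is singular).
    DegenerateGeometryError
        If fewer than three real roots fall inside ``(0, 1)`` — the taper is
        too steep for the given stenosis height.
    """
    if geom.eps == 0:
        raise NoStenosisError(
            "eps = 0: a stenosis-free tube has no extremum cubic"
        )
    const = -11.0 + 2.0 * geom.zeta / (3.0 * geom.eps)
    roots = np.roots([144.0, -216.0, 94.0, const])
    real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    real = real[(real > _ROOT_TOL) & (real < 1.0 - _ROOT_TOL)]
    if real.size != 3:
        raise DegenerateGeometryError(
            f"expected 3 extrema in (0, 1), found {real.size} "
            f"(zeta = {geom.zeta}, eps = {geom.eps})"
        )
    polished = [_newton_polish(u, geom) for u in real]
    zs = [geom.gamma + u for u in polished]
    hs = [artery_radius(z, geom) for z in zs]
    return ExtremaReport(zs[0], zs[1], zs[2], hs[0], hs[1], hs[2])


def _newton_polish(u: float, geom: GeometryParams, tol: float = 1e-12) -> float:
    # dh/dz = zeta - (3 eps/2) S'(u); zero of this is the extremum
    for _ in range(50):
        f = geom.zeta - 1.5 * geom.eps * _shape_d1(u)
        df = -1.5 * geom.eps * _shape_d2(u)
        if df == 0.0:
            break
        step = f / df
        u -= step
        if abs(step) < tol:
            break
    return min(max(u, 0.0), 1.0)
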