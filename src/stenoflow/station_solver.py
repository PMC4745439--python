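"""Micropolar annular-flow boundary-value problem at one axial station.

At a fixed axial station the lubrication-order balance laws for a micropolar
(Eringen polar) fluid in the annulus ``rc <= r <= h`` reduce, for a constant
axial pressure gradient ``P = dp/dz``, to

    P = [N/(1-N)] (1/r) d(r nu)/dr + [1/(1-N)] (1/r) d(r dv/dr)/dr
    2 nu = -dv/dr + [(2-N)/m^2] d/dr[(1/r) d(r nu)/dr]

for the axial velocity ``v(r)`` and microrotation ``nu(r)``.  The general
solution is

    nu(r) = c2 I1(m r) + c3 K1(m r) - b (c1/r + r/2) P
    v(r)  = (N/m)(-c2 I0(m r) + c3 K0(m r))
            + 2 b (c1 ln r + r^2/4) P + c4,            b = (1-N)/(2-N)

with modified Bessel functions I, K.  The four constants follow from the
no-slip/no-spin conditions on the catheter, ``v(rc) = 0``, ``nu(rc) = 0``, and
the slip/no-spin conditions on the wall, ``v(h) = u``, ``nu(h) = 0``.

Scaled representation
---------------------
For physiological ``m`` (tens) ``I1(m h)`` overflows double precision long
before it loses accuracy, so the linear system is assembled with the
exponentially scaled Bessel functions ``ive``/``kve`` and the constants are
stored in a scaled basis::

    c = (k1, c2s, c3s, c4)   with   c2 = c2s * exp(-m h),
                                    c3 = c3s * exp(+m rc),
                                    k1 = c1 * P.

Every downstream expression combines only like-scaled products
``c2s * I(m r) e^{m(r-h)}`` and ``c3s * K(m r) e^{m(rc-r)}``, whose
exponentials never exceed one inside the annulus.  Absorbing ``P`` into the
first constant makes the basis linear in ``(P, u)`` jointly, so superposition
``c(P, u) = P c(1, 0) + u c(0, 1)`` holds componentwise and the pure-slip
sub-problem (``P = 0``) is nondegenerate.

The station flux splits affinely as ``Q = A P + B u`` with closed-form
coefficients from the termwise antiderivatives of ``2 r v(r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ive, kve

__all__ = [
    "FluidParams",
    "StationSolution",
    "ConditioningError",
    "solve_constants",
    "solve_station",
    "axial_velocity",
    "microrotation",
    "velocity_gradient",
    "wall_velocity_gradient",
    "flux_coefficients",
    "station_flux",
]

#: condition-number ceiling for the 4x4 boundary matrix
_COND_MAX = 1e12


class ConditioningError(RuntimeError):
    """Boundary matrix too ill-conditioned to trust (e.g. rc -> h)."""

    def __init__(self, cond: float, h: float, rc: float):
        self.cond = cond
        super().__init__(
            f"boundary matrix condition estimate {cond:.3e} exceeds "
            f"{_COND_MAX:.0e} (h = {h}, rc = {rc})"
        )


@dataclass(frozen=True)
class FluidParams:
    """Micropolar material state: the only two surviving fluid constants.

    ``N = kappa/(mu + kappa)`` is the coupling number, the strength of the
    microrotation-velocity coupling (``0 <= N < 1``; ``N -> 0`` recovers a
    Newtonian fluid).  ``m`` sets the microrotation boundary-layer scale
    (large ``m`` means thin layers, weak micropolar effects).
    """

    N: float = 0.75
    m: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.N < 1.0:
            raise ValueError(f"coupling number N must lie in [0, 1), got {self.N}")
        if self.m <= 0:
            raise ValueError(f"micropolar parameter m must be > 0, got {self.m}")

    @property
    def b(self) -> float:
        """The recurring combination (1 - N)/(2 - N)."""
        return (1.0 - self.N) / (2.0 - self.N)

    def replace(self, **changes) -> "FluidParams":
        return replace(self, **changes)


def _iscaled(n: int, r, m: float, h: float):
    """I_n(m r) * exp(-m h), finite for all r in [rc, h]."""
    return ive(n, m * r) * np.exp(m * (r - h))


def _kscaled(n: int, r, m: float, rc: float):
    """K_n(m r) * exp(+m rc), finite for all r in [rc, h]."""
    return kve(n, m * r) * np.exp(m * (rc - r))


def _boundary_matrix(h: float, rc: float, fluid: FluidParams) -> np.ndarray:
    N, m, b = fluid.N, fluid.m, fluid.b
    rows = []
    for r in (h, rc):  # nu(r) = 0
        rows.append([-b / r, _iscaled(1, r, m, h), _kscaled(1, r, m, rc), 0.0])
    for r in (h, rc):  # v(r) = boundary value
        rows.append(
            [2.0 * b * np.log(r), -(N / m) * _iscaled(0, r, m, h),
             (N / m) * _kscaled(0, r, m, rc), 1.0]
        )
    return np.array(rows)


def _rhs(h: float, rc: float, fluid: FluidParams, dpdz: float, u: float) -> np.ndarray:
    b = fluid.b
    return np.array([
        b * h / 2.0 * dpdz,
        b * rc / 2.0 * dpdz,
        u - 2.0 * b * h * h / 4.0 * dpdz,
        -2.0 * b * rc * rc / 4.0 * dpdz,
    ])


def solve_constants(h: float, rc: float, fluid: FluidParams,
                    dpdz: float, u: float) -> np.ndarray:
    """Integration constants ``(k1, c2s, c3s, c4)`` in the scaled basis.

    The four boundary conditions ``nu(h) = nu(rc) = 0``, ``v(h) = u``,
    ``v(rc) = 0`` are imposed exactly (direct dense solve with partial
    pivoting).  The result is linear in ``(dpdz, u)``.

    Raises
    ------
    ConditioningError
        If the boundary-matrix condition estimate exceeds 1e12.
    ValueError
        If the annulus is empty (``rc >= h``).
    """
    if not 0.0 < rc < h:
        raise ValueError(f"need 0 < rc < h, got rc = {rc}, h = {h}")
    M = _boundary_matrix(h, rc, fluid)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise ConditioningError(cond, h, rc)
    return np.linalg.solve(M, _rhs(h, rc, fluid, dpdz, u))


@dataclass(frozen=True)
class StationSolution:
    """Everything needed to evaluate the flow at one axial station.

    ``cp`` are the scaled constants of the unit-pressure-gradient sub-problem
    (``dpdz = 1, u = 0``), ``cu`` those of the unit-slip sub-problem
    (``dpdz = 0, u = 1``); superposition gives the constants for any flow
    condition.  ``A`` and ``B`` are the affine flux coefficients,
    ``Q = A dpdz + B u``.  ``cond`` is the boundary-matrix condition estimate.
    """

    h: float
    rc: float
    fluid: FluidParams
    cp: np.ndarray
    cu: np.ndarray
    A: float
    B: float
    cond: float

    def constants(self, dpdz: float, u: float) -> np.ndarray:
        """Scaled constants for the given pressure gradient and slip."""
        return self.cp * dpdz + self.cu * u

    def flux(self, dpdz: float, u: float) -> float:
        return self.A * dpdz + self.B * u


def solve_station(h: float, rc: float, fluid: FluidParams) -> StationSolution:
    """Solve both unit sub-problems and the closed-form flux coefficients."""
    if not 0.0 < rc < h:
        raise ValueError(f"need 0 < rc < h, got rc = {rc}, h = {h}")
    M = _boundary_matrix(h, rc, fluid)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise ConditioningError(cond, h, rc)
    rhs = np.column_stack([
        _rhs(h, rc, fluid, 1.0, 0.0),
        _rhs(h, rc, fluid, 0.0, 1.0),
    ])
    sol = np.linalg.solve(M, rhs)
    cp, cu = sol[:, 0].copy(), sol[:, 1].copy()
    A = _flux_closed_form(h, rc, fluid, cp, 1.0)
    B = _flux_closed_form(h, rc, fluid, cu, 0.0)
    return StationSolution(h=h, rc=rc, fluid=fluid, cp=cp, cu=cu,
                           A=A, B=B, cond=cond)


def _check_r(r, station: StationSolution, tol: float = 1e-12):
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < station.rc - tol) or np.any(r_arr > station.h + tol):
        raise ValueError(
            f"r outside annulus [{station.rc}, {station.h}]: r = {r}"
        )
    return r_arr


def axial_velocity(r, station: StationSolution, dpdz: float, u: float):
    """Axial velocity ``v(r)``; satisfies ``v(rc) = 0`` and ``v(h) = u``."""
    r_arr = _check_r(r, station)
    N, m, b = station.fluid.N, station.fluid.m, station.fluid.b
    k1, c2s, c3s, c4 = station.constants(dpdz, u)
    out = (
        (N / m) * (-c2s * _iscaled(0, r_arr, m, station.h)
                   + c3s * _kscaled(0, r_arr, m, station.rc))
        + 2.0 * b * (k1 * np.log(r_arr) + r_arr ** 2 / 4.0 * dpdz)
        + c4
    )
    return out if r_arr.ndim else float(out)


def microrotation(r, station: StationSolution, dpdz: float, u: float):
    """Microrotation ``nu(r)``; vanishes at both walls."""
    r_arr = _check_r(r, station)
    m, b = station.fluid.m, station.fluid.b
    k1, c2s, c3s, _ = station.constants(dpdz, u)
    out = (
        c2s * _iscaled(1, r_arr, m, station.h)
        + c3s * _kscaled(1, r_arr, m, station.rc)
        - b * (k1 / r_arr + r_arr / 2.0 * dpdz)
    )
    return out if r_arr.ndim else float(out)


def velocity_gradient(r, station: StationSolution, dpdz: float, u: float):
    """Analytic ``dv/dr`` (uses I0' = I1, K0' = -K1)."""
    r_arr = _check_r(r, station)
    N, m, b = station.fluid.N, station.fluid.m, station.fluid.b
    k1, c2s, c3s, _ = station.constants(dpdz, u)
    out = (
        -N * (c2s * _iscaled(1, r_arr, m, station.h)
              + c3s * _kscaled(1, r_arr, m, station.rc))
        + 2.0 * b * (k1 / r_arr + r_arr / 2.0 * dpdz)
    )
    return out if r_arr.ndim else float(out)


def wall_velocity_gradient(station: StationSolution, dpdz: float, u: float) -> float:
    """``dv/dr`` evaluated at the arterial wall ``r = h``."""
    return float(velocity_gradient(station.h, station, dpdz, u))


def _flux_closed_form(h: float, rc: float, fluid: FluidParams,
                      c: np.ndarray, dpdz: float) -> float:
    # termwise antiderivatives of 2 r v(r):
    #   int r I0(mr) dr = (r/m) I1(mr),  int r K0(mr) dr = -(r/m) K1(mr),
    #   int r ln r dr = (r^2/2)(ln r - 1/2),  int r^3 dr = r^4/4.
    N, m, b = fluid.N, fluid.m, fluid.b
    k1, c2s, c3s, c4 = c

    def antideriv(r: float) -> float:
        return 2.0 * (
            (N / m) * (-c2s * (r / m) * _iscaled(1, r, m, h)
                       - c3s * (r / m) * _kscaled(1, r, m, rc))
            + 2.0 * b * (k1 * (r * r / 2.0) * (np.log(r) - 0.5)
                         + dpdz * r ** 4 / 16.0)
            + c4 * r * r / 2.0
        )

    return antideriv(h) - antideriv(rc)


def flux_coefficients(h: float, rc: float, fluid: FluidParams) -> tuple[float, float]:
    """Affine flux decomposition ``Q = A dpdz + B u`` for the station.

    ``A`` (pressure-gradient conductance, negative: a negative gradient
    drives positive flux) and ``B`` (slip contribution, positive) come from
    the closed-form antiderivative of ``2 r v(r)`` between ``rc`` and ``h``.
    """
    st = solve_station(h, rc, fluid)
    return st.A, st.B


def station_flux(station: StationSolution, dpdz: float, u: float) -> float:
    """Volumetric flux ``Q = int_rc^h 2 r v(r) dr`` in closed form."""
    return station.flux(dpdz, u)
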