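"""Independent references the test suite (and `stenoflow self-check`) lean on.

Nothing here shares code paths with the main solver: the Newtonian annulus is
the classical closed form, fluxes come from adaptive quadrature of the
velocity profile, extrema come from a brute-force derivative sign scan, and
the optional high-precision re-evaluation rebuilds the station solution with
mpmath's arbitrary-precision Bessel functions.  The oracles are deliberately
slow and simple; they exist to catch silent regressions in the Bessel
scaling and the closed-form antiderivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .geometry import DegenerateGeometryError, GeometryParams, wall_slope
from .station_solver import FluidParams

__all__ = [
    "NewtonianStation",
    "newtonian_annulus_velocity",
    "newtonian_annulus_gradient",
    "newtonian_annulus_flux",
    "quadrature_flux",
    "extrema_scan",
    "highprec_velocity",
    "self_check",
]


@dataclass(frozen=True)
class NewtonianStation:
    """Annular Poiseuille flow with outer-wall slip: the N -> 0 limit."""

    h: float
    rc: float
    dpdz: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rc < self.h:
            raise ValueError(f"need 0 < rc < h, got rc={self.rc}, h={self.h}")

    @property
    def _constants(self) -> tuple[float, float]:
        # v = (dpdz/4) r^2 + C1 ln r + C2, v(rc) = 0, v(h) = u
        C1 = (self.u - self.dpdz * (self.h ** 2 - self.rc ** 2) / 4.0) \
            / math.log(self.h / self.rc)
        C2 = -self.dpdz * self.rc ** 2 / 4.0 - C1 * math.log(self.rc)
        return C1, C2


def newtonian_annulus_velocity(r, station: NewtonianStation):
    """Closed-form annular Poiseuille velocity with outer-wall slip."""
    C1, C2 = station._constants
    r_arr = np.asarray(r, dtype=float)
    v = station.dpdz / 4.0 * r_arr ** 2 + C1 * np.log(r_arr) + C2
    return v if r_arr.ndim else float(v)


def newtonian_annulus_gradient(r, station: NewtonianStation):
    """Closed-form dv/dr of the Newtonian annulus solution."""
    C1, _ = station._constants
    r_arr = np.asarray(r, dtype=float)
    g = station.dpdz / 2.0 * r_arr + C1 / r_arr
    return g if r_arr.ndim else float(g)


def newtonian_annulus_flux(station: NewtonianStation) -> float:
    """Closed-form Q = int 2 r v dr via the symbolic antiderivative."""
    C1, C2 = station._constants

    def antideriv(r: float) -> float:
        return 2.0 * (station.dpdz * r ** 4 / 16.0
                      + C1 * (r * r / 2.0) * (math.log(r) - 0.5)
                      + C2 * r * r / 2.0)

    return antideriv(station.h) - antideriv(station.rc)


def quadrature_flux(velocity, rc: float, h: float) -> float:
    """Flux of an arbitrary profile by adaptive quadrature of ``2 r v(r)``.

    Raises ``RuntimeError`` when the quadrature error estimate stays above
    1e-8 (an oracle failure, not a model error).
    """
    val, err = quad(lambda r: 2.0 * r * velocity(r), rc, h,
                    epsabs=1e-10, epsrel=1e-10, limit=200)
    if err > 1e-8:
        raise RuntimeError(f"flux quadrature did not converge (err={err:.2e})")
    return val


def extrema_scan(geom: GeometryParams, step: float = 1e-6) -> tuple[float, float, float]:
    """Brute-force extrema: sign changes of the analytic dh/dz on the
    stenosed segment, each refined by root bracketing to ~1e-12.

    Independent of the cubic solve — this walks the derivative directly.
    """
    if step > 1e-5:
        raise ValueError(f"scan step must be <= 1e-5, got {step}")
    a, b = geom.gamma, geom.gamma + 1.0
    n = int(math.ceil((b - a) / step)) + 1
    zs = np.linspace(a, b, n)
    slopes = wall_slope(zs, geom)
    sign = np.sign(slopes)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = [brentq(lambda z: wall_slope(z, geom), zs[i], zs[i + 1],
                    xtol=1e-13, rtol=1e-15) for i in idx]
    roots.extend(zs[np.nonzero(sign == 0)[0]])
    roots = sorted(roots)
    if len(roots) != 3:
        raise DegenerateGeometryError(
            f"derivative scan found {len(roots)} extrema, expected 3"
        )
    return tuple(roots)


def highprec_velocity(h: float, rc: float, fluid: FluidParams,
                      dpdz: float, u: float, r: float, dps: int = 250) -> float:
    """Axial velocity re-derived end to end with mpmath at ``dps`` digits.

    Rebuilds the 4x4 boundary system with unscaled arbitrary-precision
    Bessel functions and solves it exactly; no shared code with the scaled
    double-precision path.
    """
    import mpmath as mp

    with mp.workdps(dps):
        N = mp.mpf(fluid.N)
        m = mp.mpf(fluid.m)
        b = (1 - N) / (2 - N)
        hh, rr, rcc = mp.mpf(h), mp.mpf(r), mp.mpf(rc)
        P, uu = mp.mpf(dpdz), mp.mpf(u)

        def nu_row(x):
            return [-b / x, mp.besseli(1, m * x), mp.besselk(1, m * x),
                    mp.mpf(0)]

        def v_row(x):
            return [2 * b * mp.log(x), -(N / m) * mp.besseli(0, m * x),
                    (N / m) * mp.besselk(0, m * x), mp.mpf(1)]

        M = mp.matrix([nu_row(hh), nu_row(rcc), v_row(hh), v_row(rcc)])
        rhs = mp.matrix([b * hh / 2 * P, b * rcc / 2 * P,
                         uu - 2 * b * hh ** 2 / 4 * P,
                         -2 * b * rcc ** 2 / 4 * P])
        k1, c2, c3, c4 = mp.lu_solve(M, rhs)
        v = ((N / m) * (-c2 * mp.besseli(0, m * rr)
                        + c3 * mp.besselk(0, m * rr))
             + 2 * b * (k1 * mp.log(rr) + rr ** 2 / 4 * P) + c4)
        return float(v)


def self_check(seed: int = 0) -> list[dict]:
    """Run the oracle identities and return one pass/fail record each.

    Used by the ``stenoflow self-check`` CLI command; regressions in the
    Bessel scaling or the closed-form flux are silent without it.
    """
    from .station_solver import (axial_velocity, microrotation,
                                 solve_station, station_flux)

    rng = np.random.default_rng(seed)
    checks: list[dict] = []

    def record(name: str, error: float, tol: float) -> None:
        checks.append({"name": name, "error": float(error), "tol": tol,
                       "ok": bool(error < tol)})

    # closed-form flux vs quadrature at random stations
    worst = 0.0
    for _ in range(5):
        h = rng.uniform(0.6, 1.1)
        rc = rng.uniform(0.05, 0.4 * h)
        fluid = FluidParams(N=rng.uniform(0.05, 0.95),
                            m=rng.uniform(2.0, 80.0))
        dpdz, u = rng.uniform(-5, -0.5), rng.uniform(0, 0.02)
        st = solve_station(h, rc, fluid)
        q_closed = station_flux(st, dpdz, u)
        q_quad = quadrature_flux(
            lambda r: axial_velocity(r, st, dpdz, u), rc, h)
        worst = max(worst, abs(q_closed - q_quad) / max(abs(q_quad), 1e-30))
    record("flux closed-form vs quadrature", worst, 1e-7)

    # boundary residuals
    st = solve_station(0.9, 0.1, FluidParams(N=0.75, m=50.0))
    res = max(abs(axial_velocity(0.1, st, -1.0, 0.01)),
              abs(axial_velocity(0.9, st, -1.0, 0.01) - 0.01),
              abs(microrotation(0.1, st, -1.0, 0.01)),
              abs(microrotation(0.9, st, -1.0, 0.01)))
    record("boundary residuals", res, 1e-10)

    # Newtonian limit
    stN = solve_station(0.9, 0.1, FluidParams(N=1e-6, m=50.0))
    newt = NewtonianStation(h=0.9, rc=0.1, dpdz=-1.0, u=0.0)
    rs = np.linspace(0.1, 0.9, 41)
    dev = float(np.max(np.abs(axial_velocity(rs, stN, -1.0, 0.0)
                              - newtonian_annulus_velocity(rs, newt))))
    record("Newtonian annulus limit (N=1e-6)", dev, 1e-4)

    # cubic extrema vs derivative scan
    from .geometry import stenosis_extrema
    geom = GeometryParams(zeta=math.tan(-0.05), eps=0.1)
    scan = extrema_scan(geom, step=1e-5)
    rep = stenosis_extrema(geom)
    record("extrema cubic vs derivative scan",
           max(abs(a - b) for a, b in zip(rep.locations, scan)), 1e-6)

    # high-precision re-evaluation (250-digit Bessel backend)
    try:
        st = solve_station(0.9, 0.1, FluidParams(N=0.75, m=50.0))
        vmid = float(axial_velocity(0.5, st, -1.0, 0.01))
        vhp = highprec_velocity(0.9, 0.1, FluidParams(N=0.75, m=50.0),
                                -1.0, 0.01, 0.5)
        record("high-precision Bessel re-evaluation",
               abs(vmid - vhp) / abs(vhp), 1e-10)
    except ImportError:  # pragma: no cover - mpmath ships with sympy
        pass

    return checks
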