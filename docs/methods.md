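# Methods

## Physical model and assumptions

The package models steady, axisymmetric, incompressible flow of a
micropolar fluid in the annulus between a rigid coaxial catheter and a
rigid arterial wall with an overlapping stenosis on a linear taper.
Micropolar (Eringen) fluids carry an independent microrotation field
`nu_theta` alongside the velocity, supporting couple stresses; this is a
standard continuum idealization of blood's suspended-cell microstructure.
The wall admits an axial slip velocity `u`, an idealization of the
cell-depleted plasma layer near the wall.

The governing balance laws are reduced at lubrication order under the
mild-stenosis assumptions (stenosis height small against the lumen radius,
lumen radius comparable to stenosis length): radial pressure variation and
axial diffusion drop, pressure becomes a function of `z` alone, and the
radial velocity decouples.  The only surviving material parameters are the
coupling number `N = kappa/(mu + kappa)` with `0 <= N < 1` (the ratio of
microstructure coupling to total shear viscosity; `N -> 0` is Newtonian)
and the micropolar parameter `m > 0` (which sets the thickness `~1/m` of
the microrotation boundary layers; large `m` means weak micropolar
effects).  The individual material moduli are deliberately not stored:
they enter only through `N` and `m`.

Consequences built into the code rather than asserted from outside:

- The station problem is linear, so the solution splits exactly into a
  unit-pressure-gradient and a unit-slip sub-problem, and the flux is
  affine: `Q = A(z) dpdz + B(z) u` with `A < 0 < B`.
- Microrotation vanishes at both walls by boundary condition, so the wall
  shear stress reduces to `tau_w = -[1/(1-N)] dv/dr` at `r = h(z)`.
- At prescribed flux, increasing wall slip flattens the velocity profile
  and therefore *lowers* both the impedance and the wall shear stress; the
  slip-lowers-`tau_w` direction is a structural consequence of the affine
  flux split, and the test suite asserts it as such.

## Geometry

`h(z) = 1 + zeta z - (3 eps/2)(11u - 47u^2 + 72u^3 - 36u^4)`, `u = z -
gamma`, inside the stenosed segment; `1 + zeta z` outside.  The quartic
bracket vanishes at both segment ends, so the profile is continuous (the
slope is not, which is why axial integrals are split there).  Although
`eps` is conventionally named the stenosis "height", the actual depth at
the two extrema is `(3 eps/2) S(u_L) ~ 1.2604 eps` and `0.75 eps` at the
saddle; the package follows the formula and documents the naming quirk.

Extrema are the roots of `144u^3 - 216u^2 + 94u - 11 + 2 zeta/(3 eps) = 0`,
found via the companion-matrix eigenvalues and polished by Newton
iteration on the analytic `dh/dz` to 1e-12.  `eps = 0` is a supported
flow geometry (plain tapered tube) but has no extrema: asking for them
raises rather than fabricating locations.  A taper steep enough to
destroy the three-real-root structure raises a degenerate-geometry error.

The taper convention is `zeta = tan(phi)` with `phi` in radians; a raw
slope can be supplied directly through the `zeta` key instead.  Supplying
both is rejected as overdetermined.

## Station solution and numerical choices

The closed-form solution is

```
nu(r) = c2 I1(mr) + c3 K1(mr) - b (c1/r + r/2) P,        b = (1-N)/(2-N)
v(r)  = (N/m)(-c2 I0(mr) + c3 K0(mr)) + 2b (c1 ln r + r^2/4) P + c4
```

with the four constants fixed by `v(rc) = 0`, `v(h) = u`, `nu(rc) =
nu(h) = 0`.  The relative signs of the microrotation and velocity blocks
are fixed by back-substitution into the momentum balance (an easy place
for a sign slip; the flux antiderivative and the independent checks below
pin it down).

- **Overflow control.** For `m ~ 50`, `I1(m h) ~ 1e20`; the boundary
  system is assembled with scipy's exponentially scaled `ive`/`kve`, and
  the constants are stored in a scaled basis (`c2` relative to `e^{+mh}`,
  `c3` relative to `e^{-m rc}`) so every downstream expression multiplies
  only like-scaled pairs whose exponentials never exceed one inside the
  annulus.
- **Parametrization.** The product `c1 * P` is carried as a single
  unknown, which keeps the basis linear in `(P, u)` jointly and makes the
  pure-slip sub-problem (`P = 0`) nondegenerate.
- **Linear solve.** Direct dense 4x4 with partial pivoting; the condition
  number is estimated and a solve is refused above 1e12 (reached only as
  `rc -> h`).
- **Flux.** Closed form via termwise antiderivatives
  (`int r I0 = (r/m) I1`, `int r K0 = -(r/m) K1`,
  `int r ln r = (r^2/2)(ln r - 1/2)`), cross-checked against adaptive
  quadrature to 1e-8 relative in the tests and the `self-check` command.
- **Sign convention.** `dpdz < 0` drives flow in `+z`; profile evaluation
  accepts any sign.

## Axial integration

The impedance integrates the prescribed-flux pressure gradient
`(Q - B u)/A` with Gauss-Kronrod adaptive quadrature (absolute and
relative tolerance 1e-9) over the three segments `[0, gamma]`,
`[gamma, gamma+1]`, `[gamma+1, 1/Gamma]` — the integrand kinks at the
segment joins — and reports the summed error estimate.  `lambda = dp/Q`
with `dp` the length-normalized pressure loss, so `lambda` is positive
for forward flow.  The affine treatment of slip in the pressure drop is
the canonical path; a compatibility mode (`slip_in_pressure=False`)
reproduces the classical inverse-conductance form, exact only at `u = 0`,
and the two are asserted to coincide there.

The prescribed flux defaults to `Q = 1`.  At `u = 0` the impedance is
flux-scale-free; under slip it is not, so `Q` is an explicit, logged
parameter.

## Defaults

`phi = -0.05` (converging), `eps = 0.1`, `gamma = 0.5`, `Gamma = 0.5`
(stenosis of length `L1 = L/2` centred in an artery of length `L = 2`),
`rc = 0.1`, `N = 0.75`, `m = 50`, `u = 0.01`, `Q = 1`.  These are the
configuration the model study's figures and tables are built around; the
slip values 0.01-0.02 correspond to 1-2% of the typical axial velocity.

## Verification strategy

Independent references live in `stenoflow.reference_oracles` (installed,
not test-only, so `stenoflow self-check` can flag silent Bessel-scaling
regressions at run time):

- the classical Newtonian annulus closed form (the `N -> 0` limit; the
  micropolar solver must agree to 1e-4 max-norm at `N = 1e-6`);
- adaptive-quadrature flux of an arbitrary profile;
- a brute-force derivative sign-scan locating the stenosis extrema
  without the cubic;
- an end-to-end 250-digit re-derivation of the station solution with
  mpmath's arbitrary-precision Bessel functions (no shared code with the
  scaled double-precision path).

The pytest suite asserts the boundary residuals (< 1e-10), superposition,
the flux identity (< 1e-7 relative), the Newtonian limit, the geometric
symmetries (nontapered profiles give equal wall shear at both depth
maxima to 1e-9), and the monotone parameter trends of impedance and wall
shear stress on three-point stencils around the defaults.

## Limitations

- Lubrication order only: no inertial corrections, no radial velocity, no
  pulsatility; the walls and catheter are rigid and the catheter is
  stationary and perfectly coaxial.
- The model is quasi-one-dimensional in `z`; it cannot represent
  recirculation or separation downstream of a severe stenosis.
- The wall shear stress is reported with its computed sign and magnitude;
  no folding conventions are applied.
- The monotone-trend tests are finite-difference sign checks on 3-point
  stencils around the default configuration, not global claims.
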