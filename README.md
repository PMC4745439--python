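# stenoflow

Steady blood flow through a **catheterized, tapered artery with an
overlapping stenosis**, with blood modelled as an Eringen **micropolar
fluid** and **velocity slip** at the arterial wall.

Catheterization turns the arterial lumen into an annulus between a rigid
coaxial catheter of radius `r_c` and the diseased wall `r = h(z)`.  An
overlapping stenosis — two merged plaque constrictions — gives the wall two
depth maxima (`z_L`, `z_R`) separated by a central saddle (`z_C`), possibly
superposed on a linear taper `zeta = tan(phi)`.  The library computes, for
this configuration, the quantities an interventional model study cares
about: the extremum geometry, radial profiles of axial velocity `v_z(r)` and
microrotation `nu_theta(r)`, the flow impedance `lambda`, and the wall shear
stress `tau_w` across the stenosis.

## Model

All quantities are nondimensional: radii in units of the healthy lumen
radius, axial distance in units of the stenosis length `L1`, so the artery
spans `0 <= z <= 1/Gamma` (`Gamma = L1/L`) and the stenosis occupies
`gamma <= z <= gamma + 1`.  Inside the stenosed segment the wall is

```
h(z) = 1 + zeta z - (3 eps/2)(11u - 47u^2 + 72u^3 - 36u^4),   u = z - gamma,
```

whose interior extrema solve `144u^3 - 216u^2 + 94u - 11 + 2 zeta/(3 eps) = 0`.

At lubrication (mild-stenosis) order the micropolar balance laws at each
axial station reduce to, with `P = dp/dz` and coupling number
`N = kappa/(mu + kappa)` (`0 <= N < 1`), micropolar parameter `m > 0`:

```
P     = [N/(1-N)] (1/r) d(r nu)/dr + [1/(1-N)] (1/r) d(r v')/dr
2 nu  = -v' + [(2-N)/m^2] d/dr[(1/r) d(r nu)/dr]
```

solved in closed form with modified Bessel functions `I_0, I_1, K_0, K_1`
under no-slip/no-spin on the catheter and slip `v = u`, no-spin on the wall.
The station flux splits affinely, `Q = A(z) P + B(z) u`, so a prescribed
flux fixes the local pressure gradient `P = (Q - B u)/A` and

```
lambda = Gamma * int_0^{1/Gamma} (-P) dz / Q,
tau_w  = -[1/(1-N)] dv/dr |_{r=h(z)}.
```

Exponentially scaled Bessel functions keep the solve stable at
physiological `m` (where `I_1(m h)` would overflow double precision).

## Worked example

Extrema of the nontapered stenosis (`eps = 0.1`):

```
$ stenoflow extrema --set phi=0
          zL  zC          zR           hL    hC           hR
0.6881952178   1 1.311804782 0.8739583333 0.925 0.8739583333
```

The two depth maxima sit symmetrically about the saddle at `z = 1`; the
lumen narrows from 1 to 0.874 there (the true depth is `~1.26 eps`, larger
than the height parameter itself — a known quirk of the overlapping
profile).  The default converging-artery configuration (`phi = -0.05`,
`N = 0.75`, `m = 50`, `r_c = 0.1`, `u = 0.01`, `Q = 1`):

```
$ stenoflow impedance
          zeta  eps  gamma  Gamma  rc    N  m  Q    u         lam ...       tw_zL       tw_zC       tw_zR
-0.05004170838  0.1    0.5    0.5 0.1 0.75 50  1 0.01 59.95672459 ... 25.19835172 21.92298011 28.54731176
```

`lam = 59.96` is the pressure loss per unit flux across the whole segment;
the wall shear stress peaks at the *downstream* depth maximum
(`tau_w(z_R) = 28.5 > tau_w(z_L) = 25.2`) because the converging taper has
already narrowed the lumen there — for `phi = 0` the two peaks are equal.

Other subcommands: `wss` (stress across the stenosis), `profile`
(radial `v_z`, `nu_theta`), `sweep` (cartesian parameter sweeps to CSV),
and `self-check`, which runs the built-in oracle identities:

```
$ stenoflow self-check
flux closed-form vs quadrature       PASS  err=1.386e-15  tol=1e-07
boundary residuals                   PASS  err=1.388e-17  tol=1e-10
Newtonian annulus limit (N=1e-6)     PASS  err=4.954e-08  tol=1e-04
extrema cubic vs derivative scan     PASS  err=1.443e-15  tol=1e-06
high-precision Bessel re-evaluation  PASS  err=3.431e-16  tol=1e-10
```

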