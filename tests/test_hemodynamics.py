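"""Axially integrated quantities: pressure gradient, impedance, wall shear."""

import math

import numpy as np
import pytest

from stenoflow import (
    FlowConditions,
    FluidParams,
    GeometryParams,
    artery_radius,
    axial_velocity,
    impedance,
    pressure_gradient_at,
    solve_station,
    stenosis_extrema,
    wall_shear_stress_at,
    wss_curve,
)
from stenoflow.reference_oracles import quadrature_flux


class TestPressureGradient:
    def test_prescribed_flux_recovered_along_artery(self, nontapered_geom,
                                                    default_fluid,
                                                    default_flow, rng):
        """Mass conservation: quadrature of the station profile returns Q."""
        zs = rng.uniform(0.0, 2.0, size=20)
        for z in zs:
            dpdz = pressure_gradient_at(z, nontapered_geom, default_fluid,
                                        default_flow)
            h = artery_radius(z, nontapered_geom)
            st = solve_station(h, nontapered_geom.rc, default_fluid)
            q = quadrature_flux(
                lambda r: axial_velocity(r, st, dpdz, default_flow.u),
                nontapered_geom.rc, h)
            assert q == pytest.approx(default_flow.Q, rel=1e-7)

    def test_negative_for_forward_flow(self, nontapered_geom, default_fluid,
                                       default_flow):
        assert pressure_gradient_at(1.0, nontapered_geom, default_fluid,
                                    default_flow) < 0

    def test_straight_tube_gradient_constant(self, default_fluid):
        geom = GeometryParams(zeta=0.0, eps=0.0, rc=0.1)
        flow = FlowConditions(Q=1.0, u=0.01)
        vals = [pressure_gradient_at(z, geom, default_fluid, flow)
                for z in (0.1, 0.9, 1.7)]
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)

    def test_no_slip_reduces_to_conductance_ratio(self, nontapered_geom,
                                                  default_fluid):
        from stenoflow import flux_coefficients
        flow = FlowConditions(Q=1.0, u=0.0)
        z = 1.0
        h = artery_radius(z, nontapered_geom)
        A, _ = flux_coefficients(h, nontapered_geom.rc, default_fluid)
        assert pressure_gradient_at(z, nontapered_geom, default_fluid,
                                    flow) == pytest.approx(flow.Q / A,
                                                           rel=1e-12)


class TestImpedance:
    def test_straight_annulus_closed_form(self, default_fluid):
        """For a uniform annulus the integrand is constant and the impedance
        has the closed form Gamma * L * (Q - B u)/(|A| Q)."""
        from stenoflow import flux_coefficients
        geom = GeometryParams(zeta=0.0, eps=0.0, rc=0.1)
        flow = FlowConditions(Q=1.0, u=0.01)
        A, B = flux_coefficients(1.0, 0.1, default_fluid)
        expected = geom.Gamma * geom.length * (flow.Q - B * flow.u) \
            / (abs(A) * flow.Q)
        res = impedance(geom, default_fluid, flow)
        assert res.lam == pytest.approx(expected, rel=1e-9)
        assert res.lam == pytest.approx(res.dp / flow.Q, rel=1e-15)

    def test_positive_and_error_reported(self, nontapered_geom, default_fluid,
                                         default_flow):
        res = impedance(nontapered_geom, default_fluid, default_flow)
        assert res.lam > 0
        assert 0 <= res.quadrature_error < 1e-6
        assert set(res.tw_at) == {"zL", "zC", "zR"}

    def test_stenosis_raises_impedance(self, default_fluid, default_flow):
        lam_sten = impedance(GeometryParams(zeta=0.0, eps=0.1, rc=0.1),
                             default_fluid, default_flow).lam
        lam_straight = impedance(GeometryParams(zeta=0.0, eps=0.0, rc=0.1),
                                 default_fluid, default_flow).lam
        assert lam_sten > lam_straight

    def test_slip_facilitates_flow(self, nontapered_geom, default_fluid):
        lam_noslip = impedance(nontapered_geom, default_fluid,
                               FlowConditions(Q=1.0, u=0.0)).lam
        lam_slip = impedance(nontapered_geom, default_fluid,
                             FlowConditions(Q=1.0, u=0.01)).lam
        assert lam_slip < lam_noslip

    def test_compatibility_mode_drops_slip_from_pressure(self, nontapered_geom,
                                                         default_fluid):
        flow = FlowConditions(Q=1.0, u=0.01)
        affine = impedance(nontapered_geom, default_fluid, flow).lam
        classical = impedance(nontapered_geom, default_fluid, flow,
                              slip_in_pressure=False).lam
        noslip = impedance(nontapered_geom, default_fluid,
                           FlowConditions(Q=1.0, u=0.0)).lam
        assert classical == pytest.approx(noslip, rel=1e-10)
        assert affine < classical

    @pytest.mark.parametrize(
        "param, direction",
        [
            ("eps", +1), ("rc", +1), ("N", +1), ("Gamma", +1),
            ("m", -1), ("u", -1), ("phi", -1),
        ],
    )
    def test_monotone_parameter_trends(self, param, direction):
        """Impedance rises with stenosis height, catheter radius, coupling
        number and stenosis length fraction; falls with the micropolar
        parameter, wall slip and taper angle."""
        stencils = {
            "eps": [0.05, 0.1, 0.15], "rc": [0.05, 0.1, 0.15],
            "N": [0.6, 0.75, 0.9], "Gamma": [0.4, 0.5, 0.6],
            "m": [10.0, 50.0, 90.0], "u": [0.0, 0.01, 0.02],
            "phi": [-0.05, 0.0, 0.05],
        }
        lams = []
        for val in stencils[param]:
            geom = dict(zeta=0.0, eps=0.1, rc=0.1, Gamma=0.5)
            fluid = dict(N=0.75, m=50.0)
            flow = dict(Q=1.0, u=0.01)
            if param == "phi":
                geom["zeta"] = math.tan(val)
            elif param in geom:
                geom[param] = val
            elif param in fluid:
                fluid[param] = val
            else:
                flow[param] = val
            lams.append(impedance(GeometryParams(**geom), FluidParams(**fluid),
                                  FlowConditions(**flow)).lam)
        diffs = np.diff(lams) * direction
        assert np.all(diffs > 0), f"{param}: {lams}"


class TestWallShearStress:
    def test_nontapered_extrema_carry_equal_stress(self, nontapered_geom,
                                                   default_fluid,
                                                   default_flow):
        rep = stenosis_extrema(nontapered_geom)
        twL = wall_shear_stress_at(rep.zL, nontapered_geom, default_fluid,
                                   default_flow)
        twR = wall_shear_stress_at(rep.zR, nontapered_geom, default_fluid,
                                   default_flow)
        assert twL == pytest.approx(twR, abs=1e-9)

    def test_converging_taper_downstream_maximum_larger(self, converging_geom,
                                                        default_fluid,
                                                        default_flow):
        rep = stenosis_extrema(converging_geom)
        twL = wall_shear_stress_at(rep.zL, converging_geom, default_fluid,
                                   default_flow)
        twR = wall_shear_stress_at(rep.zR, converging_geom, default_fluid,
                                   default_flow)
        assert twR > twL

    def test_linear_in_flux_at_zero_slip(self, nontapered_geom, default_fluid):
        tw1 = wall_shear_stress_at(1.0, nontapered_geom, default_fluid,
                                   FlowConditions(Q=1.0, u=0.0))
        tw_small = wall_shear_stress_at(1.0, nontapered_geom, default_fluid,
                                        FlowConditions(Q=1e-8, u=0.0))
        assert tw_small == pytest.approx(1e-8 * tw1, rel=1e-9)
        assert abs(tw_small) < 1e-6

    def test_slip_lowers_wall_shear_at_fixed_flux(self, converging_geom,
                                                  default_fluid):
        """At prescribed flux, wall slip flattens the profile and must lower
        the wall velocity gradient (a consequence of the affine flux split)."""
        rep = stenosis_extrema(converging_geom)
        tws = [wall_shear_stress_at(rep.zL, converging_geom, default_fluid,
                                    FlowConditions(Q=1.0, u=u))
               for u in (0.0, 0.01, 0.02)]
        assert tws[0] > tws[1] > tws[2]

    @pytest.mark.parametrize(
        "param, direction",
        [("N", +1), ("rc", +1), ("eps", +1), ("m", -1), ("phi", -1)],
    )
    def test_monotone_parameter_trends_at_first_maximum(self, param,
                                                        direction):
        stencils = {
            "N": [0.6, 0.75, 0.9], "rc": [0.05, 0.1, 0.15],
            "eps": [0.05, 0.1, 0.15], "m": [10.0, 50.0, 90.0],
            "phi": [-0.05, 0.0, 0.05],
        }
        tws = []
        for val in stencils[param]:
            geom = dict(zeta=math.tan(-0.05), eps=0.1, rc=0.1)
            fluid = dict(N=0.75, m=50.0)
            if param == "phi":
                geom["zeta"] = math.tan(val)
            elif param in geom:
                geom[param] = val
            else:
                fluid[param] = val
            g = GeometryParams(**geom)
            rep = stenosis_extrema(g)
            tws.append(wall_shear_stress_at(rep.zL, g, FluidParams(**fluid),
                                            FlowConditions(Q=1.0, u=0.01)))
        diffs = np.diff(tws) * direction
        assert np.all(diffs > 0), f"{param}: {tws}"


class TestWssCurve:
    def test_endpoints_and_pointwise_consistency(self, nontapered_geom,
                                                 default_fluid, default_flow):
        curve = wss_curve(nontapered_geom, default_fluid, default_flow,
                          n_points=21)
        assert curve[0, 0] == pytest.approx(nontapered_geom.gamma)
        assert curve[-1, 0] == pytest.approx(nontapered_geom.gamma + 1.0)
        z_mid = curve[10, 0]
        assert curve[10, 1] == pytest.approx(
            wall_shear_stress_at(z_mid, nontapered_geom, default_fluid,
                                 default_flow), rel=1e-12)

    def test_nontapered_curve_symmetric(self, nontapered_geom, default_fluid,
                                        default_flow):
        curve = wss_curve(nontapered_geom, default_fluid, default_flow,
                          n_points=41)
        np.testing.assert_allclose(curve[:, 1], curve[::-1, 1],
                                   rtol=0, atol=1e-9)

    def test_maxima_sit_at_depth_maxima(self, nontapered_geom, default_fluid,
                                        default_flow):
        rep = stenosis_extrema(nontapered_geom)
        curve = wss_curve(nontapered_geom, default_fluid, default_flow,
                          n_points=201)
        dz = curve[1, 0] - curve[0, 0]
        half = len(curve) // 2
        zmax_left = curve[np.argmax(curve[:half, 1]), 0]
        zmax_right = curve[half + np.argmax(curve[half:, 1]), 0]
        assert abs(zmax_left - rep.zL) <= dz
        assert abs(zmax_right - rep.zR) <= dz

    def test_taller_stenosis_raises_stress_pointwise(self, default_fluid,
                                                     default_flow):
        curves = [wss_curve(GeometryParams(zeta=0.0, eps=eps, rc=0.1),
                            default_fluid, default_flow, n_points=31)[:, 1]
                  for eps in (0.05, 0.1, 0.15)]
        assert np.all(np.abs(curves[1]) >= np.abs(curves[0]))
        assert np.all(np.abs(curves[2]) >= np.abs(curves[1]))

    def test_too_few_points_rejected(self, nontapered_geom, default_fluid,
                                     default_flow):
        with pytest.raises(ValueError):
            wss_curve(nontapered_geom, default_fluid, default_flow, n_points=1)
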