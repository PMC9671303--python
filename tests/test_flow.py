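"""Flow network: viscous resistance oracles, bilateral solve, calibration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhinoflow.ambient import AIR_25C, AirProperties
from rhinoflow.errors import InvalidGeometryError
from rhinoflow.flow import (
    MinorLossModel,
    calibrate_outlet_pressure,
    path_resistance,
    segment_resistance,
    segment_viscous_resistance,
    solve_bilateral_flow,
    solve_linear_network,
)
from rhinoflow.geometry import (
    Region,
    default_template,
    make_circular_segment,
    make_slit_segment,
)

MM = 1e-3
ML_S = 1e-6


class TestSegmentResistance:
    def test_hagen_poiseuille_oracle(self):
        """Uniform circular duct must match 128·μ·L·Q/(π·D⁴) exactly."""
        props = AirProperties(dynamic_viscosity=1.81e-5)
        seg = make_circular_segment("p", Region.AREA3_NASOPHARYNX, 60 * MM, 6 * MM)
        q = 100 * ML_S
        expected = 128 * 1.81e-5 * 60 * MM * q / (math.pi * (6 * MM) ** 4)
        dp = segment_viscous_resistance(seg, q, props)
        assert dp == pytest.approx(expected, rel=1e-10)
        assert dp == pytest.approx(3.41, abs=0.01)

    def test_wide_slit_matches_cubic_gap_law(self):
        """For W ≫ g the slit coefficient reduces to 12·μ·L/(g³·W)."""
        seg = make_slit_segment("s", Region.AREA2_CAVITY, 60 * MM, 1 * MM, 200 * MM)
        plane = 12 * AIR_25C.dynamic_viscosity * 60 * MM / ((1 * MM) ** 3 * 200 * MM)
        assert segment_resistance(seg) == pytest.approx(plane, rel=0.02)

    def test_zero_flow_zero_drop(self, template):
        for seg in template.left_path:
            assert segment_viscous_resistance(seg, 0.0) == 0.0

    def test_linearity_in_flow(self, template):
        seg = template.left_path[0]
        assert segment_viscous_resistance(seg, 2e-4) == pytest.approx(
            2 * segment_viscous_resistance(seg, 1e-4), rel=1e-12
        )

    def test_negative_flow_rejected(self, template):
        with pytest.raises(ValueError):
            segment_viscous_resistance(template.left_path[0], -1e-5)

    def test_invalid_geometry_propagates(self):
        seg = make_circular_segment("bad", Region.AREA3_NASOPHARYNX, -1.0, 6 * MM)
        with pytest.raises(InvalidGeometryError):
            segment_resistance(seg)


class TestLinearNetwork:
    def test_two_resistor_current_divider(self):
        """Side resistances 0.3 / 0.075 Pa/(mL·s) split flow 20 : 80."""
        ql, qr, _ = solve_linear_network(0.3e6, 0.075e6, 0.0, -10.0)
        assert 100 * ql / (ql + qr) == pytest.approx(20.0, rel=1e-12)

    def test_series_parallel_target_flow(self):
        """0.05 each side + 0.01 shared at −8.75 Pa gives 250 mL/s total."""
        ql, qr, _ = solve_linear_network(0.05e6, 0.05e6, 0.01e6, -8.75)
        assert (ql + qr) / ML_S == pytest.approx(250.0, rel=1e-12)

    def test_symmetric_template_splits_evenly(self, template):
        sol = solve_bilateral_flow(template, -10.0)
        assert sol.q_left == pytest.approx(sol.q_right, rel=1e-12)
        assert 100 * sol.q_left / sol.q_total == pytest.approx(50.0, rel=1e-12)

    def test_solution_matches_independent_series_parallel_algebra(self):
        model = default_template(left_gap_factor=0.6, right_gap_factor=1.1)
        sol = solve_bilateral_flow(model, -15.0)
        # independent oracle: per-unit-flow pressure drops summed per path
        r_l = sum(segment_viscous_resistance(s, 1.0) for s in model.left_path)
        r_r = sum(segment_viscous_resistance(s, 1.0) for s in model.right_path)
        r_s = sum(segment_viscous_resistance(s, 1.0) for s in model.shared_path)
        r_par = 1.0 / (1.0 / r_l + 1.0 / r_r)
        q_tot = 15.0 / (r_par + r_s)
        p_ch = -q_tot * r_par
        assert sol.q_total == pytest.approx(q_tot, rel=1e-9)
        assert sol.choanal_pressure == pytest.approx(p_ch, rel=1e-9)
        assert sol.q_left == pytest.approx(-p_ch / r_l, rel=1e-9)

    def test_mass_conservation_at_junction(self, template):
        sol = solve_bilateral_flow(template, -12.3)
        assert abs(sol.q_total - (sol.q_left + sol.q_right)) <= 1e-12 * sol.q_total

    def test_pressure_monotone_along_paths(self, template):
        sol = solve_bilateral_flow(template, -10.0)
        assert sol.outlet_pressure < sol.choanal_pressure < 0.0
        assert all(dp >= 0.0 for dp in sol.segment_pressure_drops.values())

    def test_flow_increases_with_driving_pressure(self, template):
        q = [solve_bilateral_flow(template, p).q_total for p in (-5.0, -10.0, -20.0)]
        assert q[0] < q[1] < q[2]

    def test_enlarging_one_side_never_decreases_its_flow(self):
        base = solve_bilateral_flow(default_template(left_gap_factor=0.7), -10.0)
        wider = solve_bilateral_flow(default_template(left_gap_factor=0.8), -10.0)
        assert wider.q_left > base.q_left

    def test_inspiratory_sign_enforced(self, template):
        with pytest.raises(ValueError):
            solve_bilateral_flow(template, +5.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        rl=st.floats(0.02, 0.5),
        rr=st.floats(0.02, 0.5),
        rs=st.floats(0.001, 0.05),
        p=st.floats(1.0, 40.0),
    )
    def test_linear_solution_property(self, rl, rr, rs, p):
        """Junction balance and side characteristics hold for arbitrary networks."""
        ql, qr, p_ch = solve_linear_network(rl * 1e6, rr * 1e6, rs * 1e6, -p)
        assert -p_ch == pytest.approx(rl * 1e6 * ql, rel=1e-9)
        assert -p_ch == pytest.approx(rr * 1e6 * qr, rel=1e-9)
        assert p_ch - (-p) == pytest.approx(rs * 1e6 * (ql + qr), rel=1e-9)


class TestNewtonPath:
    def test_newton_reduces_to_linear_when_losses_vanish(self, template):
        zero = MinorLossModel(entrance_k=0.0, borda_carnot=False)
        lin = solve_bilateral_flow(template, -10.0)
        non = solve_bilateral_flow(template, -10.0, minor_losses=zero)
        assert non.q_left == pytest.approx(lin.q_left, rel=1e-9)
        assert non.converged and non.residual <= 1e-10

    def test_newton_with_losses_satisfies_characteristics(self):
        model = default_template(left_gap_factor=0.6)
        losses = MinorLossModel()
        sol = solve_bilateral_flow(model, -12.0, minor_losses=losses)
        # verify the left-side characteristic directly from the solution
        r_l = path_resistance(model.left_path)
        from rhinoflow.flow import _path_minor_coeff

        k_l = _path_minor_coeff(model.left_path, AIR_25C, losses, True)
        dp_side = -sol.choanal_pressure
        assert dp_side == pytest.approx(
            r_l * sol.q_left + k_l * sol.q_left**2, rel=1e-8
        )
        # minor losses can only reduce the flow at fixed driving pressure
        assert sol.q_total < solve_bilateral_flow(model, -12.0).q_total


class TestCalibration:
    def test_linear_network_closed_form(self, template):
        """p_out = −R_total·Q for the purely viscous network."""
        p = calibrate_outlet_pressure(template, 250 * ML_S)
        r_l = path_resistance(template.left_path)
        r_s = path_resistance(template.shared_path)
        assert p == pytest.approx(-(r_l / 2 + r_s) * 250 * ML_S, rel=1e-12)

    def test_zero_target_zero_pressure(self, template):
        assert calibrate_outlet_pressure(template, 0.0) == 0.0

    def test_pressure_linear_in_target(self, template):
        p1 = calibrate_outlet_pressure(template, 125 * ML_S)
        p2 = calibrate_outlet_pressure(template, 250 * ML_S)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_calibrated_flow_hits_target(self, template):
        p = calibrate_outlet_pressure(template, 250 * ML_S)
        q = solve_bilateral_flow(template, p).q_total
        assert abs(q - 250 * ML_S) / (250 * ML_S) <= 1e-6

    def test_calibration_with_minor_losses(self, template):
        losses = MinorLossModel()
        p = calibrate_outlet_pressure(template, 250 * ML_S, minor_losses=losses)
        q = solve_bilateral_flow(template, p, minor_losses=losses).q_total
        assert abs(q - 250 * ML_S) / (250 * ML_S) <= 1e-6
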