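"""Matched-pressure protocol, MOS labeling, and metric extraction."""

import numpy as np
import pytest

import rhinoflow as rf
from rhinoflow.errors import DomainError
from rhinoflow.flow import FlowSolution
from rhinoflow.geometry import Side, SubjectState, default_template
from rhinoflow.protocol import (
    NRScope,
    extract_subject_metrics,
    flow_partition,
    label_mos,
    nasal_resistance,
    plane_averages,
    regional_surface_heat_flux,
    run_subject_protocol,
)


def fake_flow(q_left, q_right, p_ch, r_left=0.0, r_right=0.0):
    return FlowSolution(
        outlet_pressure=p_ch - 1.0,
        choanal_pressure=p_ch,
        q_left=q_left,
        q_right=q_right,
        segment_pressure_drops={},
        converged=True,
        residual=0.0,
        metadata={"resistance_left": r_left, "resistance_right": r_right},
    )


class TestMosLabel:
    def test_smaller_flow_side_is_mos(self):
        flow = fake_flow(50.5e-6, 199.5e-6, -15.0)
        assert label_mos(flow) is Side.LEFT
        part = flow_partition(flow, Side.LEFT)
        assert part["partition_mos"] == pytest.approx(20.2, rel=1e-12)
        assert part["ratio_los_over_mos"] == pytest.approx(3.95, abs=0.01)

    def test_exact_tie_breaks_left(self):
        assert label_mos(fake_flow(1e-4, 1e-4, -10.0, 1.0, 1.0)) is Side.LEFT

    def test_tie_with_larger_right_resistance_breaks_right(self):
        assert label_mos(fake_flow(1e-4, 1e-4, -10.0, 1.0, 2.0)) is Side.RIGHT

    def test_label_frozen_when_postop_partition_crosses_half(self, ambient):
        # severe left deviation; overcorrection makes the left side wider after
        pre = default_template("s", SubjectState.PREOP, left_gap_factor=0.5)
        post = default_template("s", SubjectState.POSTOP, left_gap_factor=1.3)
        res = run_subject_protocol(pre, post, ambient, compute_transport=False)
        assert res.mos_side is Side.LEFT
        post_part = flow_partition(res.post.flow, res.mos_side)["partition_mos"]
        assert post_part > 50.0  # reported against the frozen preoperative label


class TestNasalResistance:
    def test_unilateral_arithmetic(self):
        flow = fake_flow(50e-6, 200e-6, -15.6)
        assert nasal_resistance(flow, NRScope.UNILATERAL_MOS, Side.LEFT) == pytest.approx(
            0.312, rel=1e-12
        )

    def test_symmetric_bilateral_is_half_unilateral(self, template):
        sol = rf.solve_bilateral_flow(template, -10.0)
        mos = label_mos(sol)
        uni = nasal_resistance(sol, NRScope.UNILATERAL_MOS, mos)
        bil = nasal_resistance(sol, NRScope.BILATERAL, mos)
        assert bil == pytest.approx(uni / 2, rel=1e-9)

    def test_linear_network_nr_independent_of_driving_pressure(self, template):
        mos = Side.LEFT
        nr = [
            nasal_resistance(rf.solve_bilateral_flow(template, p), NRScope.BILATERAL, mos)
            for p in (-5.0, -10.0)
        ]
        assert nr[0] == pytest.approx(nr[1], rel=1e-12)

    def test_bilateral_never_exceeds_either_unilateral(self, protocol_result):
        for sr in (protocol_result.pre, protocol_result.post):
            mos = protocol_result.mos_side
            bil = nasal_resistance(sr.flow, NRScope.BILATERAL, mos)
            assert bil <= nasal_resistance(sr.flow, NRScope.UNILATERAL_MOS, mos)
            assert bil <= nasal_resistance(sr.flow, NRScope.UNILATERAL_LOS, mos)

    def test_partitions_sum_to_hundred(self, protocol_result):
        flow = protocol_result.pre.flow
        mos = protocol_result.mos_side
        p_mos = flow_partition(flow, mos)["partition_mos"]
        p_los = flow_partition(flow, mos.other)["partition_mos"]
        assert p_mos + p_los == pytest.approx(100.0, rel=1e-12)


class TestProtocol:
    def test_identical_models_give_identical_metrics(self, ambient):
        pre = default_template("same", SubjectState.PREOP, left_gap_factor=0.8)
        post = default_template("same", SubjectState.POSTOP, left_gap_factor=0.8)
        res = run_subject_protocol(pre, post, ambient)
        m_pre = extract_subject_metrics(res, SubjectState.PREOP)
        m_post = extract_subject_metrics(res, SubjectState.POSTOP)
        assert m_pre.q_total_mL_s == pytest.approx(m_post.q_total_mL_s, rel=1e-12)
        assert m_pre.nr_unilateral_mos == pytest.approx(m_post.nr_unilateral_mos, rel=1e-12)
        assert m_pre.plane2_RH_pct == pytest.approx(m_post.plane2_RH_pct, rel=1e-12)

    def test_postop_flow_hits_protocol_target(self, protocol_result):
        assert abs(protocol_result.post.flow.q_total - 250e-6) / 250e-6 <= 1e-6

    def test_preop_solved_at_same_outlet_pressure_carries_less_flow(self, protocol_result):
        assert protocol_result.pre.flow.outlet_pressure == protocol_result.post.flow.outlet_pressure
        assert protocol_result.pre.flow.q_total < protocol_result.post.flow.q_total

    def test_mismatched_subjects_rejected(self, ambient):
        a = default_template("a", SubjectState.PREOP)
        b = default_template("b", SubjectState.POSTOP)
        with pytest.raises(DomainError):
            run_subject_protocol(a, b, ambient)

    def test_narrowing_mos_monotone_in_nr_and_partition(self, ambient):
        nr, part = [], []
        for gap in (0.8, 0.6, 0.4):
            model = default_template("m", SubjectState.PREOP, left_gap_factor=gap)
            sol = rf.solve_bilateral_flow(model, -10.0)
            nr.append(nasal_resistance(sol, NRScope.UNILATERAL_MOS, Side.LEFT))
            part.append(flow_partition(sol, Side.LEFT)["partition_mos"])
        assert nr[0] < nr[1] < nr[2]
        assert part[0] > part[1] > part[2]

    def test_widening_surgery_never_decreases_total_flow(self, ambient):
        pre = default_template("w", SubjectState.PREOP, left_gap_factor=0.5)
        post = default_template("w", SubjectState.POSTOP, left_gap_factor=1.0,
                                right_gap_factor=1.1)
        res = run_subject_protocol(pre, post, ambient, compute_transport=False)
        assert res.post.flow.q_total >= res.pre.flow.q_total


class TestHeatFluxAndPlanes:
    def test_dry_vestibule_latent_contribution_vanishes(self, protocol_result):
        tr = protocol_result.pre.transport
        mos = protocol_result.mos_side
        sens = regional_surface_heat_flux(tr, "AREA1", mos, include_latent=False)
        both = regional_surface_heat_flux(tr, "AREA1", mos, include_latent=True)
        assert both == sens

    def test_cavity_latent_dominates_sensible(self, protocol_result):
        tr = protocol_result.pre.transport
        for side in (Side.LEFT, Side.RIGHT, None):
            sens = regional_surface_heat_flux(tr, "AREA2", side, include_latent=False)
            both = regional_surface_heat_flux(tr, "AREA2", side, include_latent=True)
            assert both >= sens > 0.0

    def test_combined_region_is_area_weighted_mean(self, protocol_result):
        tr = protocol_result.pre.transport
        mos = protocol_result.mos_side
        from rhinoflow.geometry import region_surface_areas

        surf = region_surface_areas(protocol_result.pre.model, mos)
        q1 = regional_surface_heat_flux(tr, "AREA1", mos, False)
        q2 = regional_surface_heat_flux(tr, "AREA2", mos, False)
        expected = (q1 * surf["AREA1"] + q2 * surf["AREA2"]) / (surf["AREA1"] + surf["AREA2"])
        q12 = regional_surface_heat_flux(tr, "AREA1+AREA2", mos, False)
        assert q12 == pytest.approx(expected, rel=1e-9)

    def test_unknown_region_rejected(self, protocol_result):
        with pytest.raises(DomainError):
            regional_surface_heat_flux(protocol_result.pre.transport, "AREA9", None, False)

    def test_plane2_temperature_between_plane1_values(self, protocol_result):
        planes = plane_averages(protocol_result.pre.transport)
        t1 = sorted([planes["plane1_left"]["temperature_C"], planes["plane1_right"]["temperature_C"]])
        assert t1[0] <= planes["plane2"]["temperature_C"] <= t1[1]

    def test_no_wall_exchange_leaves_air_at_ambient(self, subject_pair, ambient):
        from rhinoflow.conditioning import MoistAirState, integrate_segment_transport

        seg = subject_pair[0].left_path[2]
        inlet = MoistAirState.from_relative_humidity(25.0, 0.35, 1e-4)
        outlet, _ = integrate_segment_transport(
            inlet, seg, 1e-4, ambient, fixed_coefficients=(0.0, 0.0)
        )
        assert outlet.temperature == 25.0
        assert outlet.relative_humidity == pytest.approx(0.35, abs=1e-12)

    def test_faster_postop_transit_reduces_plane2_conditioning(self, small_cohort):
        """When surgery raises total flow, Plane-2 RH must not rise."""
        pre = small_cohort.state_frame("PREOP")
        post = small_cohort.state_frame("POSTOP")
        faster = post["q_total_mL_s"].to_numpy() > pre["q_total_mL_s"].to_numpy()
        drop = post["plane2_RH_pct"].to_numpy() <= pre["plane2_RH_pct"].to_numpy()
        assert np.all(drop[faster])


class TestMetricsRecord:
    def test_row_units_and_invariants(self, protocol_result):
        m = extract_subject_metrics(protocol_result, SubjectState.PREOP)
        row = m.to_row()
        assert row["nr_unilateral_mos_Pa_per_mL_s"] == m.nr_unilateral_mos
        assert m.flow_partition_mos_pct <= 50.0  # preoperative MOS definition
        ratio = (100.0 - m.flow_partition_mos_pct) / m.flow_partition_mos_pct
        assert m.partition_ratio_los_over_mos == pytest.approx(ratio, rel=1e-9)
        assert m.nr_bilateral <= min(m.nr_unilateral_mos, m.nr_unilateral_los)
        assert row["q_sensible_plus_latent_area2_mos_W_m2"] >= row["q_sensible_area2_mos_W_m2"]
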