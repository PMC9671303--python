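"""The matched trans-nasal pressure-drop comparison protocol and its metrics.

Pre- and postoperative models of one subject are compared at the *same
breathing effort*: the outlet pressure is calibrated so the postoperative
model carries a target bilateral flow (250 mL/s by default) and that same
pressure is then imposed on the preoperative model.  From the two solved
states the clinical metric set is extracted:

* unilateral nasal resistance (NR) per side, nostril → choanae, Pa/(mL·s);
* bilateral NR, inlet → choanae;
* flow partition at the nostrils and the LOS/MOS flow ratio;
* mass-weighted Plane-1 (per side) and Plane-2 temperature and RH;
* region-resolved mean wall heat flux, sensible and sensible+latent.

The more obstructed side (MOS) is labeled on the *preoperative* solution —
the side carrying the smaller flow fraction — and the label is frozen for
postoperative reporting even if the partition later crosses 50 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .ambient import AmbientConditions
from .conditioning import MoistAirState, TransportSolution, solve_transport
from .errors import DomainError
from .flow import (
    TARGET_FLOW_DEFAULT,
    FlowSolution,
    MinorLossModel,
    calibrate_outlet_pressure,
    solve_bilateral_flow,
)
from .geometry import BilateralAirwayModel, Region, Side, SubjectState

__all__ = [
    "NRScope",
    "StateResult",
    "ProtocolResult",
    "SubjectMetrics",
    "run_subject_protocol",
    "label_mos",
    "nasal_resistance",
    "flow_partition",
    "regional_surface_heat_flux",
    "plane_averages",
    "extract_subject_metrics",
    "PA_PER_ML_S",
]

#: 1 Pa/(mL·s) expressed in SI resistance units (Pa·s/m³).
PA_PER_ML_S = 1e6

_REGION_SETS: Mapping[str, tuple[Region, ...]] = {
    "AREA1": (Region.AREA1_VESTIBULE,),
    "AREA2": (Region.AREA2_CAVITY,),
    "AREA1+AREA2": (Region.AREA1_VESTIBULE, Region.AREA2_CAVITY),
}


class NRScope:
    UNILATERAL_MOS = "UNILATERAL_MOS"
    UNILATERAL_LOS = "UNILATERAL_LOS"
    BILATERAL = "BILATERAL"


@dataclass(frozen=True)
class StateResult:
    """Flow and transport solutions for one subject state."""

    model: BilateralAirwayModel
    flow: FlowSolution
    transport: TransportSolution | None


@dataclass(frozen=True)
class ProtocolResult:
    """Both states solved under the common calibrated outlet pressure."""

    pre: StateResult
    post: StateResult
    outlet_pressure: float
    target_flow: float
    mos_side: Side


def label_mos(pre_flow: FlowSolution) -> Side:
    """More obstructed side from the *preoperative* solution.

    The MOS carries the smaller flow fraction; a tie goes to the side with
    the larger unilateral NR, and a second tie to LEFT.  The label is frozen
    for postoperative reporting.
    """
    if pre_flow.q_left < pre_flow.q_right:
        return Side.LEFT
    if pre_flow.q_right < pre_flow.q_left:
        return Side.RIGHT
    r_left = pre_flow.metadata.get("resistance_left", 0.0)
    r_right = pre_flow.metadata.get("resistance_right", 0.0)
    if r_right > r_left:
        return Side.RIGHT
    return Side.LEFT


def nasal_resistance(flow: FlowSolution, scope: str, mos_side: Side) -> float:
    """Nasal resistance in Pa/(mL·s) for the requested scope.

    Unilateral NR is (0 − p_choanae)/q_side between nostril and choanae;
    bilateral NR is (0 − p_choanae)/q_total between the inlet chamber and
    the choanae.  With a zero-resistance inlet chamber both references
    coincide at 0 gauge.
    """
    dp = -flow.choanal_pressure
    if scope == NRScope.BILATERAL:
        q = flow.q_total
    elif scope == NRScope.UNILATERAL_MOS:
        q = flow.q_side(mos_side)
    elif scope == NRScope.UNILATERAL_LOS:
        q = flow.q_side(mos_side.other)
    else:
        raise DomainError(f"unknown NR scope {scope!r}")
    if q <= 0.0:
        raise DomainError(f"zero flow in scope {scope}; NR undefined")
    return (dp / q) / PA_PER_ML_S


def flow_partition(flow: FlowSolution, mos_side: Side) -> dict[str, float]:
    """MOS flow partition (%) at the nostrils and the LOS/MOS flow ratio."""
    if flow.q_total <= 0.0:
        raise DomainError("total flow is zero; partition undefined")
    q_mos = flow.q_side(mos_side)
    if q_mos <= 0.0:
        raise DomainError("MOS carries no flow; LOS/MOS ratio undefined")
    return {
        "partition_mos": 100.0 * q_mos / flow.q_total,
        "ratio_los_over_mos": flow.q_side(mos_side.other) / q_mos,
    }


def regional_surface_heat_flux(
    transport: TransportSolution,
    region: str,
    side: Side | None,
    include_latent: bool,
) -> float:
    """Area-weighted mean wall heat flux (W/m²) over a region selection.

    ``region`` is one of ``"AREA1"``, ``"AREA2"``, ``"AREA1+AREA2"``;
    ``side=None`` pools both sides with surface-area weights.
    """
    if region not in _REGION_SETS:
        raise DomainError(f"unknown region {region!r}")
    qs, ql, wt = transport.wall_nodes(_REGION_SETS[region], side)
    if wt.size == 0 or wt.sum() == 0.0:
        raise DomainError(f"empty region selection {region}/{side}")
    flux = qs + ql if include_latent else qs
    return float(np.dot(flux, wt) / wt.sum())


def plane_averages(transport: TransportSolution) -> dict[str, dict[str, float]]:
    """Plane-1 (per side) and Plane-2 temperature (°C) and RH (%)."""

    def fmt(state: MoistAirState) -> dict[str, float]:
        return {
            "temperature_C": state.temperature,
            "rh_percent": 100.0 * state.relative_humidity,
        }

    return {
        "plane1_left": fmt(transport.plane1[Side.LEFT]),
        "plane1_right": fmt(transport.plane1[Side.RIGHT]),
        "plane2": fmt(transport.plane2),
    }


def run_subject_protocol(
    preop: BilateralAirwayModel,
    postop: BilateralAirwayModel,
    ambient: AmbientConditions | None = None,
    target_flow: float = TARGET_FLOW_DEFAULT,
    minor_losses: MinorLossModel | None = None,
    compute_transport: bool = True,
    n_steps: int = 100,
) -> ProtocolResult:
    """Run the matched-pressure protocol for one subject.

    The outlet pressure is calibrated on the *postoperative* model to reach
    ``target_flow`` and then imposed unchanged on the preoperative model, so
    the preoperative airway — being more resistive — carries less total flow
    at the same breathing effort.
    """
    if preop.subject_id != postop.subject_id:
        raise DomainError(
            f"protocol pairs one subject: got {preop.subject_id!r} and {postop.subject_id!r}"
        )
    ambient = ambient or AmbientConditions()
    ambient.validate()
    props = ambient.air
    p_out = calibrate_outlet_pressure(postop, target_flow, props, minor_losses)
    post_flow = solve_bilateral_flow(postop, p_out, props, minor_losses)
    pre_flow = solve_bilateral_flow(preop, p_out, props, minor_losses)
    mos = label_mos(pre_flow)
    pre_tr = post_tr = None
    if compute_transport:
        pre_tr = solve_transport(preop, pre_flow, ambient, n_steps)
        post_tr = solve_transport(postop, post_flow, ambient, n_steps)
    return ProtocolResult(
        pre=StateResult(preop, pre_flow, pre_tr),
        post=StateResult(postop, post_flow, post_tr),
        outlet_pressure=p_out,
        target_flow=target_flow,
        mos_side=mos,
    )


@dataclass(frozen=True)
class SubjectMetrics:
    """Per-state metric record for one subject (flat, CSV-serializable).

    Heat-flux keys are ``(region, side_label, kind)`` with region in
    {AREA1, AREA2, AREA1+AREA2}, side_label in {MOS, LOS, BOTH} and kind in
    {sensible, sensible+latent}; values in W/m².
    """

    subject_id: str
    state: SubjectState
    mos_side: Side
    q_total_mL_s: float
    outlet_pressure_Pa: float
    flow_partition_mos_pct: float
    partition_ratio_los_over_mos: float
    nr_unilateral_mos: float  # Pa/(mL·s)
    nr_unilateral_los: float
    nr_bilateral: float
    nr_ratio_mos_over_los: float
    plane1_mos_T_C: float | None = None
    plane1_mos_RH_pct: float | None = None
    plane1_los_T_C: float | None = None
    plane1_los_RH_pct: float | None = None
    plane2_T_C: float | None = None
    plane2_RH_pct: float | None = None
    heat_flux: dict = field(default_factory=dict)
    nose: int | None = None

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "state": self.state.value,
            "mos_side": self.mos_side.value,
            "q_total_mL_s": self.q_total_mL_s,
            "outlet_pressure_Pa": self.outlet_pressure_Pa,
            "flow_partition_mos_pct": self.flow_partition_mos_pct,
            "partition_ratio_los_over_mos": self.partition_ratio_los_over_mos,
            "nr_unilateral_mos_Pa_per_mL_s": self.nr_unilateral_mos,
            "nr_unilateral_los_Pa_per_mL_s": self.nr_unilateral_los,
            "nr_bilateral_Pa_per_mL_s": self.nr_bilateral,
            "nr_ratio_mos_over_los": self.nr_ratio_mos_over_los,
            "plane1_mos_T_C": self.plane1_mos_T_C,
            "plane1_mos_RH_pct": self.plane1_mos_RH_pct,
            "plane1_los_T_C": self.plane1_los_T_C,
            "plane1_los_RH_pct": self.plane1_los_RH_pct,
            "plane2_T_C": self.plane2_T_C,
            "plane2_RH_pct": self.plane2_RH_pct,
            "nose": self.nose,
        }
        for (region, side_label, kind), value in self.heat_flux.items():
            kind_tag = kind.replace("+", "_plus_")
            region_tag = region.replace("+", "_").lower()
            row[f"q_{kind_tag}_{region_tag}_{side_label.lower()}_W_m2"] = value
        return row


def _heat_flux_table(
    transport: TransportSolution, mos: Side
) -> dict[tuple[str, str, str], float]:
    table: dict[tuple[str, str, str], float] = {}
    for region in _REGION_SETS:
        for side_label, side in (("MOS", mos), ("LOS", mos.other), ("BOTH", None)):
            for kind, latent in (("sensible", False), ("sensible+latent", True)):
                table[(region, side_label, kind)] = regional_surface_heat_flux(
                    transport, region, side, latent
                )
    return table


def extract_subject_metrics(
    result: ProtocolResult, state: SubjectState
) -> SubjectMetrics:
    """Assemble the full metric record for one state of a protocol run."""
    sr = result.pre if state is SubjectState.PREOP else result.post
    mos = result.mos_side
    part = flow_partition(sr.flow, mos)
    nr_mos = nasal_resistance(sr.flow, NRScope.UNILATERAL_MOS, mos)
    nr_los = nasal_resistance(sr.flow, NRScope.UNILATERAL_LOS, mos)
    metrics = dict(
        subject_id=sr.model.subject_id,
        state=state,
        mos_side=mos,
        q_total_mL_s=sr.flow.q_total * 1e6,
        outlet_pressure_Pa=result.outlet_pressure,
        flow_partition_mos_pct=part["partition_mos"],
        partition_ratio_los_over_mos=part["ratio_los_over_mos"],
        nr_unilateral_mos=nr_mos,
        nr_unilateral_los=nr_los,
        nr_bilateral=nasal_resistance(sr.flow, NRScope.BILATERAL, mos),
        nr_ratio_mos_over_los=nr_mos / nr_los,
    )
    if sr.transport is not None:
        planes = plane_averages(sr.transport)
        p1_mos = planes["plane1_left"] if mos is Side.LEFT else planes["plane1_right"]
        p1_los = planes["plane1_right"] if mos is Side.LEFT else planes["plane1_left"]
        metrics.update(
            plane1_mos_T_C=p1_mos["temperature_C"],
            plane1_mos_RH_pct=p1_mos["rh_percent"],
            plane1_los_T_C=p1_los["temperature_C"],
            plane1_los_RH_pct=p1_los["rh_percent"],
            plane2_T_C=planes["plane2"]["temperature_C"],
            plane2_RH_pct=planes["plane2"]["rh_percent"],
            heat_flux=_heat_flux_table(sr.transport, mos),
        )
    return SubjectMetrics(**metrics)
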