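"""Steady laminar flow through the bilateral airway network.

Each segment contributes a fully developed laminar viscous pressure drop

    ΔP(Q) = Q · ∫ fRe·μ / (2·Dh(x)²·A(x)) dx ,

with fRe = 64 for circular ducts and 96 for parallel-plate slits.  For a
uniform circular duct this reduces exactly to Hagen–Poiseuille
(128·μ·L·Q/(π·D⁴)) and for a wide slit to the cubic-gap law 12·μ·L·Q/(g³·W).
Inspiration is pressure-driven: the inlet sits at 0 gauge, a negative outlet
pressure is imposed at the nasopharynx, and the two sides meet at a common
choanal junction pressure.

With the default (purely viscous) model every resistance is linear in Q and
the network is solved in closed form.  Optional minor losses (entrance
contraction, Borda–Carnot expansions) make the side pressure drops quadratic
in Q; the solver then switches to a damped Newton iteration on the two side
flows.  Nasal resistance uses static gauge pressures (inlet chamber 0,
choanal junction p_ch); dynamic-pressure corrections are deliberately
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ambient import AIR_25C, AirProperties
from .errors import CalibrationError, ConvergenceError, InvalidGeometryError
from .geometry import (
    AirwaySegment,
    BilateralAirwayModel,
    CrossSection,
    validate_airway,
)

__all__ = [
    "FRICTION_FACTOR_RE",
    "MinorLossModel",
    "FlowSolution",
    "segment_resistance",
    "segment_viscous_resistance",
    "path_resistance",
    "solve_linear_network",
    "solve_bilateral_flow",
    "calibrate_outlet_pressure",
    "TARGET_FLOW_DEFAULT",
]

FRICTION_FACTOR_RE = {CrossSection.CIRCULAR: 64.0, CrossSection.SLIT: 96.0}

#: Protocol target for the calibrated post-operative bilateral flow (m³/s).
TARGET_FLOW_DEFAULT = 250e-6

_QUAD_PANELS = 64


@dataclass(frozen=True)
class MinorLossModel:
    """Optional lumped losses added on top of viscous friction.

    ``entrance_k`` applies ½·K·ρ·v² at the first segment of each unilateral
    path; Borda–Carnot terms ½·(1 − A_up/A_down)²·ρ·v_up² apply at every
    abrupt area increase between consecutive segments.  Both make the side
    characteristic quadratic in Q.
    """

    entrance_k: float = 0.5
    borda_carnot: bool = True


def segment_resistance(
    segment: AirwaySegment,
    properties: AirProperties = AIR_25C,
    n_panels: int = _QUAD_PANELS,
) -> float:
    """Linear viscous resistance ΔP/Q of one segment (Pa·s/m³).

    Composite-Simpson quadrature of fRe·μ/(2·Dh²·A) along the segment; exact
    for uniform cross-sections and accurate to O(h⁴) under linear taper.
    """
    bad = segment.violations()
    if bad:
        raise InvalidGeometryError("; ".join(bad))
    f_re = FRICTION_FACTOR_RE[segment.cross_section_kind]
    mu = properties.dynamic_viscosity
    n = max(2, n_panels + (n_panels % 2))
    xs = np.linspace(0.0, 1.0, n + 1)
    area = segment.area_in + (segment.area_out - segment.area_in) * xs
    per = segment.perimeter_in + (segment.perimeter_out - segment.perimeter_in) * xs
    dh = 4.0 * area / per
    integrand = f_re * mu / (2.0 * dh**2 * area)
    weights = np.ones(n + 1)
    weights[1:-1:2] = 4.0
    weights[2:-1:2] = 2.0
    return float(segment.length / n / 3.0 * np.dot(weights, integrand))


def segment_viscous_resistance(
    segment: AirwaySegment,
    flow_rate: float,
    properties: AirProperties = AIR_25C,
) -> float:
    """Viscous pressure drop (Pa) across one segment at flow ``flow_rate``."""
    if flow_rate < 0.0:
        raise ValueError("flow_rate must be non-negative")
    return segment_resistance(segment, properties) * flow_rate


def path_resistance(
    path: Sequence[AirwaySegment], properties: AirProperties = AIR_25C
) -> float:
    """Series viscous resistance of an ordered segment list (Pa·s/m³)."""
    return sum(segment_resistance(s, properties) for s in path)


def _path_minor_coeff(
    path: Sequence[AirwaySegment],
    properties: AirProperties,
    losses: MinorLossModel,
    is_inlet_path: bool,
) -> float:
    """Quadratic coefficient k such that ΔP_minor = k·Q² (Pa·s²/m⁶)."""
    rho = properties.density
    k = 0.0
    if is_inlet_path and losses.entrance_k > 0.0:
        k += 0.5 * losses.entrance_k * rho / path[0].area_in**2
    if losses.borda_carnot:
        for up, down in zip(path[:-1], path[1:]):
            a_up, a_down = up.area_out, down.area_in
            if a_down > a_up:
                k += 0.5 * rho * (1.0 - a_up / a_down) ** 2 / a_up**2
    return k


@dataclass(frozen=True)
class FlowSolution:
    """Pressures, per-side flows, and the per-segment pressure-drop ledger."""

    outlet_pressure: float  # Pa gauge, at the nasopharyngeal outlet
    choanal_pressure: float  # Pa gauge, common junction pressure
    q_left: float  # m³/s
    q_right: float  # m³/s
    segment_pressure_drops: dict[str, float]
    converged: bool
    residual: float
    metadata: dict = field(default_factory=dict)

    @property
    def q_total(self) -> float:
        return self.q_left + self.q_right

    def q_side(self, side) -> float:
        from .geometry import Side

        return self.q_left if side is Side.LEFT else self.q_right


def solve_linear_network(
    r_left: float, r_right: float, r_shared: float, outlet_pressure: float
) -> tuple[float, float, float]:
    """Closed-form series/parallel solution: (q_left, q_right, p_choanae).

    Resistances in Pa·s/m³, pressures in Pa gauge (inlet at 0).
    """
    r_par = r_left * r_right / (r_left + r_right)
    q_total = -outlet_pressure / (r_par + r_shared)
    p_ch = -q_total * r_par
    return -p_ch / r_left, -p_ch / r_right, p_ch


def _ledger(
    model: BilateralAirwayModel,
    q_left: float,
    q_right: float,
    properties: AirProperties,
) -> dict[str, float]:
    drops: dict[str, float] = {}
    for path, q in (
        (model.left_path, q_left),
        (model.right_path, q_right),
        (model.shared_path, q_left + q_right),
    ):
        for seg in path:
            drops[seg.label] = segment_resistance(seg, properties) * q
    return drops


def solve_bilateral_flow(
    model: BilateralAirwayModel,
    outlet_pressure: float,
    properties: AirProperties = AIR_25C,
    minor_losses: MinorLossModel | None = None,
    max_iter: int = 200,
    rtol: float = 1e-10,
) -> FlowSolution:
    """Solve for the two side flows under an imposed outlet gauge pressure.

    ``outlet_pressure`` must be ≤ 0 (inspiration).  Purely viscous networks
    are solved directly; with minor losses a damped Newton iteration on
    (q_left, q_right) runs to relative residual ≤ ``rtol``.
    """
    bad = validate_airway(model)
    if bad:
        raise InvalidGeometryError("; ".join(bad))
    if outlet_pressure > 0.0:
        raise ValueError("outlet_pressure must be ≤ 0 gauge for inspiration")

    r_l = path_resistance(model.left_path, properties)
    r_r = path_resistance(model.right_path, properties)
    r_s = path_resistance(model.shared_path, properties)
    meta = {
        "pressure_drop_model": "viscous" if minor_losses is None else "viscous+minor",
        "resistance_left": r_l,
        "resistance_right": r_r,
        "resistance_shared": r_s,
    }

    if outlet_pressure == 0.0:
        return FlowSolution(0.0, 0.0, 0.0, 0.0, _ledger(model, 0.0, 0.0, properties), True, 0.0, meta)

    if minor_losses is None:
        q_l, q_r, p_ch = solve_linear_network(r_l, r_r, r_s, outlet_pressure)
        return FlowSolution(
            outlet_pressure, p_ch, q_l, q_r,
            _ledger(model, q_l, q_r, properties), True, 0.0, meta,
        )

    k_l = _path_minor_coeff(model.left_path, properties, minor_losses, True)
    k_r = _path_minor_coeff(model.right_path, properties, minor_losses, True)
    k_s = _path_minor_coeff(model.shared_path, properties, minor_losses, False)

    def residuals(q: np.ndarray) -> np.ndarray:
        ql, qr = q
        qt = ql + qr
        dp_s = r_s * qt + k_s * qt * abs(qt)
        return np.array(
            [
                r_l * ql + k_l * ql * abs(ql) + dp_s + outlet_pressure,
                r_r * qr + k_r * qr * abs(qr) + dp_s + outlet_pressure,
            ]
        )

    def jacobian(q: np.ndarray) -> np.ndarray:
        ql, qr = q
        qt = ql + qr
        d_s = r_s + 2.0 * k_s * abs(qt)
        return np.array(
            [[r_l + 2.0 * k_l * abs(ql) + d_s, d_s],
             [d_s, r_r + 2.0 * k_r * abs(qr) + d_s]]
        )

    scale = abs(outlet_pressure)
    q = np.array(solve_linear_network(r_l, r_r, r_s, outlet_pressure)[:2])
    res = residuals(q)
    history = [float(np.max(np.abs(res)) / scale)]
    converged = False
    for _ in range(max_iter):
        if history[-1] <= rtol:
            converged = True
            break
        step = np.linalg.solve(jacobian(q), res)
        damping = 1.0
        while damping >= 1e-6:
            trial = q - damping * step
            trial_res = residuals(trial)
            if np.max(np.abs(trial_res)) < np.max(np.abs(res)):
                q, res = trial, trial_res
                break
            damping *= 0.5  # halve on divergence
        else:
            break
        history.append(float(np.max(np.abs(res)) / scale))
    else:
        converged = history[-1] <= rtol
    if not converged:
        raise ConvergenceError(
            f"flow solve did not reach rtol={rtol} (last residual {history[-1]:.3e})",
            residual_history=history,
        )
    q_l, q_r = float(q[0]), float(q[1])
    qt = q_l + q_r
    p_ch = outlet_pressure + r_s * qt + k_s * qt * abs(qt)
    return FlowSolution(
        outlet_pressure, p_ch, q_l, q_r,
        _ledger(model, q_l, q_r, properties), True, history[-1], meta,
    )


def calibrate_outlet_pressure(
    model: BilateralAirwayModel,
    target_flow: float = TARGET_FLOW_DEFAULT,
    properties: AirProperties = AIR_25C,
    minor_losses: MinorLossModel | None = None,
    rtol: float = 1e-9,
    max_pressure: float = 5000.0,
) -> float:
    """Outlet gauge pressure (Pa) that yields ``target_flow`` through the model.

    This implements the matched-effort comparison protocol: the pressure is
    calibrated on the post-operative model and then *reused unchanged* on the
    pre-operative model, so both are driven by the same trans-nasal pressure
    drop.  For linear networks the answer is direct (ΔP = R·Q); otherwise a
    bracketed bisection with a secant polish runs to |q − target| ≤ rtol·target.
    """
    if target_flow < 0.0:
        raise ValueError("target_flow must be non-negative")
    if target_flow == 0.0:
        return 0.0
    r_total = (
        path_resistance(model.left_path, properties)
        * path_resistance(model.right_path, properties)
        / (path_resistance(model.left_path, properties) + path_resistance(model.right_path, properties))
        + path_resistance(model.shared_path, properties)
    )
    if minor_losses is None:
        return -r_total * target_flow

    def total_flow(p_out: float) -> float:
        return solve_bilateral_flow(model, p_out, properties, minor_losses).q_total

    # bracket around the linear estimate
    lo, hi = -r_total * target_flow * 2.0, -r_total * target_flow * 0.25
    for _ in range(60):
        if total_flow(lo) >= target_flow:
            break
        lo *= 2.0
        if -lo > max_pressure:
            raise CalibrationError(
                f"no outlet pressure within ±{max_pressure} Pa reaches "
                f"{target_flow * 1e6:.1f} mL/s"
            )
    a, b = lo, hi  # q(a) >= target >= q(b); q decreasing in p_out
    fa, fb = total_flow(a) - target_flow, total_flow(b) - target_flow
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = total_flow(mid) - target_flow
        if abs(fm) <= rtol * target_flow:
            return mid
        if (fa > 0.0) == (fm > 0.0):
            a, fa = mid, fm
        else:
            b, fb = mid, fm
        # secant polish once the bracket is tight
        if abs(b - a) < 1e-3 * abs(b):
            p = b - fb * (b - a) / (fb - fa)
            if min(a, b) < p < max(a, b) and abs(total_flow(p) - target_flow) <= rtol * target_flow:
                return p
    raise CalibrationError("outlet-pressure calibration did not converge")
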