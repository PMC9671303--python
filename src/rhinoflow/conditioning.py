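"""Bulk heat and water-vapor transport along the airway.

The model carries one bulk (mixed-mean) state per streamwise station:
temperature T(x) and specific humidity w(x), driven by wall exchange

    ṁ·c_p·dT/dx   = h(x)·P(x)·(T_wall − T)
    ṁ_dry·dw/dx   = h_m(x)·ρ·P(x)·(w_sat(T_wall) − w)      (wet walls only)

with a fixed mucosal wall temperature.  Local transfer coefficients come
from the thermally developing laminar (Graetz) problem via the Hausen
correlation, with the mass-transfer coefficient tied to the heat-transfer
one by the Chilton–Colburn analogy.  The streamwise coordinate for the
entrance effect accumulates from the nostril, one developing boundary layer
per passage.

Wall fluxes are reported per unit wetted area: q_sensible = h·(T_wall − T)
everywhere, and q_latent = h_m·ρ·(w_sat(T_wall) − w)·L_v on wet walls only —
the vestibule's squamous lining exchanges no water, so its latent flux is
identically zero.  The bulk energy balance tracks sensible exchange only;
the enthalpy carried into the airstream by added vapor (≲1 % of the air
enthalpy flux) is neglected, so latent heat appears solely as the reported
wall-side flux.

Saturation vapor pressure uses the Arden Buck form throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .ambient import AirProperties, AmbientConditions
from .errors import DomainError, TransportIntegrityError
from .flow import FlowSolution
from .geometry import (
    AirwaySegment,
    BilateralAirwayModel,
    CrossSection,
    Region,
    Side,
    derive_segment_geometry,
)

__all__ = [
    "saturation_vapor_pressure",
    "specific_humidity_from_rh",
    "rh_from_specific_humidity",
    "MoistAirState",
    "local_transfer_coefficients",
    "integrate_segment_transport",
    "mix_streams_at_choanae",
    "SegmentTransport",
    "TransportSolution",
    "solve_transport",
    "NU_FULLY_DEVELOPED",
]

#: Fully developed laminar Nusselt numbers at constant wall temperature.
NU_FULLY_DEVELOPED = {CrossSection.CIRCULAR: 3.66, CrossSection.SLIT: 7.54}

#: Floor on the entrance-length coordinate (m); the Graetz similarity
#: solution is singular at x = 0.
_X_ENTRANCE_FLOOR = 1e-4

_RH_TOLERANCE = 1e-6


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapor pressure over liquid water (Pa), Arden Buck form.

    e_s(T) = 611.21 · exp(17.502·T / (240.97 + T)), T in °C, valid for the
    physiological range; outside [−20, 60] °C the fit is not trusted and a
    :class:`DomainError` is raised.
    """
    if not -20.0 <= temperature <= 60.0:
        raise DomainError(f"temperature {temperature} °C outside Buck-fit range [-20, 60]")
    return 611.21 * math.exp(17.502 * temperature / (240.97 + temperature))


def specific_humidity_from_rh(
    temperature: float, relative_humidity: float, pressure: float = 101325.0
) -> float:
    """w = 0.622·e/(p − e) with e = RH·e_s(T); kg vapor per kg dry air."""
    if relative_humidity < 0.0 or relative_humidity > 1.0 + _RH_TOLERANCE:
        raise DomainError(f"relative humidity {relative_humidity} outside [0, 1]")
    e = relative_humidity * saturation_vapor_pressure(temperature)
    if pressure <= e:
        raise DomainError("total pressure must exceed the vapor pressure")
    return 0.622 * e / (pressure - e)


def rh_from_specific_humidity(
    temperature: float, specific_humidity: float, pressure: float = 101325.0
) -> float:
    """Inverse of :func:`specific_humidity_from_rh`; exact round-trip."""
    if specific_humidity < 0.0:
        raise DomainError("specific humidity must be non-negative")
    e = pressure * specific_humidity / (0.622 + specific_humidity)
    return e / saturation_vapor_pressure(temperature)


@dataclass(frozen=True)
class MoistAirState:
    """Bulk moist-air state at one station.

    ``mass_flow_dry_air`` is the dry-air mass flow carrying the state; the
    vapor content rides on it as specific humidity w (kg vapor / kg dry air).
    """

    temperature: float  # °C
    specific_humidity: float  # kg/kg
    mass_flow_dry_air: float  # kg/s
    pressure: float = 101325.0  # Pa absolute

    @property
    def relative_humidity(self) -> float:
        return rh_from_specific_humidity(
            self.temperature, self.specific_humidity, self.pressure
        )

    @classmethod
    def from_relative_humidity(
        cls,
        temperature: float,
        relative_humidity: float,
        mass_flow_dry_air: float,
        pressure: float = 101325.0,
    ) -> "MoistAirState":
        return cls(
            temperature,
            specific_humidity_from_rh(temperature, relative_humidity, pressure),
            mass_flow_dry_air,
            pressure,
        )


def ambient_inlet_state(ambient: AmbientConditions, mass_flow_dry_air: float) -> MoistAirState:
    """Inhaled-air state at the nostril for a given dry-air mass flow."""
    return MoistAirState.from_relative_humidity(
        ambient.temperature, ambient.relative_humidity, mass_flow_dry_air, ambient.pressure
    )


def local_transfer_coefficients(
    segment: AirwaySegment,
    x_fraction: float,
    x_from_nostril: float,
    flow_rate: float,
    properties: AirProperties,
) -> tuple[float, float]:
    """Local (h, h_m): heat (W/(m²·K)) and mass (m/s) transfer coefficients.

    Thermally developing laminar flow at constant wall temperature:
    Gz = Dh·Re·Pr/x, Nu = Nu_∞ + 0.0668·Gz/(1 + 0.04·Gz^(2/3)) (Hausen),
    then Sh = Nu·(Sc/Pr)^(1/3) (Chilton–Colburn) and h_m = Sh·D_v/Dh.
    """
    if flow_rate <= 0.0:
        raise DomainError("flow_rate must be positive")
    geo = derive_segment_geometry(segment, x_fraction)
    x = max(x_from_nostril, _X_ENTRANCE_FLOOR)
    re = properties.density * flow_rate * geo.hydraulic_diameter / (
        geo.area * properties.dynamic_viscosity
    )
    gz = geo.hydraulic_diameter * re * properties.prandtl / x
    nu_inf = NU_FULLY_DEVELOPED[segment.cross_section_kind]
    nu = nu_inf + 0.0668 * gz / (1.0 + 0.04 * gz ** (2.0 / 3.0))
    h = nu * properties.thermal_conductivity / geo.hydraulic_diameter
    sh = nu * (properties.schmidt / properties.prandtl) ** (1.0 / 3.0)
    h_m = sh * properties.vapor_diffusivity / geo.hydraulic_diameter
    return h, h_m


@dataclass(frozen=True)
class SegmentTransport:
    """Sampled transport profile along one segment (node arrays)."""

    label: str
    region: Region
    side: Side | None  # None on the shared path
    wall_is_wet: bool
    x_from_nostril: np.ndarray  # m, at nodes
    temperature: np.ndarray  # °C
    specific_humidity: np.ndarray  # kg/kg
    relative_humidity: np.ndarray  # fraction
    q_sensible: np.ndarray  # W/m²
    q_latent: np.ndarray  # W/m²
    wall_weights: np.ndarray  # m², wetted-area weight per node (sums to surface)


def integrate_segment_transport(
    inlet: MoistAirState,
    segment: AirwaySegment,
    flow_rate: float,
    ambient: AmbientConditions,
    x_offset: float = 0.0,
    side: Side | None = None,
    n_steps: int = 100,
    fixed_coefficients: tuple[float, float] | None = None,
) -> tuple[MoistAirState, SegmentTransport]:
    """March the bulk state through one segment with fixed-step RK4.

    ``fixed_coefficients`` pins (h, h_m) to constants, which turns the system
    into the closed-form exponential relaxation used as the numerical oracle.
    Raises :class:`TransportIntegrityError` if RH exceeds saturation beyond
    tolerance during the march.
    """
    if flow_rate <= 0.0:
        raise DomainError("flow_rate must be positive")
    if n_steps < 1:
        raise DomainError("n_steps must be ≥ 1")
    props = ambient.air
    t_wall = ambient.wall_temperature
    m_dry = inlet.mass_flow_dry_air
    m_air = props.density * flow_rate  # bulk mixture mass flow
    wet = segment.wall_is_wet
    w_wall = specific_humidity_from_rh(t_wall, 1.0, inlet.pressure)

    def coeffs(x_frac: float) -> tuple[float, float, float]:
        geo = derive_segment_geometry(segment, x_frac)
        if fixed_coefficients is not None:
            h, h_m = fixed_coefficients
        else:
            h, h_m = local_transfer_coefficients(
                segment, x_frac, x_offset + x_frac * segment.length, flow_rate, props
            )
        return h, h_m, geo.perimeter

    def rhs(x_frac: float, y: np.ndarray) -> np.ndarray:
        h, h_m, per = coeffs(x_frac)
        dt = h * per * (t_wall - y[0]) / (m_air * props.specific_heat)
        dw = h_m * props.density * per * (w_wall - y[1]) / m_dry if wet else 0.0
        return np.array([dt, dw])

    dxf = 1.0 / n_steps
    dx = segment.length * dxf
    y = np.array([inlet.temperature, inlet.specific_humidity])
    n_nodes = n_steps + 1
    temp = np.empty(n_nodes)
    hum = np.empty(n_nodes)
    rh = np.empty(n_nodes)
    q_sens = np.empty(n_nodes)
    q_lat = np.empty(n_nodes)
    per_nodes = np.empty(n_nodes)

    def record(i: int, x_frac: float) -> None:
        h, h_m, per = coeffs(x_frac)
        temp[i], hum[i] = y
        rh[i] = rh_from_specific_humidity(y[0], y[1], inlet.pressure)
        if rh[i] > 1.0 + _RH_TOLERANCE:
            raise TransportIntegrityError(
                f"segment {segment.label!r}: RH {rh[i]:.6f} exceeds saturation"
            )
        q_sens[i] = h * (t_wall - y[0])
        q_lat[i] = h_m * props.density * (w_wall - y[1]) * props.latent_heat if wet else 0.0
        per_nodes[i] = per

    record(0, 0.0)
    for i in range(n_steps):
        xf = i * dxf
        k1 = rhs(xf, y)
        k2 = rhs(xf + 0.5 * dxf, y + 0.5 * dx * k1)
        k3 = rhs(xf + 0.5 * dxf, y + 0.5 * dx * k2)
        k4 = rhs(xf + dxf, y + dx * k3)
        y = y + dx / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        # the exact solution relaxes monotonically toward the wall state;
        # clamp the O(h^5) overshoot so invariants hold exactly
        y[0] = min(y[0], t_wall)
        if wet:
            # saturation limiter: vapor relaxes slightly faster than heat
            # (Le ≠ 1 under Chilton–Colburn), so near equilibrium the bulk
            # can marginally supersaturate; excess vapor condenses out
            y[1] = min(y[1], w_wall, specific_humidity_from_rh(y[0], 1.0, inlet.pressure))
        record(i + 1, (i + 1) * dxf)

    weights = np.full(n_nodes, dx)
    weights[0] = weights[-1] = 0.5 * dx
    weights *= per_nodes  # trapezoidal wetted-area weights

    outlet = replace(inlet, temperature=float(y[0]), specific_humidity=float(y[1]))
    profile = SegmentTransport(
        label=segment.label,
        region=segment.region,
        side=side,
        wall_is_wet=wet,
        x_from_nostril=x_offset + np.linspace(0.0, segment.length, n_nodes),
        temperature=temp,
        specific_humidity=hum,
        relative_humidity=rh,
        q_sensible=q_sens,
        q_latent=q_lat,
        wall_weights=weights,
    )
    return outlet, profile


def mix_streams_at_choanae(left: MoistAirState, right: MoistAirState) -> MoistAirState:
    """Merge the two side streams: dry-air-mass-flow-weighted T and w.

    With constant c_p the mass-weighted and enthalpy-weighted temperature
    averages coincide, which is the convention adopted.  Vapor mass and
    sensible enthalpy are conserved exactly by construction.
    """
    m1, m2 = left.mass_flow_dry_air, right.mass_flow_dry_air
    if m1 < 0.0 or m2 < 0.0:
        raise DomainError("mass flows must be non-negative")
    if m1 + m2 == 0.0:
        raise DomainError("cannot mix two zero-flow streams")
    if m1 == 0.0:
        return right
    if m2 == 0.0:
        return left
    m = m1 + m2
    return MoistAirState(
        temperature=(m1 * left.temperature + m2 * right.temperature) / m,
        specific_humidity=(m1 * left.specific_humidity + m2 * right.specific_humidity) / m,
        mass_flow_dry_air=m,
        pressure=left.pressure,
    )


@dataclass(frozen=True)
class TransportSolution:
    """Transport profiles for one solved subject state.

    Plane-1 states are each side's bulk state at the choanal end of its
    cavity; Plane-2 is the merged stream immediately downstream of the
    choanae, before any nasopharyngeal exchange.
    """

    profiles: tuple[SegmentTransport, ...]
    plane1: dict[Side, MoistAirState]
    plane2: MoistAirState

    def wall_nodes(
        self,
        regions: Sequence[Region],
        side: Side | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(q_sensible, q_latent, area weights) over the selected wall nodes.

        ``side=None`` selects both unilateral sides (the shared path belongs
        to neither and is only selected via ``Region.AREA3_NASOPHARYNX``).
        """
        qs, ql, wt = [], [], []
        for prof in self.profiles:
            if prof.region not in regions:
                continue
            if side is not None and prof.side is not side:
                continue
            if side is None and prof.region is not Region.AREA3_NASOPHARYNX and prof.side is None:
                continue
            qs.append(prof.q_sensible)
            ql.append(prof.q_latent)
            wt.append(prof.wall_weights)
        if not qs:
            return np.array([]), np.array([]), np.array([])
        return np.concatenate(qs), np.concatenate(ql), np.concatenate(wt)


def solve_transport(
    model: BilateralAirwayModel,
    flow: FlowSolution,
    ambient: AmbientConditions,
    n_steps: int = 100,
) -> TransportSolution:
    """Integrate transport through both sides and the shared path.

    Each side starts from the ambient inhaled state at its nostril with its
    share of the total flow; the streams merge at the choanae (Plane-2) and
    continue through the nasopharynx.  The shared path's entrance-length
    coordinate continues from the mean unilateral path length.
    """
    ambient.validate()
    profiles: list[SegmentTransport] = []
    plane1: dict[Side, MoistAirState] = {}
    props = ambient.air
    side_states: dict[Side, MoistAirState] = {}
    for side in (Side.LEFT, Side.RIGHT):
        q = flow.q_side(side)
        if q <= 0.0:
            raise DomainError(f"{side.value}: non-positive flow; transport undefined")
        w_amb = specific_humidity_from_rh(
            ambient.temperature, ambient.relative_humidity, ambient.pressure
        )
        m_dry = props.density * q / (1.0 + w_amb)
        state = ambient_inlet_state(ambient, m_dry)
        x = 0.0
        for seg in model.side_path(side):
            state, prof = integrate_segment_transport(
                state, seg, q, ambient, x_offset=x, side=side, n_steps=n_steps
            )
            profiles.append(prof)
            x += seg.length
        side_states[side] = state
        plane1[side] = state
    plane2 = mix_streams_at_choanae(side_states[Side.LEFT], side_states[Side.RIGHT])
    x_shared = 0.5 * (
        sum(s.length for s in model.left_path) + sum(s.length for s in model.right_path)
    )
    state = plane2
    for seg in model.shared_path:
        state, prof = integrate_segment_transport(
            state, seg, flow.q_total, ambient, x_offset=x_shared, side=None, n_steps=n_steps
        )
        profiles.append(prof)
        x_shared += seg.length
    return TransportSolution(profiles=tuple(profiles), plane1=plane1, plane2=plane2)
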