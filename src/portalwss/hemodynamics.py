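"""Flow assignment, propagation and wall-shear-stress fields on a portal tree.

The inlet flows are set from the ultrasound-measured portal vein (PV)
velocity: the preoperative total PV flow is Q_PV = V_PV · π D_PV²/4, split
among the SMV, SV, LGV and IMV according to population-averaged flow
proportions. After virtual splenectomy the ligated SV contributes nothing;
by default the SV share is simply removed (the PV then carries
Q_SMV + Q_LGV + Q_IMV), with an alternative mode that keeps the total PV
flow and renormalizes the split over the remaining inlets.

Flows propagate by pure continuity: a segment's flow is its own inflow
plus every tributary joining upstream of the point considered, so the flow
is piecewise constant along segments that host mid-course junctions. Wall
shear stress on each surface strip follows from the local flow and radius
through the generalized-Newtonian tube solution; node pressures integrate
the wall friction ΔP = 2 τ_w Δx / R upstream from the fixed-pressure
outlet (25 mmHg by default, the conventional portal-hypertensive value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, DomainError, TopologyError, ValidationError
from .geometry import INLET_VEINS, PortalTree, SurfaceStrip, discretize_surface
from .rheology import CarreauParams, wall_shear_stress_tube

MMHG_TO_PA = 133.3223874
DEFAULT_OUTLET_PRESSURE_PA = 25.0 * MMHG_TO_PA

#: Population-averaged flow-rate proportions for portal-hypertensive
#: patients (config-overridable stand-in; every report records the split).
DEFAULT_FLOW_SPLIT = {"SMV": 0.40, "SV": 0.45, "LGV": 0.05, "IMV": 0.10}

FLOW_MODES = ("subtract_sv", "renormalize")
STUMP_MODELS = ("stasis", "decay")


@dataclass(frozen=True)
class FlowSplit:
    """Fractions of the total PV flow carried by each inlet vein."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        props = dict(self.proportions)
        unknown = set(props) - set(INLET_VEINS)
        if unknown:
            raise ValidationError(f"unknown veins in flow split: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ValidationError("flow proportions must be >= 0")
        total = sum(props.values())
        if abs(total - 1.0) > 1.0e-12:
            raise ValidationError(f"flow proportions must sum to 1, got {total}")
        object.__setattr__(self, "proportions", props)

    def __getitem__(self, vein: str) -> float:
        if vein not in self.proportions:
            raise ConfigError(f"flow split does not cover inlet {vein!r}")
        return self.proportions[vein]


@dataclass(frozen=True)
class BoundaryConditions:
    """Outlet pressure, measured PV velocity and the inlet flow split."""

    pv_velocity: float  # m/s, cross-sectional mean
    outlet_pressure: float = DEFAULT_OUTLET_PRESSURE_PA  # Pa
    flow_split: FlowSplit = field(
        default_factory=lambda: FlowSplit(DEFAULT_FLOW_SPLIT)
    )
    flow_mode: str = "subtract_sv"

    def __post_init__(self) -> None:
        if not self.pv_velocity > 0:
            raise ValidationError("pv_velocity must be > 0")
        if not self.outlet_pressure > 0:
            raise ValidationError("outlet_pressure must be > 0")
        if self.flow_mode not in FLOW_MODES:
            raise ConfigError(f"flow_mode must be one of {FLOW_MODES}")


@dataclass(frozen=True)
class FlowSolution:
    """Piecewise-constant flow per segment plus junction bookkeeping.

    ``breakpoints[name]`` is a sorted tuple of ``(s, flow_m3_s)`` pairs:
    the segment carries ``flow`` for axial positions ≥ s (until the next
    breakpoint). Flow is conserved at every junction by construction.
    """

    breakpoints: Mapping[str, tuple[tuple[float, float], ...]]

    def flow_at(self, segment_name: str, s: float) -> float:
        """Volumetric flow (m³/s) in ``segment_name`` at arclength ``s``."""
        pts = self.breakpoints[segment_name]
        flow = pts[0][1]
        for pos, q in pts:
            if pos <= s:
                flow = q
            else:
                break
        return flow

    def outflow(self, segment_name: str) -> float:
        return self.breakpoints[segment_name][-1][1]


@dataclass(frozen=True)
class WSSField:
    """Surface strips with their wall shear stress (Pa)."""

    strips: tuple[tuple[SurfaceStrip, float], ...]

    def __post_init__(self) -> None:
        if any(t < 0 for _, t in self.strips):
            raise ValidationError("wall shear stress must be >= 0")


def assign_inlet_flows(tree: PortalTree, bc: BoundaryConditions) -> dict[str, float]:
    """Per-inlet volumetric flow (m³/s) from the PV velocity and flow split.

    The PV diameter is read from the geometry at PV mid-length. For a
    postoperative tree the ligated SV receives no flow; the default
    ``subtract_sv`` mode drops its share outright, while ``renormalize``
    keeps the total PV flow and rescales the remaining proportions.
    """
    pv = tree.segment("PV")
    d_pv = 2.0 * float(pv.radius_at(0.5))
    q_total = bc.pv_velocity * math.pi * d_pv**2 / 4.0
    split = bc.flow_split
    if tree.state == "preoperative":
        return {seg.name: split[seg.name] * q_total for seg in tree.inlets()}
    active = [seg.name for seg in tree.inlets()]
    if bc.flow_mode == "subtract_sv":
        flows = {name: split[name] * q_total for name in active}
    else:  # renormalize over the remaining inlets
        remaining = sum(split[name] for name in active)
        if remaining <= 0:
            raise ConfigError("flow split leaves no flow for the remaining inlets")
        flows = {name: split[name] / remaining * q_total for name in active}
    return flows


def solve_flows(tree: PortalTree, inlet_flows: Mapping[str, float]) -> FlowSolution:
    """Propagate inlet flows to every segment by continuity.

    A stump segment carries exactly zero flow; segments hosting mid-course
    junctions get a new flow value at each attachment position.
    """
    if any(q < 0 for q in inlet_flows.values()):
        raise DomainError("inlet flows must be >= 0")
    for seg in tree.inlets():
        if seg.name not in inlet_flows:
            raise ConfigError(f"no inlet flow provided for {seg.name}")

    order: list[str] = []
    seen: set[str] = set()

    def visit(name: str) -> None:
        if name in seen:
            return
        if name in visiting:
            raise TopologyError(f"cycle detected at {name}")
        visiting.add(name)
        for trib, _ in tree.tributaries_of(name):
            visit(trib)
        visiting.discard(name)
        seen.add(name)
        order.append(name)

    visiting: set[str] = set()
    visit("PV")
    if len(order) != len(tree.segments):
        raise TopologyError("network is not connected to the outlet")

    breakpoints: dict[str, tuple[tuple[float, float], ...]] = {}
    for name in order:
        seg = tree.segment(name)
        base = inlet_flows.get(name, 0.0) if seg.role == "inlet" else 0.0
        pts = [(0.0, base)]
        running = base
        for trib, pos in tree.tributaries_of(name):
            running += breakpoints[trib][-1][1]
            if pos == pts[-1][0]:
                pts[-1] = (pos, running)
            else:
                pts.append((pos, running))
        breakpoints[name] = tuple(pts)
    return FlowSolution(breakpoints=breakpoints)


def _stump_names(tree: PortalTree) -> set[str]:
    return {seg.name for seg in tree.segments if seg.role == "stump"}


def compute_wss_field(
    tree: PortalTree,
    flows: FlowSolution,
    params: CarreauParams = CarreauParams(),
    dx: float = 1.0e-3,
    *,
    stump_model: str = "stasis",
) -> WSSField:
    """Wall shear stress on every surface strip of the tree.

    Each strip's τ_w comes from the generalized-Newtonian tube solution at
    the local flow and radius. A dead-end stump carries no flow; under the
    default ``stasis`` model its wall is at τ_w = 0, while the ``decay``
    model paints an exponentially decaying stress τ_junction·exp(−s/D) from
    the junction into the stump (penetration length = stump diameter) to
    mimic 3D recirculation spill-over.
    """
    if stump_model not in STUMP_MODELS:
        raise ConfigError(f"stump_model must be one of {STUMP_MODELS}")
    strips = discretize_surface(tree, dx)
    stumps = _stump_names(tree)
    cache: dict[tuple[float, float], float] = {}

    def tau(q: float, r: float) -> float:
        key = (q, r)
        if key not in cache:
            cache[key] = wall_shear_stress_tube(q, r, params)
        return cache[key]

    decay_tau: dict[str, float] = {}
    if stump_model == "decay":
        for name in stumps:
            seg = tree.segment(name)
            host, pos = tree.attachments[seg.distal_node]
            q_host = flows.flow_at(host, pos)
            r_host = float(tree.segment(host).radius_at(pos))
            decay_tau[name] = tau(q_host, r_host) if q_host > 0 else 0.0

    out = []
    for strip in strips:
        seg = tree.segment(strip.segment_id)
        q = flows.flow_at(seg.name, strip.axial_position)
        if seg.name in stumps or q == 0.0:
            if stump_model == "decay" and seg.name in decay_tau:
                dist = (1.0 - strip.axial_position) * seg.length
                d_stump = 2.0 * float(seg.radius_at(strip.axial_position))
                t = decay_tau[seg.name] * math.exp(-dist / d_stump)
            else:
                t = 0.0
        else:
            t = tau(q, float(seg.radius_at(strip.axial_position)))
        out.append((strip, t))
    return WSSField(strips=tuple(out))


def compute_pressures(
    tree: PortalTree,
    flows: FlowSolution,
    params: CarreauParams = CarreauParams(),
    outlet_pressure: float = DEFAULT_OUTLET_PRESSURE_PA,
    dx: float = 1.0e-3,
) -> dict[str, float]:
    """Node pressures (Pa) by integrating wall friction up from the outlet.

    Over a strip of axial extent Δx the fully developed momentum balance
    gives ΔP = 2 τ_w Δx / R. Stump segments carry no flow and hence no
    pressure drop: the stump tip sits at its junction pressure.
    """
    # flow-consistent wall stress (stasis on stumps), independent of the
    # decorative stump wall model used for the ALWSS surface field
    field_ = compute_wss_field(tree, flows, params, dx, stump_model="stasis")
    by_seg: dict[str, list[tuple[SurfaceStrip, float]]] = {}
    for strip, t in field_.strips:
        by_seg.setdefault(strip.segment_id, []).append((strip, t))

    def drop_over(name: str, s_from: float, s_to: float) -> float:
        """Pressure drop along ``name`` between arclengths s_from < s_to."""
        seg = tree.segment(name)
        total = 0.0
        for strip, t in by_seg[name]:
            if s_from <= strip.axial_position <= s_to:
                step = strip.area / (2.0 * math.pi * float(seg.radius_at(strip.axial_position)))
                total += 2.0 * t * step / float(seg.radius_at(strip.axial_position))
        return total

    pressures: dict[str, float] = {tree.outlet_node: float(outlet_pressure)}

    def node_pressure(node: str) -> float:
        if node in pressures:
            return pressures[node]
        host, pos = tree.attachments[node]
        hostseg = tree.segment(host)
        p = node_pressure(hostseg.distal_node) + drop_over(host, pos, 1.0)
        pressures[node] = p
        return p

    for seg in tree.segments:
        p_dist = node_pressure(seg.distal_node)
        pressures[seg.proximal_node] = p_dist + drop_over(seg.name, 0.0, 1.0)
    return pressures
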