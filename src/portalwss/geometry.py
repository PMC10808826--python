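"""Parametric portal venous tree geometry.

The portal venous system is modeled as a centerline network of five named
vessels — portal vein (PV), superior mesenteric vein (SMV), splenic vein
(SV), left gastric vein (LGV) and inferior mesenteric vein (IMV) — each a
segment with a piecewise-linear radius profile over normalized arclength
(0 = proximal/inflow end, 1 = distal end). Junctions are point nodes; a
tributary's distal node is anchored either at the SMV/SV confluence (the
PV origin) or part-way along a host segment.

Three anatomical variants are supported, distinguished by where the LGV
and IMV drain:

* Type 1 — LGV and IMV both drain into the SV (at its confluence end);
* Type 2 — LGV drains into the PV, IMV into the SV;
* Type 3 — LGV drains into the SV, IMV into the SMV mid-course.

A *virtual splenectomy* closes the SV's proximal (splenic hilum) end,
turning it into a dead-end stump while leaving every geometric field of
every segment untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DiscretizationError, ParseError, StateError, ValidationError

VEIN_NAMES = ("PV", "SMV", "SV", "LGV", "IMV")
INLET_VEINS = ("SMV", "SV", "LGV", "IMV")
ANATOMY_TYPES = (1, 2, 3)

#: Node identifiers used by :func:`build_tree`.
CONFLUENCE_NODE = "C"
OUTLET_NODE = "PV_out"

SCHEMA_VERSION = 1

#: Default fractional arclength of mid-segment junctions along their host.
DEFAULT_LGV_PV_POSITION = 0.35
DEFAULT_IMV_SMV_POSITION = 0.50


@dataclass(frozen=True)
class VesselSegment:
    """One vessel of the portal venous tree.

    ``radius_profile`` holds ``(s, r)`` samples of the lumen radius in
    meters at normalized arclength ``s`` in [0, 1]; the radius is linearly
    interpolated between samples. ``tortuosity`` is path length divided by
    the straight-line distance between the endpoints (≥ 1).
    """

    id: str
    name: str
    proximal_node: str
    distal_node: str
    length: float
    radius_profile: tuple[tuple[float, float], ...]
    tortuosity: float = 1.0
    role: str = "internal"

    def __post_init__(self) -> None:
        if self.name not in VEIN_NAMES:
            raise ValidationError(f"unknown vein name {self.name!r}")
        if self.role not in ("inlet", "internal", "stump"):
            raise ValidationError(f"unknown segment role {self.role!r}")
        if not self.length > 0:
            raise ValidationError(f"{self.name}: length must be > 0, got {self.length}")
        if not self.tortuosity >= 1.0:
            raise ValidationError(
                f"{self.name}: tortuosity must be >= 1, got {self.tortuosity}"
            )
        profile = tuple((float(s), float(r)) for s, r in self.radius_profile)
        if len(profile) < 2:
            raise ValidationError(f"{self.name}: radius profile needs >= 2 samples")
        ss = [s for s, _ in profile]
        if ss[0] != 0.0 or ss[-1] != 1.0 or any(b <= a for a, b in zip(ss, ss[1:])):
            raise ValidationError(
                f"{self.name}: radius samples must be strictly increasing from 0 to 1"
            )
        if any(r <= 0 for _, r in profile):
            raise ValidationError(f"{self.name}: all radii must be > 0")
        object.__setattr__(self, "radius_profile", profile)

    def radius_at(self, s: float | np.ndarray) -> float | np.ndarray:
        """Lumen radius (m) at normalized arclength ``s``."""
        ss = np.array([p[0] for p in self.radius_profile])
        rr = np.array([p[1] for p in self.radius_profile])
        return np.interp(s, ss, rr)

    def lateral_area(self) -> float:
        """Analytic lateral surface area ∫ 2πR(x) dx of the revolved profile."""
        ss = np.array([p[0] for p in self.radius_profile])
        rr = np.array([p[1] for p in self.radius_profile])
        return float(2.0 * math.pi * np.trapezoid(rr, ss) * self.length)


@dataclass(frozen=True)
class SurfaceStrip:
    """One circumferential strip of a segment's lateral surface."""

    segment_id: str
    axial_position: float  # normalized arclength of the strip midpoint
    area: float  # m²

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError("strip area must be > 0")
        if not 0.0 <= self.axial_position <= 1.0:
            raise ValidationError("strip axial position must lie in [0, 1]")


@dataclass(frozen=True)
class PortalTree:
    """A rooted portal venous network.

    ``attachments`` maps a junction node id to ``(host_segment_name, s)``:
    the node sits on the host segment at normalized arclength ``s``. The
    SMV/SV confluence node is anchored at the PV origin (s = 0).
    """

    segments: tuple[VesselSegment, ...]
    attachments: Mapping[str, tuple[str, float]]
    anatomy_type: int
    state: str = "preoperative"
    outlet_node: str = OUTLET_NODE

    def __post_init__(self) -> None:
        if self.anatomy_type not in ANATOMY_TYPES:
            raise ValidationError(f"anatomy_type must be one of {ANATOMY_TYPES}")
        if self.state not in ("preoperative", "postoperative"):
            raise ValidationError(f"unknown state {self.state!r}")
        names = [seg.name for seg in self.segments]
        if sorted(names) != sorted(VEIN_NAMES):
            raise ValidationError(f"tree must contain exactly {VEIN_NAMES}, got {names}")
        object.__setattr__(self, "attachments", dict(self.attachments))
        self._check_topology()
        self._check_anatomy()
        self._check_state()

    # -- invariants ----------------------------------------------------

    def _check_topology(self) -> None:
        by_name = {seg.name: seg for seg in self.segments}
        outlets = [s for s in self.segments if s.distal_node == self.outlet_node]
        if len(outlets) != 1 or outlets[0].name != "PV":
            raise ValidationError("exactly one outlet (distal PV) is required")
        # every non-PV segment must drain into a host via its distal node,
        # and host links must be acyclic with all paths reaching the PV
        for seg in self.segments:
            if seg.name == "PV":
                continue
            anchor = self.attachments.get(seg.distal_node)
            if anchor is None:
                raise ValidationError(
                    f"{seg.name}: distal node {seg.distal_node!r} is not attached"
                )
            host, pos = anchor
            if host not in by_name or host == seg.name:
                raise ValidationError(f"{seg.name}: invalid host {host!r}")
            if not 0.0 <= pos <= 1.0:
                raise ValidationError(f"{seg.name}: attachment position outside [0,1]")
        for seg in self.segments:
            seen, cur = set(), seg.name
            while cur != "PV":
                if cur in seen:
                    raise ValidationError(f"cycle through {cur}")
                seen.add(cur)
                cur = self.attachments[by_name[cur].distal_node][0]

    def _check_anatomy(self) -> None:
        expected = {
            1: {"LGV": "SV", "IMV": "SV"},
            2: {"LGV": "PV", "IMV": "SV"},
            3: {"LGV": "SV", "IMV": "SMV"},
        }[self.anatomy_type]
        for trib, want in expected.items():
            host = self.host_of(trib)
            if host != want:
                raise ValidationError(
                    f"Type {self.anatomy_type} requires {trib}->{want}, got {trib}->{host}"
                )

    def _check_state(self) -> None:
        sv = self.segment("SV")
        if self.state == "postoperative":
            if sv.role != "stump":
                raise ValidationError("postoperative tree requires SV role=stump")
            if sorted(s.name for s in self.inlets()) != ["IMV", "LGV", "SMV"]:
                raise ValidationError("postoperative tree must have inlets SMV, LGV, IMV")
        else:
            if sv.role != "inlet":
                raise ValidationError("preoperative tree requires SV role=inlet")
            if len(self.inlets()) != 4:
                raise ValidationError("preoperative tree must have 4 inlets")

    # -- accessors -----------------------------------------------------

    def segment(self, name: str) -> VesselSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def inlets(self) -> tuple[VesselSegment, ...]:
        return tuple(s for s in self.segments if s.role == "inlet")

    def host_of(self, name: str) -> str | None:
        """Name of the segment this segment drains into (None for the PV).

        A tributary anchored at the confluence node (the PV origin, where
        the SV terminates) counts as draining into the SV when the spec of
        the anatomy calls for an SV connection; topologically the anchor
        resolves to the PV origin. For anatomy checks we report the SV for
        confluence-anchored LGV/IMV, matching the clinical description.
        """
        seg = self.segment(name)
        if seg.name == "PV":
            return None
        host, pos = self.attachments[seg.distal_node]
        if host == "PV" and pos == 0.0 and name in ("LGV", "IMV"):
            return "SV"  # drains at the SV terminus / confluence
        return host

    def tributaries_of(self, name: str) -> list[tuple[str, float]]:
        """(tributary, position-on-host) pairs for segments draining into ``name``."""
        out = []
        for seg in self.segments:
            if seg.name == "PV":
                continue
            host, pos = self.attachments[seg.distal_node]
            if host == name:
                out.append((seg.name, pos))
        return sorted(out, key=lambda t: t[1])


# ---------------------------------------------------------------------
# construction and editing
# ---------------------------------------------------------------------


def build_tree(
    diameters: Mapping[str, float],
    lengths: Mapping[str, float],
    tortuosities: Mapping[str, float] | None = None,
    anatomy_type: int = 1,
    *,
    lgv_pv_position: float = DEFAULT_LGV_PV_POSITION,
    imv_smv_position: float = DEFAULT_IMV_SMV_POSITION,
    radius_profiles: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> PortalTree:
    """Build a preoperative portal tree from per-vein dimensions (SI units).

    ``diameters`` and ``lengths`` map vein names to meters; ``tortuosities``
    defaults to 1 (straight). ``radius_profiles`` may override the default
    constant radius of a vein with explicit ``(s, r)`` samples.
    """
    if anatomy_type not in ANATOMY_TYPES:
        raise ValidationError(f"unknown anatomy_type {anatomy_type!r}")
    tort = dict(tortuosities or {})
    profiles = dict(radius_profiles or {})
    for name in VEIN_NAMES:
        if name not in diameters or name not in lengths:
            raise ValidationError(f"missing diameter/length for {name}")
        if not diameters[name] > 0 or not lengths[name] > 0:
            raise ValidationError(f"{name}: dimensions must be positive")

    def profile(name: str) -> tuple[tuple[float, float], ...]:
        if name in profiles:
            return tuple((float(s), float(r)) for s, r in profiles[name])
        r = diameters[name] / 2.0
        return ((0.0, r), (1.0, r))

    # distal anchors per anatomy type; the confluence node C is the PV origin
    lgv_node, imv_node = CONFLUENCE_NODE, CONFLUENCE_NODE
    attachments: dict[str, tuple[str, float]] = {CONFLUENCE_NODE: ("PV", 0.0)}
    if anatomy_type == 2:
        lgv_node = "J_LGV"
        attachments[lgv_node] = ("PV", float(lgv_pv_position))
    if anatomy_type == 3:
        imv_node = "J_IMV"
        attachments[imv_node] = ("SMV", float(imv_smv_position))

    def seg(name: str, prox: str, dist: str, role: str) -> VesselSegment:
        return VesselSegment(
            id=name,
            name=name,
            proximal_node=prox,
            distal_node=dist,
            length=float(lengths[name]),
            radius_profile=profile(name),
            tortuosity=float(tort.get(name, 1.0)),
            role=role,
        )

    segments = (
        seg("PV", CONFLUENCE_NODE, OUTLET_NODE, "internal"),
        seg("SMV", "SMV_in", CONFLUENCE_NODE, "inlet"),
        seg("SV", "SV_in", CONFLUENCE_NODE, "inlet"),
        seg("LGV", "LGV_in", lgv_node, "inlet"),
        seg("IMV", "IMV_in", imv_node, "inlet"),
    )
    return PortalTree(
        segments=segments,
        attachments=attachments,
        anatomy_type=anatomy_type,
        state="preoperative",
    )


def apply_splenectomy(tree: PortalTree) -> PortalTree:
    """Virtual splenectomy: close the SV's proximal end, keep all geometry.

    Returns a new postoperative tree in which the SV is a zero-inflow stump;
    every geometric field of every segment is preserved byte-for-byte.
    """
    if tree.state != "preoperative":
        raise StateError("splenectomy can only be applied to a preoperative tree")
    new_segments = tuple(
        replace(seg, role="stump") if seg.name == "SV" else seg for seg in tree.segments
    )
    return PortalTree(
        segments=new_segments,
        attachments=dict(tree.attachments),
        anatomy_type=tree.anatomy_type,
        state="postoperative",
        outlet_node=tree.outlet_node,
    )


def distance_metric(segment: VesselSegment) -> float:
    """Straight-line distance (m) between segment endpoints: length / tortuosity."""
    return segment.length / segment.tortuosity


# ---------------------------------------------------------------------
# surface discretization
# ---------------------------------------------------------------------


def discretize_surface(tree: PortalTree, dx: float = 1.0e-3) -> list[SurfaceStrip]:
    """Split every segment's lateral surface into strips of axial extent ≈ dx.

    Strip area is 2πR(s_mid)·Δx (midpoint rule), which is exact for constant
    and linearly tapered radius profiles within each strip.
    """
    if not dx > 0:
        raise DiscretizationError("dx must be > 0")
    shortest = min(seg.length for seg in tree.segments)
    if dx >= shortest:
        raise DiscretizationError(
            f"dx={dx} m is not smaller than the shortest segment ({shortest} m)"
        )
    strips: list[SurfaceStrip] = []
    for seg in tree.segments:
        n = max(1, int(math.ceil(seg.length / dx)))
        step = seg.length / n
        mids = (np.arange(n) + 0.5) / n
        radii = np.asarray(seg.radius_at(mids), dtype=float)
        areas = 2.0 * math.pi * radii * step
        strips.extend(
            SurfaceStrip(segment_id=seg.id, axial_position=float(s), area=float(a))
            for s, a in zip(mids, areas)
        )
    return strips


# ---------------------------------------------------------------------
# serialization (geometry JSON schema, version 1)
# ---------------------------------------------------------------------


def tree_to_dict(tree: PortalTree) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "anatomy_type": tree.anatomy_type,
        "state": tree.state,
        "outlet_node": tree.outlet_node,
        "attachments": {k: [v[0], v[1]] for k, v in tree.attachments.items()},
        "segments": [
            {
                "id": seg.id,
                "name": seg.name,
                "proximal_node": seg.proximal_node,
                "distal_node": seg.distal_node,
                "length_m": seg.length,
                "tortuosity": seg.tortuosity,
                "role": seg.role,
                "radius_profile_m": [[s, r] for s, r in seg.radius_profile],
            }
            for seg in tree.segments
        ],
    }


def tree_from_dict(data: Mapping) -> PortalTree:
    def need(mapping: Mapping, key: str, where: str):
        if key not in mapping:
            raise ParseError(f"missing required field {where}{key!r}")
        return mapping[key]

    version = need(data, "schema_version", "")
    if version != SCHEMA_VERSION:
        raise ParseError(f"unsupported schema_version {version!r}")
    segments = []
    for i, raw in enumerate(need(data, "segments", "")):
        where = f"segments[{i}]."
        try:
            segments.append(
                VesselSegment(
                    id=need(raw, "id", where),
                    name=need(raw, "name", where),
                    proximal_node=need(raw, "proximal_node", where),
                    distal_node=need(raw, "distal_node", where),
                    length=need(raw, "length_m", where),
                    radius_profile=tuple(
                        (s, r) for s, r in need(raw, "radius_profile_m", where)
                    ),
                    tortuosity=need(raw, "tortuosity", where),
                    role=need(raw, "role", where),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{where[:-1]}: {exc}") from exc
    try:
        return PortalTree(
            segments=tuple(segments),
            attachments={
                k: (v[0], float(v[1]))
                for k, v in need(data, "attachments", "").items()
            },
            anatomy_type=need(data, "anatomy_type", ""),
            state=need(data, "state", ""),
            outlet_node=need(data, "outlet_node", ""),
        )
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def write_tree(path: str | Path, tree: PortalTree) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2) + "\n")


def read_tree(path: str | Path) -> PortalTree:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    return tree_from_dict(data)
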