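"""Neuronal morphology data model and SWC input/output.

A reconstruction is a rooted tree of *sections*: unbranched runs of 3D sample
points (x, y, z, diameter) between branch points. The root section is the soma,
which may be a single point (spherical convention) or a traced contour. All
coordinates and diameters are in micrometres.

SWC files are 7-column plain text (id, type, x, y, z, radius, parent), node ids
1-based, radius = diameter / 2. Types 1/2/3 are soma/axon/dendrite; custom types
>= 5 encode AIS, myelin, nodes of Ranvier and spine compartments and are
documented in the file header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MorphPoint",
    "Section",
    "NeuronMorphology",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "apply_shrinkage_correction",
    "soma_equivalent_cylinder",
    "SHRINKAGE_PRESETS",
]

# SWC type codes <-> structural labels. 4 (apical dendrite) is folded into
# "dendrite": Purkinje cells have a single dendritic domain.
SWC_TYPES = {
    1: "soma",
    2: "axon",
    3: "dendrite",
    4: "dendrite",
    5: "AIS",
    6: "myelin",
    7: "node_of_ranvier",
    8: "spine_neck",
    9: "spine_head",
}
TYPE_CODES = {
    "soma": 1,
    "axon": 2,
    "dendrite": 3,
    "AIS": 5,
    "myelin": 6,
    "node_of_ranvier": 7,
    "spine_neck": 8,
    "spine_head": 9,
}

#: Named tissue-shrinkage corrections: isotropic xyz factor and an extra z-axis
#: factor compensating confocal z-distension. Applied only on request.
SHRINKAGE_PRESETS = {
    "human_autopsy": {"xyz_factor": 0.81, "z_factor": 1.0},
    "human_autopsy_zcorr": {"xyz_factor": 0.81, "z_factor": 0.84},
}

_COINCIDENT_TOL = 1e-6


class MorphologyError(ValueError):
    """Structural or value error in a morphology or SWC file."""


@dataclass(frozen=True)
class MorphPoint:
    x: float
    y: float
    z: float
    diameter: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.x, self.y, self.z, self.diameter))):
            raise MorphologyError("non-finite coordinate or diameter")
        if self.diameter <= 0:
            raise MorphologyError(f"non-positive diameter {self.diameter}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Section:
    """Unbranched run of points between branch points (or soma/tip)."""

    id: int
    parent_id: int | None
    stype: str
    points: list[MorphPoint]

    def __post_init__(self):
        if self.stype not in TYPE_CODES:
            raise MorphologyError(f"unknown section type {self.stype!r}")
        if self.stype != "soma" and len(self.points) < 2:
            raise MorphologyError(
                f"section {self.id}: non-soma section needs >= 2 points"
            )

    @property
    def length(self) -> float:
        """Arc length: sum of consecutive point distances."""
        if len(self.points) < 2:
            return 0.0
        p = np.array([pt.xyz for pt in self.points])
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))

    @property
    def mean_diameter(self) -> float:
        """Length-weighted mean diameter; plain mean for zero-length runs."""
        d = np.array([pt.diameter for pt in self.points])
        if len(d) == 1:
            return float(d[0])
        p = np.array([pt.xyz for pt in self.points])
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if seg.sum() == 0:
            return float(d.mean())
        mid = 0.5 * (d[:-1] + d[1:])
        return float(np.sum(mid * seg) / seg.sum())

    @property
    def surface_area(self) -> float:
        """Lateral (frustum) surface area in µm²."""
        if len(self.points) < 2:
            d = self.points[0].diameter
            return math.pi * d * d  # point soma -> sphere-equivalent cylinder
        area = 0.0
        for a, b in zip(self.points[:-1], self.points[1:]):
            h = float(np.linalg.norm(b.xyz - a.xyz))
            r1, r2 = a.diameter / 2.0, b.diameter / 2.0
            slant = math.hypot(h, r2 - r1)
            area += math.pi * (r1 + r2) * slant
        return area


@dataclass
class NeuronMorphology:
    sections: dict[int, Section]
    root_id: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        if not self.sections:
            raise MorphologyError("empty morphology")
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise MorphologyError("morphology must have exactly one root section")
        if self.root.stype != "soma":
            raise MorphologyError("root section must be the soma")
        seen: set[int] = set()
        stack = [self.root_id]
        children = self.children_map()
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise MorphologyError("cycle detected in section tree")
            seen.add(sid)
            stack.extend(children.get(sid, ()))
        if seen != set(self.sections):
            raise MorphologyError("disconnected (orphan) sections present")

    @property
    def root(self) -> Section:
        return self.sections[self.root_id]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for s in self.sections.values():
            if s.parent_id is not None:
                out.setdefault(s.parent_id, []).append(s.id)
        for v in out.values():
            v.sort()
        return out

    def sections_dfs(self, stype: str | None = None) -> list[Section]:
        """Depth-first (pre-order) section list, children in id order."""
        children = self.children_map()
        order: list[Section] = []
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            order.append(self.sections[sid])
            stack.extend(reversed(children.get(sid, ())))
        if stype is not None:
            order = [s for s in order if s.stype == stype]
        return order

    def dendrites(self) -> list[Section]:
        return self.sections_dfs(stype="dendrite")

    @property
    def total_dendritic_length(self) -> float:
        return float(sum(s.length for s in self.dendrites()))

    def copy(self) -> "NeuronMorphology":
        secs = {
            sid: replace(s, points=list(s.points)) for sid, s in self.sections.items()
        }
        return NeuronMorphology(secs, self.root_id, dict(self.metadata))


# ---------------------------------------------------------------------------
# SWC reading
# ---------------------------------------------------------------------------

def read_swc(path) -> NeuronMorphology:
    """Parse a 7-column SWC file into a section tree.

    Sections are split at every branch point; a child section is connected to
    its parent geometry either because its first node coincides with the
    parent's last node (duplication dialect) or by prepending the parent's
    attachment point.
    """
    nodes: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise MorphologyError(f"{path}:{ln}: expected 7 columns")
            nid, ntype = int(cols[0]), int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            parent = int(cols[6])
            if nid == parent:
                raise MorphologyError(f"node {nid} is its own parent")
            if r <= 0:
                raise MorphologyError(f"node {nid}: non-positive radius {r}")
            if ntype not in SWC_TYPES:
                raise MorphologyError(f"node {nid}: unknown SWC type {ntype}")
            if nid in nodes:
                raise MorphologyError(f"duplicate node id {nid}")
            nodes[nid] = (ntype, x, y, z, r, parent)

    if not nodes:
        raise MorphologyError(f"{path}: no SWC records")

    children: dict[int, list[int]] = {}
    roots = []
    for nid, rec in nodes.items():
        parent = rec[5]
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise MorphologyError(f"node {nid}: orphan (parent {parent} missing)")
            children.setdefault(parent, []).append(nid)
    for v in children.values():
        v.sort()
    if len(roots) != 1:
        raise MorphologyError(f"expected exactly one root node, found {len(roots)}")
    root_nid = roots[0]
    if nodes[root_nid][0] != 1:
        raise MorphologyError("root node must be of soma type")

    # cycle check on the node graph
    seen: set[int] = set()
    stack = [root_nid]
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise MorphologyError("cycle detected among SWC nodes")
        seen.add(nid)
        stack.extend(children.get(nid, ()))
    if seen != set(nodes):
        raise MorphologyError("cycle or disconnected component among SWC nodes")

    def pt(nid: int) -> MorphPoint:
        t, x, y, z, r, _ = nodes[nid]
        return MorphPoint(x, y, z, 2.0 * r)

    # Soma section: the contiguous run of soma-type nodes from the root.
    soma_nids = [root_nid]
    frontier = [root_nid]
    while frontier:
        nid = frontier.pop()
        for c in children.get(nid, ()):
            if nodes[c][0] == 1:
                soma_nids.append(c)
                frontier.append(c)

    sections: dict[int, Section] = {}
    next_sid = 0
    soma_sec = Section(next_sid, None, "soma", [pt(n) for n in soma_nids])
    sections[next_sid] = soma_sec
    next_sid += 1

    # Neurite sections: walk unbranched runs starting below the soma or below
    # branch points.
    # stack of (start node, parent section id, parent attachment node)
    walk: list[tuple[int, int, int]] = []
    for nid in soma_nids:
        for c in children.get(nid, ()):
            if nodes[c][0] != 1:
                walk.append((c, 0, nid))
    while walk:
        start, parent_sid, attach_nid = walk.pop()
        run = [start]
        while True:
            kids = children.get(run[-1], ())
            if len(kids) == 1 and nodes[kids[0]][0] == nodes[run[-1]][0]:
                run.append(kids[0])
            else:
                break
        stype = SWC_TYPES[nodes[start][0]]
        points = [pt(n) for n in run]
        attach = pt(attach_nid)
        first = points[0]
        if float(np.linalg.norm(first.xyz - attach.xyz)) > _COINCIDENT_TOL:
            points.insert(0, MorphPoint(attach.x, attach.y, attach.z, attach.diameter))
        if len(points) < 2:
            points.append(points[0])  # degenerate single-node child
        sec = Section(next_sid, parent_sid, stype, points)
        sections[next_sid] = sec
        sid = next_sid
        next_sid += 1
        for c in children.get(run[-1], ()):
            walk.append((c, sid, run[-1]))

    return NeuronMorphology(sections, 0, {"source_file": str(path)})


# ---------------------------------------------------------------------------
# SWC writing
# ---------------------------------------------------------------------------

def write_swc(morph: NeuronMorphology, path) -> None:
    """Write a morphology as SWC text.

    A section's first point is skipped when it exactly duplicates the parent's
    last emitted node (shared branch point), so re-reading reproduces the
    section tree, lengths and diameters exactly.
    """
    morph.validate()
    lines = [
        "# SWC export (pcarbor)",
        "# columns: id type x y z radius parent",
        "# types: 1 soma, 2 axon, 3 dendrite, 5 AIS, 6 myelin,"
        " 7 node_of_ranvier, 8 spine_neck, 9 spine_head",
    ]
    next_nid = 1
    # section id -> SWC node id of its last point
    last_node: dict[int, int] = {}
    for sec in morph.sections_dfs():
        code = TYPE_CODES[sec.stype]
        if sec.parent_id is None:
            parent_nid = -1
            points = sec.points
        else:
            parent_sec = morph.sections[sec.parent_id]
            parent_nid = last_node[sec.parent_id]
            first = sec.points[0]
            plast = parent_sec.points[-1]
            dup = (
                float(np.linalg.norm(first.xyz - plast.xyz)) <= _COINCIDENT_TOL
                and abs(first.diameter - plast.diameter) <= _COINCIDENT_TOL
            )
            points = sec.points[1:] if dup else sec.points
        for p in points:
            lines.append(
                f"{next_nid} {code} {p.x:.9g} {p.y:.9g} {p.z:.9g}"
                f" {p.diameter / 2.0:.9g} {parent_nid}"
            )
            parent_nid = next_nid
            next_nid += 1
        last_node[sec.id] = parent_nid
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Corrections and soma geometry
# ---------------------------------------------------------------------------

def apply_shrinkage_correction(
    morph: NeuronMorphology, xyz_factor: float, z_factor: float = 1.0
) -> NeuronMorphology:
    """Scale coordinates (and diameters) for tissue shrinkage.

    All coordinates and diameters are multiplied by ``xyz_factor``; z is
    additionally multiplied by ``z_factor`` (confocal z-distension). Returns a
    new morphology; factors are recorded in its metadata.
    """
    for name, f in (("xyz_factor", xyz_factor), ("z_factor", z_factor)):
        if not (0 < f <= 2):
            raise ValueError(f"{name} must be in (0, 2], got {f}")
    secs = {}
    for sid, s in morph.sections.items():
        pts = [
            MorphPoint(
                p.x * xyz_factor,
                p.y * xyz_factor,
                p.z * xyz_factor * z_factor,
                p.diameter * xyz_factor,
            )
            for p in s.points
        ]
        secs[sid] = Section(s.id, s.parent_id, s.stype, pts)
    meta = dict(morph.metadata)
    meta.setdefault("corrections", []).append(
        {"xyz_factor": xyz_factor, "z_factor": z_factor}
    )
    return NeuronMorphology(secs, morph.root_id, meta)


def soma_equivalent_cylinder(morph: NeuronMorphology) -> tuple[float, float]:
    """Equivalent-cylinder (length, diameter) of the soma, in µm.

    A single-point soma maps to L = diam = point diameter (the lateral area
    then equals the sphere area, the usual single-compartment convention). A
    traced contour maps to the diameter of the circle with the contour's
    enclosed area, projected on its dominant plane.
    """
    soma = morph.root
    if len(soma.points) == 1:
        d = soma.points[0].diameter
        return d, d
    xyz = np.array([p.xyz for p in soma.points])
    ext = xyz.max(axis=0) - xyz.min(axis=0)
    keep = np.argsort(ext)[-2:]
    poly = xyz[:, sorted(keep)]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(
        np.sum(x * np.roll(y, -1)) - np.sum(y * np.roll(x, -1))
    )
    if area <= 0:
        # degenerate contour: fall back to mean point diameter
        d = float(np.mean([p.diameter for p in soma.points]))
        return d, d
    d = 2.0 * math.sqrt(area / math.pi)
    return d, d
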