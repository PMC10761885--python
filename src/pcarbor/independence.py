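"""Dendritic electrotonic independence and combinatorial capacity.

Following the impedance criterion: a sinusoidal current (10 Hz) injected into
a spiny dendrite co-stimulates every spiny dendritic section in which the
transfer impedance magnitude stays at or above 10 MΩ. Sampling one spiny
dendrite every 20 (dendrogram depth-first order) gives a distribution of
co-stimulated counts; with N spiny dendrites in total, the number of
independent computational elements is n = N / mean(count), and the
combinatorial capacity of binary activation patterns is K = 2**round(n),
computed in exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import MorphologyError, NeuronMorphology
from .morphometrics import classify_zones
from .passive import CompartmentalModel, ImpedanceProfile, transfer_impedance_many

__all__ = [
    "IndependenceResult",
    "RoiGrid",
    "sample_sources",
    "costimulated_count",
    "independence_summary",
    "capacity",
    "capacity_sci",
    "build_roi_grid",
    "independence_analysis",
]


@dataclass
class IndependenceResult:
    counts: list[int]  # co-stimulated spiny dendrites per source
    n_sources: int
    n_spiny_dendrites: int  # N
    mean_count: float
    sd_count: float
    n_independent: float  # N / mean(count)
    capacity: int  # 2 ** round(n_independent), exact
    capacity_sci: str

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["capacity"] = str(self.capacity)  # exact big integer as text
        return d


@dataclass
class RoiGrid:
    """30x30 µm square tiling of the arbor's projection plane.

    ``cells`` maps (ix, iy) -> list of (section_id, point_index) for every
    spiny dendritic section point falling in that cell.
    """

    cell_side: float
    origin: tuple[float, float]
    plane: tuple[int, int]
    cells: dict[tuple[int, int], list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subsample(self, cell: tuple[int, int], fraction: float, seed: int):
        """Seeded random subset (e.g. 30%) of one ROI's member points."""
        members = self.cells[cell]
        k = int(round(fraction * len(members)))
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(members), size=k, replace=False)
        return [members[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------

def sample_sources(model: CompartmentalModel, stride: int = 20) -> list[int]:
    """Midpoint compartments of every ``stride``-th spiny dendritic section.

    Sections are taken in dendrogram depth-first order, so the sampling is
    deterministic for a given model.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    spiny = model.spiny_sections()
    if not spiny:
        raise MorphologyError("model has no spiny dendritic sections")
    sources = []
    for sid in spiny[::stride]:
        comps = model.section_compartments[sid]
        sources.append(comps[len(comps) // 2])
    return sources


def costimulated_count(
    profile: ImpedanceProfile,
    model: CompartmentalModel,
    threshold_mohm: float = 10.0,
) -> int:
    """Spiny dendritic sections with any compartment at |Z| >= threshold.

    The source's own section is always included (its input impedance is the
    maximum of the profile).
    """
    spiny = set(model.spiny_sections())
    hot = profile.magnitude_mohm >= threshold_mohm
    src_sec = int(model.section_id[profile.source])
    hit = {
        int(s)
        for s in np.unique(model.section_id[hot])
        if int(s) in spiny
    }
    hit.add(src_sec)
    return len(hit)


def independence_summary(counts, n_spiny: int) -> IndependenceResult:
    """Independent-element count and capacity from co-stimulation counts."""
    counts = [int(c) for c in counts]
    if not counts:
        raise ValueError("need at least one co-stimulated count")
    if n_spiny < max(counts):
        raise ValueError("N must be >= every co-stimulated count")
    arr = np.asarray(counts, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    n_ind = n_spiny / mean
    n_round = int(math.floor(n_ind + 0.5))  # round half up
    K = capacity(n_round)
    return IndependenceResult(
        counts=counts,
        n_sources=len(counts),
        n_spiny_dendrites=int(n_spiny),
        mean_count=mean,
        sd_count=sd,
        n_independent=n_ind,
        capacity=K,
        capacity_sci=capacity_sci(K),
    )


def capacity(n: int) -> int:
    """Exact number of binary activation patterns over n independent elements."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1 << int(n)


def capacity_sci(value: int, sig: int = 2) -> str:
    """Scientific-notation string with the mantissa truncated to ``sig`` digits.

    Truncation (not rounding) keeps the quoted figure a lower bound on the
    exact count: 2**51 = 2251799813685248 prints as '2.2e15'.
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    digits = str(int(value))
    exp = len(digits) - 1
    if exp < sig:
        return str(int(value))
    mantissa = digits[0] + "." + digits[1:sig]
    return f"{mantissa}e{exp}"


# ---------------------------------------------------------------------------

def build_roi_grid(
    morph: NeuronMorphology, cell_side: float = 30.0
) -> RoiGrid:
    """Tile the arbor's dominant projection plane with square ROIs.

    Every spiny-section point maps to exactly one cell; cells without spiny
    points are omitted from the membership table.
    """
    if cell_side <= 0:
        raise ValueError("cell_side must be > 0")
    zones = classify_zones(morph)
    spiny = [s for s in morph.dendrites() if zones[s.id].zone == "spiny"]
    if not spiny:
        raise MorphologyError("no spiny dendrites for the ROI grid")
    allpts = np.vstack([[p.xyz for p in s.points] for s in spiny])
    ext = allpts.max(axis=0) - allpts.min(axis=0)
    plane = tuple(sorted(np.argsort(ext)[-2:]))
    pts2 = allpts[:, plane]
    lo = pts2.min(axis=0)
    if float(max(pts2.max(axis=0) - lo)) < 1e-9:
        raise MorphologyError("degenerate extent: cannot build ROI grid")
    grid = RoiGrid(cell_side=cell_side, origin=(float(lo[0]), float(lo[1])),
                   plane=plane)
    for sec in spiny:
        for pi, p in enumerate(sec.points):
            q = (p.xyz[list(plane)] - lo) / cell_side
            key = (int(q[0]), int(q[1]))
            grid.cells.setdefault(key, []).append((sec.id, pi))
    return grid


def independence_analysis(
    model: CompartmentalModel,
    stride: int = 20,
    frequency_hz: float = 10.0,
    threshold_mohm: float = 10.0,
) -> IndependenceResult:
    """Full impedance-based independence computation on one model."""
    sources = sample_sources(model, stride)
    profiles = transfer_impedance_many(model, sources, frequency_hz)
    counts = [costimulated_count(p, model, threshold_mohm) for p in profiles]
    return independence_summary(counts, len(model.spiny_sections()))
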