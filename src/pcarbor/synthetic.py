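"""Synthetic Purkinje-cell morphologies and voltage traces.

The morphology generator emulates the cohort statistics of mouse and human
Purkinje cells: trunk-count probabilities (mouse 1 trunk w.p. 0.895, 2 w.p.
0.105; human 1/2/3 w.p. 0.2/0.4/0.4), cumulative dendritic length (mouse
2782.59 ± 671.12 µm; human 20166.96 µm mean with the sd truncated to 30% of
the mean for realizability), branch orders (mouse 12-25, human 18-41), a
diameter taper from thick trunks (3.5-6 µm) down to spiny terminals
(0.3-0.6 µm) via the 3/2-power branching rule with asymmetric daughter
splits, near-planar embedding (z jitter < 5 µm), and ~90% of dendritic length
in the spiny (< 1.6 µm) zone.

Trees are grown as stochastic binary topologies terminated by diameter; the
drawn target length is then imposed exactly by a global scaling of section
lengths (topology, orders and diameters untouched), and the geometry is
embedded afterwards. Identical seeds give byte-identical SWC output.

Voltage traces are analytic stand-ins for current-clamp recordings (regular
firing with a stereotyped AP template, hyperpolarizing sag steps, bursts),
carrying their ground truth (spike times, rate, ISI CV, sag fraction) as
annotations for closed-loop tests of the feature extractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ephys import StimulusAnnotation, VoltageTrace
from .morphology import MorphPoint, NeuronMorphology, Section, write_swc

__all__ = [
    "SpeciesPreset",
    "TraceRecipe",
    "MOUSE",
    "HUMAN",
    "generate_morphology",
    "generate_trace",
    "generate_cohort",
    "cell_seed",
]


@dataclass(frozen=True)
class SpeciesPreset:
    name: str
    trunk_counts: tuple[int, ...]
    trunk_probs: tuple[float, ...]
    length_mean: float  # µm
    length_sd: float  # µm (possibly truncated for realizability)
    branch_order_range: tuple[int, int]
    trunk_diameter_range: tuple[float, float] = (3.5, 6.0)
    terminal_diameter_range: tuple[float, float] = (0.3, 0.6)
    # asymmetry of the 3/2-power daughter split: main-branch share w ~ U(lo, hi);
    # the thick scaffold (>= 1.6 µm) branches more symmetrically than the thin
    # spiny chains, mirroring the trunk ramification that demultiplexes
    # terminal branches
    asymmetry_range: tuple[float, float] = (0.74, 0.90)
    scaffold_asymmetry_range: tuple[float, float] = (0.62, 0.88)
    # diameter-conservation exponent e of the daughter split
    # (d_parent**e = d1**e + d2**e): 3/2 in the thin spiny chains (classic
    # power rule); larger in the thick scaffold, whose trunks taper slowly
    taper_exponent: float = 1.5
    scaffold_taper_exponent: float = 2.0
    soma_diameter: float = 22.0
    # base (pre-scaling) section lengths by zone; their ratio sets the spiny
    # share of total length (~90%)
    base_length_spiny: float = 1.0
    base_length_aspiny: float = 2.0
    max_sections: int = 6000

    def __post_init__(self):
        if abs(sum(self.trunk_probs) - 1.0) > 1e-9:
            raise ValueError("trunk probabilities must sum to 1")
        if self.length_mean <= 0 or self.length_sd <= 0:
            raise ValueError("length statistics must be positive")
        for rng_ in (self.trunk_diameter_range, self.terminal_diameter_range,
                     self.branch_order_range, self.asymmetry_range):
            if rng_[0] > rng_[1]:
                raise ValueError("preset ranges must be ordered")


MOUSE = SpeciesPreset(
    name="mouse",
    trunk_counts=(1, 2),
    trunk_probs=(0.895, 0.105),
    length_mean=2782.59,
    length_sd=671.12,
    branch_order_range=(12, 25),
    asymmetry_range=(0.74, 0.90),
    soma_diameter=22.0,
)

HUMAN = SpeciesPreset(
    name="human",
    trunk_counts=(1, 2, 3),
    trunk_probs=(0.2, 0.4, 0.4),
    length_mean=20166.96,
    length_sd=0.3 * 20166.96,  # printed sd (~76% of mean) truncated
    branch_order_range=(18, 41),
    asymmetry_range=(0.82, 0.94),
    scaffold_asymmetry_range=(0.60, 0.85),
    scaffold_taper_exponent=2.2,
    base_length_aspiny=3.0,
    soma_diameter=35.0,
)

_SPINY_DIAM = 1.6


# ---------------------------------------------------------------------------
# Morphology generation
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    parent: int  # index into node list, -1 for trunk roots
    diameter: float
    depth: int
    is_side: bool
    children: list[int] = field(default_factory=list)
    base_length: float = 0.0
    length: float = 0.0


def _grow_topology(preset: SpeciesPreset, n_trunks: int, rng) -> list[_Node] | None:
    lo_w, hi_w = preset.asymmetry_range
    t_lo, t_hi = preset.terminal_diameter_range
    nodes: list[_Node] = []
    stack: list[int] = []
    for _ in range(n_trunks):
        d0 = rng.uniform(*preset.trunk_diameter_range)
        nodes.append(_Node(parent=-1, diameter=d0, depth=1, is_side=False))
        stack.append(len(nodes) - 1)
    while stack:
        if len(nodes) > preset.max_sections:
            return None
        i = stack.pop()
        node = nodes[i]
        if node.diameter < rng.uniform(t_lo, t_hi):
            continue  # terminal tip
        if node.diameter >= _SPINY_DIAM:
            w = rng.uniform(*preset.scaffold_asymmetry_range)
            e = preset.scaffold_taper_exponent
        else:
            w = rng.uniform(lo_w, hi_w)
            e = preset.taper_exponent
        d_main = node.diameter * w ** (1.0 / e)
        d_side = node.diameter * (1.0 - w) ** (1.0 / e)
        for d, side in ((d_main, False), (d_side, True)):
            nodes.append(_Node(parent=i, diameter=d, depth=node.depth + 1,
                               is_side=side))
            node.children.append(len(nodes) - 1)
            stack.append(len(nodes) - 1)
    return nodes


def generate_morphology(preset: SpeciesPreset, seed: int) -> NeuronMorphology:
    """Seeded synthetic Purkinje-cell morphology for one species preset."""
    master = np.random.default_rng(np.random.SeedSequence([0x9C, seed]))
    n_trunks = int(master.choice(preset.trunk_counts, p=preset.trunk_probs))
    lo = max(preset.length_mean - 2 * preset.length_sd, 0.25 * preset.length_mean)
    hi = preset.length_mean + 2 * preset.length_sd
    target_length = float(np.clip(master.normal(preset.length_mean,
                                                preset.length_sd), lo, hi))

    o_lo, o_hi = preset.branch_order_range
    nodes = None
    for attempt in range(200):
        rng = np.random.default_rng(np.random.SeedSequence([0x9C, seed, attempt]))
        cand = _grow_topology(preset, n_trunks, rng)
        if cand is None:
            continue
        max_depth = max(n.depth for n in cand)
        if o_lo <= max_depth <= o_hi and len(cand) >= 2 * n_trunks + 1:
            nodes = cand
            break
    if nodes is None:
        raise RuntimeError(
            f"could not realize preset {preset.name!r} within its branch-order "
            f"range after bounded retries (seed {seed})"
        )

    # section lengths: zone-dependent base draws, globally scaled to the target
    for n in nodes:
        base = (preset.base_length_spiny if n.diameter < _SPINY_DIAM
                else preset.base_length_aspiny)
        n.base_length = base * rng.lognormal(0.0, 0.35)
    scale = target_length / sum(n.base_length for n in nodes)
    for n in nodes:
        n.length = n.base_length * scale

    # planar embedding
    soma_pt = MorphPoint(0.0, 0.0, 0.0, preset.soma_diameter)
    positions = np.zeros((len(nodes), 3))
    directions = np.zeros((len(nodes), 2))
    trunk_idx = [i for i, n in enumerate(nodes) if n.parent == -1]
    spread = math.radians(50.0)
    for k, i in enumerate(trunk_idx):
        if len(trunk_idx) == 1:
            ang = math.pi / 2 + rng.normal(0.0, math.radians(8.0))
        else:
            ang = (math.pi / 2
                   + spread * (k - (len(trunk_idx) - 1) / 2.0)
                   + rng.normal(0.0, math.radians(5.0)))
        directions[i] = (math.cos(ang), math.sin(ang))

    order_idx = sorted(range(len(nodes)), key=lambda i: nodes[i].depth)
    polylines: dict[int, list[MorphPoint]] = {}
    for i in order_idx:
        node = nodes[i]
        if node.parent == -1:
            start = np.array([soma_pt.x, soma_pt.y, soma_pt.z])
            ang = math.atan2(directions[i][1], directions[i][0])
        else:
            start = positions[node.parent]
            pdir = directions[node.parent]
            pang = math.atan2(pdir[1], pdir[0])
            if node.is_side:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                ang = pang + sign * rng.normal(math.radians(40.0),
                                               math.radians(10.0))
            else:
                ang = pang + rng.normal(0.0, math.radians(8.0))
            directions[i] = (math.cos(ang), math.sin(ang))
        directions[i] = (math.cos(ang), math.sin(ang))
        npts = max(2, int(node.length / 3.0) + 2)
        step = node.length / (npts - 1)
        pts = [MorphPoint(start[0], start[1], start[2], node.diameter)]
        pos = start.copy()
        a = ang
        for _ in range(npts - 1):
            a += rng.normal(0.0, math.radians(20.0))
            dz = np.clip(rng.normal(0.0, 0.4), -1.0, 1.0)
            pos = pos + np.array([step * math.cos(a), step * math.sin(a), 0.0])
            pos[2] = float(np.clip(pos[2] + dz, -4.0, 4.0))
            pts.append(MorphPoint(pos[0], pos[1], pos[2], node.diameter))
        # drift the stored direction toward the realized end direction
        directions[i] = (math.cos(a), math.sin(a))
        positions[i] = pos
        polylines[i] = pts

    sections: dict[int, Section] = {0: Section(0, None, "soma", [soma_pt])}
    sid_of: dict[int, int] = {}
    next_sid = 1
    # depth-first over nodes to keep section ids in DFS order
    stack = list(reversed(trunk_idx))
    while stack:
        i = stack.pop()
        node = nodes[i]
        parent_sid = 0 if node.parent == -1 else sid_of[node.parent]
        sections[next_sid] = Section(next_sid, parent_sid, "dendrite",
                                     polylines[i])
        sid_of[i] = next_sid
        next_sid += 1
        stack.extend(reversed(node.children))

    # exact length normalization: embedding meander stretches arc length, so
    # rescale coordinates about the soma to restore the drawn target
    morph = NeuronMorphology(
        sections, 0,
        {"species": preset.name, "seed": seed, "n_trunks": n_trunks,
         "target_length": target_length},
    )
    realized = morph.total_dendritic_length
    if realized > 0:
        f = target_length / realized
        for sec in morph.sections.values():
            if sec.stype == "soma":
                continue
            sec.points = [
                MorphPoint(p.x * f, p.y * f, p.z * f, p.diameter)
                for p in sec.points
            ]
    return morph


# ---------------------------------------------------------------------------
# Voltage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceRecipe:
    kind: str  # regular_firing | sag_step | burst_response
    rate_hz: float = 30.0
    duration_ms: float = 1000.0
    dt_ms: float = 0.025
    baseline_mv: float = -61.0
    ap_amplitude_mv: float = 80.0
    ap_threshold_mv: float = -20.0
    ahp_depth_mv: float = 8.0
    noise_sd_mv: float = 0.0
    isi_jitter: float = 0.0  # fractional sd of the ISIs
    sag_fraction: float = 0.2
    step_amplitude_na: float = -0.5
    n_spikes: int = 5  # burst_response
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz < 0 or self.noise_sd_mv < 0:
            raise ValueError("rate and noise sd must be >= 0")
        if self.kind not in ("regular_firing", "sag_step", "burst_response"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


def _render_spikes(v, times_ms, recipe: TraceRecipe):
    """Overwrite a stereotyped AP template at each (grid-aligned) spike time.

    The template passes exactly through the detection threshold at the spike
    sample, so peak minus crossing voltage equals the nominal AP amplitude.
    """
    dt = recipe.dt_ms
    base, thr = recipe.baseline_mv, recipe.ap_threshold_mv
    peak = thr + recipe.ap_amplitude_mv
    knots_t = np.array([-0.5, 0.0, 0.2, 1.0, 4.0])
    knots_v = np.array([base, thr, peak, base - recipe.ahp_depth_mv, base])
    for k, t0 in enumerate(times_ms):
        horizon = (times_ms[k + 1] - t0 - dt) if k + 1 < len(times_ms) else 4.0
        tw = np.arange(-0.5, min(4.0, horizon) + dt / 2, dt)
        i0 = int(round(t0 / dt))
        idx = i0 + np.rint(tw / dt).astype(int)
        ok = (idx >= 0) & (idx < v.size)
        v[idx[ok]] = np.interp(tw[ok], knots_t, knots_v)


def generate_trace(recipe: TraceRecipe) -> VoltageTrace:
    rng = np.random.default_rng(np.random.SeedSequence([0xE9, recipe.seed]))
    dt = recipe.dt_ms
    n = int(round(recipe.duration_ms / dt)) + 1
    v = np.full(n, recipe.baseline_mv)
    annotations: dict = {"kind": recipe.kind}
    stim = StimulusAnnotation()

    if recipe.kind == "regular_firing":
        period = 1000.0 / recipe.rate_hz if recipe.rate_hz > 0 else math.inf
        k = int(round(recipe.rate_hz * recipe.duration_ms / 1000.0))
        times = (np.arange(k) + 0.5) * period
        if recipe.isi_jitter > 0 and k > 1:
            isis = np.diff(times)
            isis = np.maximum(2.0, isis * (1 + recipe.isi_jitter
                                           * rng.standard_normal(len(isis))))
            times = np.concatenate([[times[0]], times[0] + np.cumsum(isis)])
            times = times[times < recipe.duration_ms - 4.0]
        times = np.round(times / dt) * dt
        _render_spikes(v, times, recipe)
        isis = np.diff(times)
        annotations.update(
            spike_times_ms=times.tolist(),
            rate_hz=recipe.rate_hz,
            isi_cv=float(isis.std(ddof=1) / isis.mean()) if len(isis) >= 2 else None,
        )

    elif recipe.kind == "burst_response":
        period = 1000.0 / recipe.rate_hz
        times = 20.0 + np.arange(recipe.n_spikes) * period
        times = np.round(times[times < recipe.duration_ms - 4.0] / dt) * dt
        _render_spikes(v, times, recipe)
        annotations.update(spike_times_ms=times.tolist(),
                           n_spikes=len(times))

    else:  # sag_step
        if recipe.step_amplitude_na >= 0:
            raise ValueError("sag_step needs a hyperpolarizing amplitude")
        onset, offset = 100.0, min(recipe.duration_ms - 50.0, 400.0)
        stim = StimulusAnnotation("step", recipe.step_amplitude_na, onset, offset)
        t = np.arange(n) * dt
        d_peak = recipe.step_amplitude_na * 100.0  # nominal 100 MΩ deflection
        d_ss = d_peak * (1.0 - recipe.sag_fraction)
        tau_r, tau_d, t_peak = 8.0, 40.0, 60.0
        tt = t - onset
        rise = np.where(tt > 0, 1.0 - np.exp(-np.maximum(tt, 0) / tau_r), 0.0)
        relax = np.where(tt > t_peak,
                         np.exp(-(np.maximum(tt - t_peak, 0)) / tau_d), 1.0)
        defl = rise * (d_ss + (d_peak - d_ss) * relax)
        inside = (t >= onset) & (t < offset)
        v = v + np.where(inside, defl, 0.0)
        annotations.update(sag_fraction=recipe.sag_fraction)

    if recipe.noise_sd_mv > 0:
        v = v + rng.normal(0.0, recipe.noise_sd_mv, size=n)
    return VoltageTrace(v, dt, stim, annotations)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def cell_seed(master_seed: int, index: int) -> int:
    """Stable per-cell seed derivation from a single master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_mouse: int = 19,
    n_human: int = 6,
    seed: int = 0,
    outdir=None,
    presets: dict[str, SpeciesPreset] | None = None,
):
    """Generate a two-species cohort; optionally write SWC files + manifest.

    Returns ``(cells, manifest)`` where cells is a list of
    (species, cell_id, seed, morphology) and manifest is a DataFrame of the
    realized per-cell statistics, reproducible from the recorded seeds.
    """
    presets = presets or {"mouse": MOUSE, "human": HUMAN}
    plan = [("mouse", i) for i in range(n_mouse)] + [
        ("human", i) for i in range(n_human)
    ]
    cells, rows = [], []
    for index, (species, i) in enumerate(plan):
        s = cell_seed(seed, index)
        morph = generate_morphology(presets[species], s)
        cid = f"{species}_{i:02d}"
        cells.append((species, cid, s, morph))
        from .morphometrics import build_dendrogram, count_primary_dendrites

        dg = build_dendrogram(morph)
        rows.append(
            {
                "cell_id": cid,
                "species": species,
                "seed": s,
                "n_trunks": count_primary_dendrites(morph),
                "total_length_um": morph.total_dendritic_length,
                "n_sections": len(morph.dendrites()),
                "max_branch_order": dg.max_order,
                "file": f"{cid}.swc" if outdir else "",
            }
        )
        if outdir is not None:
            import os

            os.makedirs(outdir, exist_ok=True)
            write_swc(morph, os.path.join(outdir, f"{cid}.swc"))
    manifest = pd.DataFrame(rows)
    if outdir is not None:
        import os

        manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return cells, manifest
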