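"""Passive compartmental model: discretization, membrane parameters, impedance.

A morphology is discretized into iso-arclength compartments (default max 5 µm
per compartment). Each compartment carries a membrane conductance g_m = G_m *
area and capacitance c_m = C_m * area, plus an axial conductance to its parent
from the axial resistivity R_a and the frustum geometry (series half-resistance
coupling between compartment centres).

Membrane capacitance follows the spine-compensation scheme used in Purkinje
cell models: soma 1 µF/cm², large dendrites (diameter >= 1.6 µm) 2 µF/cm², and
thin spiny dendrites a diameter-dependent value

    C_m(d) = 11.510294 ** (-1.376463 * d) + 2.120503   [µF/cm²]

that compensates for the membrane area of the spines not represented
explicitly. When spines are modelled explicitly (two cylindrical compartments,
neck and head, at 2 spines/µm), the dendritic C_m is instead uniform at
2 µF/cm² and the spine head/neck carry their own C_m (2 and 3 µF/cm²).

Impedance is solved directly in the frequency domain: the complex nodal system
(G + iωC per compartment plus axial coupling) is factorized sparsely and
solved for a unit current at the source, which for a linear (passive) model is
identical to time-domain sinusoidal injection. The input-resistance protocol
mirrors the two-level somatic voltage-clamp step measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import MorphologyError, NeuronMorphology, soma_equivalent_cylinder
from .morphometrics import SPINY_MAX_DIAMETER

__all__ = [
    "PassiveParams",
    "SpineSpec",
    "CompartmentalModel",
    "ImpedanceProfile",
    "cm_spiny",
    "discretize",
    "assign_passive",
    "scaffold_spines",
    "transfer_impedance",
    "transfer_impedance_many",
    "rin_step_protocol",
    "cylinder_model",
    "MOUSE_SPINES",
    "HUMAN_SPINES",
]

_UM2_TO_CM2 = 1e-8


def cm_spiny(diameter_um: float | np.ndarray) -> float | np.ndarray:
    """Spine-compensating specific capacitance (µF/cm²) for thin dendrites.

    Strictly decreasing in diameter with asymptote 2.120503 µF/cm²
    (the bare-membrane dendritic value) at large diameters.
    """
    return 11.510294 ** (-1.376463 * np.asarray(diameter_um)) + 2.120503


@dataclass(frozen=True)
class PassiveParams:
    """Passive electrical constants (Purkinje-cell model defaults)."""

    Ra: float = 122.0  # axial resistivity, Ω·cm
    Cm_soma: float = 1.0  # µF/cm²
    Cm_large_dendrite: float = 2.0  # µF/cm², diameter >= 1.6 µm
    Gm_soma: float = 0.003  # S/cm²
    Gm_other: float = 0.0003  # S/cm²
    E_leak: float = -61.0  # mV
    Gm_myelin: float = 5.60e-9  # S/cm²
    Cm_myelin: float = 1.87e-11  # µF/cm²
    spine_mode: str = "implicit"  # implicit (C_m(d)) | explicit (spine compartments)

    def __post_init__(self):
        for name in ("Gm_soma", "Gm_other", "Gm_myelin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("Ra", "Cm_soma", "Cm_large_dendrite", "Cm_myelin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.spine_mode not in ("implicit", "explicit"):
            raise ValueError(f"unknown spine_mode {self.spine_mode!r}")


@dataclass(frozen=True)
class SpineSpec:
    """Two-cylinder spine geometry (µm) and membrane constants."""

    head_length: float
    head_diameter: float
    neck_length: float
    neck_diameter: float
    Cm_head: float = 2.0  # µF/cm²
    Cm_neck: float = 3.0  # µF/cm²
    density: float = 2.0  # spines/µm of spiny dendrite

    def __post_init__(self):
        vals = (
            self.head_length, self.head_diameter, self.neck_length,
            self.neck_diameter, self.Cm_head, self.Cm_neck,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("spine geometry and capacitances must be positive")
        if self.density < 0:
            raise ValueError("spine density must be >= 0")


MOUSE_SPINES = SpineSpec(head_length=0.35, head_diameter=1.0,
                         neck_length=0.7, neck_diameter=0.2)
HUMAN_SPINES = SpineSpec(head_length=0.26, head_diameter=1.0,
                         neck_length=0.72, neck_diameter=0.18)


@dataclass
class CompartmentalModel:
    """Electrical discretization of a morphology (plus optional spines).

    Arrays are indexed by compartment; ``parent[i] == -1`` marks the root.
    ``g_axial[i]`` couples compartment i to its parent. ``axial_half_res[i]``
    is half the internal axial resistance of compartment i (Ω), kept so spines
    and other attachments can couple into any compartment consistently.
    """

    parent: np.ndarray  # int
    g_axial: np.ndarray  # S, to parent (0 for root)
    area_cm2: np.ndarray
    length_um: np.ndarray
    diameter_um: np.ndarray
    stype: np.ndarray  # str per compartment
    section_id: np.ndarray  # morphology section provenance
    axial_half_res: np.ndarray  # Ω
    xyz: np.ndarray  # (n, 3) compartment midpoints, µm
    g_m: np.ndarray | None = None  # S, set by assign_passive
    c_m: np.ndarray | None = None  # F
    section_order: list[int] = field(default_factory=list)  # dendrites, DFS
    section_diameter: dict[int, float] = field(default_factory=dict)
    section_compartments: dict[int, list[int]] = field(default_factory=dict)
    n_spines: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def assigned(self) -> bool:
        return self.g_m is not None

    @property
    def soma_index(self) -> int:
        return int(np.where(self.stype == "soma")[0][0])

    def spiny_sections(self) -> list[int]:
        """Spiny dendritic section ids in dendrogram depth-first order."""
        return [
            sid for sid in self.section_order
            if self.section_diameter[sid] < SPINY_MAX_DIAMETER
        ]

    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())

    def to_frame(self):
        """Compartment table (one row per compartment) for export."""
        import pandas as pd

        cols = {
            "parent": self.parent,
            "stype": self.stype,
            "section_id": self.section_id,
            "length_um": self.length_um,
            "diameter_um": self.diameter_um,
            "area_cm2": self.area_cm2,
            "g_axial_S": self.g_axial,
            "x_um": self.xyz[:, 0],
            "y_um": self.xyz[:, 1],
            "z_um": self.xyz[:, 2],
        }
        if self.assigned:
            cols["g_m_S"] = self.g_m
            cols["c_m_F"] = self.c_m
        return pd.DataFrame(cols)


@dataclass
class ImpedanceProfile:
    """Transfer impedance from one source compartment to all compartments."""

    source: int
    frequency_hz: float
    magnitude_mohm: np.ndarray
    phase_rad: np.ndarray

    @property
    def input_mohm(self) -> float:
        return float(self.magnitude_mohm[self.source])


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _frustum_geometry(pts_xyz: np.ndarray, diam: np.ndarray, Ra: float):
    """(area_um2, axial_res_ohm) for a tapering polyline piece."""
    seg = np.linalg.norm(np.diff(pts_xyz, axis=0), axis=1)
    r1, r2 = diam[:-1] / 2.0, diam[1:] / 2.0
    slant = np.sqrt(seg**2 + (r2 - r1) ** 2)
    area = float(np.sum(math.pi * (r1 + r2) * slant))
    with np.errstate(divide="ignore"):
        res = float(np.sum(Ra * seg * 1e4 / (math.pi * r1 * r2)))
    return area, res


def discretize(
    morph: NeuronMorphology,
    max_seg_length: float = 5.0,
    params: PassiveParams | None = None,
) -> CompartmentalModel:
    """Split each section into ceil(length / max_seg_length) compartments.

    The soma contour becomes a single equivalent-cylinder compartment. Axial
    conductances couple compartment centres through series half-resistances.
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be > 0")
    params = params or PassiveParams()
    Ra = params.Ra

    parent, g_ax, area, length, diam, stype, secid, halfres, xyz = (
        [], [], [], [], [], [], [], [], []
    )

    # soma first (compartment 0)
    soma = morph.root
    sL, sD = soma_equivalent_cylinder(morph)
    soma_area = math.pi * sD * sL
    soma_half = Ra * (sL / 2.0) * 1e4 / (math.pi * (sD / 2.0) ** 2)
    parent.append(-1)
    g_ax.append(0.0)
    area.append(soma_area * _UM2_TO_CM2)
    length.append(sL)
    diam.append(sD)
    stype.append("soma")
    secid.append(soma.id)
    halfres.append(soma_half)
    soma_xyz = np.mean([p.xyz for p in soma.points], axis=0)
    xyz.append(soma_xyz)

    last_comp: dict[int, int] = {soma.id: 0}
    section_order: list[int] = []
    section_diameter: dict[int, float] = {}
    section_comps: dict[int, list[int]] = {}

    for sec in morph.sections_dfs():
        if sec.parent_id is None:
            continue
        pts = np.array([p.xyz for p in sec.points])
        ds = np.array([p.diameter for p in sec.points])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        L = float(seg.sum())
        if L <= 0:
            raise MorphologyError(f"section {sec.id} has zero length")
        ncomp = max(1, math.ceil(L / max_seg_length))
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        bounds = np.linspace(0.0, L, ncomp + 1)

        def interp(s):
            i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
            t = (s - cum[i]) / seg[i] if seg[i] > 0 else 0.0
            return pts[i] + t * (pts[i + 1] - pts[i]), ds[i] + t * (ds[i + 1] - ds[i])

        comp_ids = []
        for k in range(ncomp):
            s0, s1 = bounds[k], bounds[k + 1]
            inner = (cum > s0 + 1e-12) & (cum < s1 - 1e-12)
            p0, d0 = interp(s0)
            p1, d1 = interp(s1)
            sub_xyz = np.vstack([p0, pts[inner], p1])
            sub_d = np.concatenate([[d0], ds[inner], [d1]])
            a_um2, r_ohm = _frustum_geometry(sub_xyz, sub_d, Ra)
            idx = len(parent)
            par = last_comp[sec.parent_id] if k == 0 else idx - 1
            parent.append(par)
            area.append(a_um2 * _UM2_TO_CM2)
            length.append(s1 - s0)
            seg_sub = np.linalg.norm(np.diff(sub_xyz, axis=0), axis=1)
            w = seg_sub.sum()
            dmean = (
                float(np.sum(0.5 * (sub_d[:-1] + sub_d[1:]) * seg_sub) / w)
                if w > 0 else float(sub_d.mean())
            )
            diam.append(dmean)
            stype.append(sec.stype)
            secid.append(sec.id)
            halfres.append(r_ohm / 2.0)
            xyz.append(0.5 * (p0 + p1))
            g_ax.append(0.0)  # filled below once half-resistances are known
            comp_ids.append(idx)
        last_comp[sec.id] = comp_ids[-1]
        if sec.stype == "dendrite":
            section_order.append(sec.id)
            section_diameter[sec.id] = sec.mean_diameter
        section_comps[sec.id] = comp_ids

    parent = np.array(parent, dtype=int)
    halfres = np.array(halfres, dtype=float)
    g_ax = np.zeros(len(parent))
    for i in range(1, len(parent)):
        g_ax[i] = 1.0 / (halfres[i] + halfres[parent[i]])

    return CompartmentalModel(
        parent=parent,
        g_axial=g_ax,
        area_cm2=np.array(area),
        length_um=np.array(length),
        diameter_um=np.array(diam),
        stype=np.array(stype, dtype=object),
        section_id=np.array(secid, dtype=int),
        axial_half_res=halfres,
        xyz=np.array(xyz),
        section_order=section_order,
        section_diameter=section_diameter,
        section_compartments=section_comps,
        meta={"max_seg_length": max_seg_length, "Ra": Ra},
    )


# ---------------------------------------------------------------------------
# Membrane assignment and spines
# ---------------------------------------------------------------------------

def assign_passive(
    model: CompartmentalModel, params: PassiveParams | None = None
) -> CompartmentalModel:
    """Set per-compartment membrane conductance and capacitance."""
    params = params or PassiveParams()
    n = model.n
    Gm = np.empty(n)
    Cm = np.empty(n)
    for i in range(n):
        st = model.stype[i]
        d = model.diameter_um[i]
        if st == "soma":
            Gm[i], Cm[i] = params.Gm_soma, params.Cm_soma
        elif st == "dendrite":
            Gm[i] = params.Gm_other
            if params.spine_mode == "explicit":
                Cm[i] = params.Cm_large_dendrite
            elif d >= SPINY_MAX_DIAMETER:
                Cm[i] = params.Cm_large_dendrite
            else:
                Cm[i] = float(cm_spiny(d))
        elif st == "myelin":
            Gm[i], Cm[i] = params.Gm_myelin, params.Cm_myelin
        elif st in ("axon", "AIS", "node_of_ranvier"):
            Gm[i], Cm[i] = params.Gm_other, 1.0
        elif st == "spine_neck":
            Gm[i], Cm[i] = params.Gm_other, 3.0
        elif st == "spine_head":
            Gm[i], Cm[i] = params.Gm_other, 2.0
        else:
            raise MorphologyError(f"compartment {i}: unclassified type {st!r}")
    out = replace(model)
    out.g_m = Gm * model.area_cm2
    out.c_m = Cm * model.area_cm2 * 1e-6  # µF -> F
    out.meta = dict(model.meta, params=params)
    return out


def scaffold_spines(
    model: CompartmentalModel,
    spec: SpineSpec,
    seed: int,
    params: PassiveParams | None = None,
) -> CompartmentalModel:
    """Attach explicit two-compartment spines to spiny dendritic sections.

    Each spiny section receives round(density * length) spines at seeded
    uniform positions; each spine is a neck compartment (child of the host
    dendritic compartment) plus a head compartment (child of the neck), both
    with leak conductance and the spec's capacitances.
    """
    if not model.assigned:
        raise ValueError("assign_passive must run before scaffold_spines")
    params = params or model.meta.get("params") or PassiveParams()
    if spec.density == 0:
        out = replace(model)
        out.meta = dict(model.meta, spine_warning="zero density: no spines added")
        return out
    rng = np.random.default_rng(seed)
    Ra = params.Ra

    def cyl(Lum, dum, Cm):
        a = math.pi * dum * Lum * _UM2_TO_CM2
        r = Ra * Lum * 1e4 / (math.pi * (dum / 2.0) ** 2)
        return a, r, params.Gm_other * a, Cm * a * 1e-6

    neck_a, neck_r, neck_g, neck_c = cyl(spec.neck_length, spec.neck_diameter,
                                         spec.Cm_neck)
    head_a, head_r, head_g, head_c = cyl(spec.head_length, spec.head_diameter,
                                         spec.Cm_head)

    new_parent, new_gax, new_area, new_len, new_diam = [], [], [], [], []
    new_st, new_sec, new_half, new_xyz, new_gm, new_cm = [], [], [], [], [], []
    idx0 = model.n
    n_spines = 0
    for sid in model.spiny_sections():
        comps = model.section_compartments[sid]
        lens = model.length_um[comps]
        L = float(lens.sum())
        k = int(math.floor(spec.density * L + 0.5))
        if k == 0:
            continue
        pos = np.sort(rng.uniform(0.0, L, size=k))
        host = np.array(comps)[
            np.clip(np.searchsorted(np.cumsum(lens), pos, side="right"),
                    0, len(comps) - 1)
        ]
        for h in host:
            neck = idx0 + len(new_parent)
            new_parent.append(int(h))
            new_gax.append(1.0 / (neck_r / 2.0 + model.axial_half_res[h]))
            new_area.append(neck_a)
            new_len.append(spec.neck_length)
            new_diam.append(spec.neck_diameter)
            new_st.append("spine_neck")
            new_sec.append(sid)
            new_half.append(neck_r / 2.0)
            new_xyz.append(model.xyz[h])
            new_gm.append(neck_g)
            new_cm.append(neck_c)
            new_parent.append(neck)
            new_gax.append(1.0 / (head_r / 2.0 + neck_r / 2.0))
            new_area.append(head_a)
            new_len.append(spec.head_length)
            new_diam.append(spec.head_diameter)
            new_st.append("spine_head")
            new_sec.append(sid)
            new_half.append(head_r / 2.0)
            new_xyz.append(model.xyz[h])
            new_gm.append(head_g)
            new_cm.append(head_c)
        n_spines += k

    out = CompartmentalModel(
        parent=np.concatenate([model.parent, np.array(new_parent, dtype=int)]),
        g_axial=np.concatenate([model.g_axial, new_gax]),
        area_cm2=np.concatenate([model.area_cm2, new_area]),
        length_um=np.concatenate([model.length_um, new_len]),
        diameter_um=np.concatenate([model.diameter_um, new_diam]),
        stype=np.concatenate([model.stype, np.array(new_st, dtype=object)]),
        section_id=np.concatenate([model.section_id, np.array(new_sec, dtype=int)]),
        axial_half_res=np.concatenate([model.axial_half_res, new_half]),
        xyz=np.vstack([model.xyz, np.array(new_xyz).reshape(-1, 3)])
        if new_xyz else model.xyz,
        g_m=np.concatenate([model.g_m, new_gm]),
        c_m=np.concatenate([model.c_m, new_cm]),
        section_order=list(model.section_order),
        section_diameter=dict(model.section_diameter),
        section_compartments=dict(model.section_compartments),
        n_spines=model.n_spines + n_spines,
        meta=dict(model.meta, spine_spec=spec, spine_seed=seed),
    )
    return out


def realized_spine_density(model: CompartmentalModel) -> float:
    """Spines per µm of spiny dendritic length actually scaffolded."""
    spiny_len = sum(
        float(model.length_um[model.section_compartments[sid]].sum())
        for sid in model.spiny_sections()
    )
    return model.n_spines / spiny_len if spiny_len > 0 else 0.0


# ---------------------------------------------------------------------------
# Frequency-domain solution
# ---------------------------------------------------------------------------

def _axial_laplacian(model: CompartmentalModel) -> sp.csc_matrix:
    n = model.n
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i in range(1, n):
        p = model.parent[i]
        g = model.g_axial[i]
        diag[i] += g
        diag[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return (L + sp.diags(diag)).tocsc()


def admittance_matrix(model: CompartmentalModel, frequency_hz: float) -> sp.csc_matrix:
    if not model.assigned:
        raise ValueError("assign_passive must run before solving impedance")
    omega = 2.0 * math.pi * frequency_hz
    Y = _axial_laplacian(model).astype(complex)
    Y += sp.diags(model.g_m + 1j * omega * model.c_m)
    return Y.tocsc()


def _profile_from_solution(model, source, frequency_hz, v) -> ImpedanceProfile:
    return ImpedanceProfile(
        source=int(source),
        frequency_hz=frequency_hz,
        magnitude_mohm=np.abs(v) / 1e6,
        phase_rad=np.angle(v),
    )


def transfer_impedance(
    model: CompartmentalModel, source: int, frequency_hz: float = 10.0
) -> ImpedanceProfile:
    """|Z| (MΩ) from ``source`` to every compartment at one frequency."""
    Y = admittance_matrix(model, frequency_hz)
    rhs = np.zeros(model.n, dtype=complex)
    rhs[source] = 1.0
    v = spla.spsolve(Y, rhs)
    return _profile_from_solution(model, source, frequency_hz, v)


def transfer_impedance_many(
    model: CompartmentalModel, sources, frequency_hz: float = 10.0
) -> list[ImpedanceProfile]:
    """Impedance profiles for many sources reusing one sparse factorization."""
    Y = admittance_matrix(model, frequency_hz)
    lu = spla.splu(Y)
    out = []
    for s in sources:
        rhs = np.zeros(model.n, dtype=complex)
        rhs[s] = 1.0
        v = lu.solve(rhs)
        out.append(_profile_from_solution(model, s, frequency_hz, v))
    return out


def rin_step_protocol(
    model: CompartmentalModel,
    v_step1: float = -70.0,
    v_step2: float = -80.0,
) -> float:
    """Input resistance (MΩ) from a two-level somatic voltage-clamp step.

    The soma is clamped at ``v_step1`` then ``v_step2`` (mV); R_in is the
    voltage difference over the steady-state electrode-current difference.
    For a passive model this equals the DC input impedance at the soma.
    """
    if not model.assigned:
        raise ValueError("assign_passive must run before the R_in protocol")
    params = model.meta.get("params") or PassiveParams()
    E = params.E_leak * 1e-3  # volts
    s = model.soma_index
    A = _axial_laplacian(model) + sp.diags(model.g_m)
    A = A.tocsc()
    n = model.n
    others = np.array([i for i in range(n) if i != s])
    b = model.g_m * E

    def electrode_current(v_clamp_mv: float) -> float:
        V = v_clamp_mv * 1e-3
        if len(others):
            Aoo = A[others][:, others]
            Aos = np.asarray(A[others][:, [s]].todense()).ravel()
            vo = spla.spsolve(Aoo, b[others] - Aos * V)
            Aso = np.asarray(A[[s]][:, others].todense()).ravel()
            return float(A[s, s] * V + Aso @ vo - b[s])
        return float(A[s, s] * V - b[s])

    I1 = electrode_current(v_step1)
    I2 = electrode_current(v_step2)
    dv = (v_step1 - v_step2) * 1e-3
    return dv / (I1 - I2) / 1e6


# ---------------------------------------------------------------------------
# Analytic validation geometry
# ---------------------------------------------------------------------------

def cylinder_model(
    length_um: float,
    diameter_um: float,
    n_comp: int,
    params: PassiveParams | None = None,
    Gm: float | None = None,
    Cm: float | None = None,
) -> CompartmentalModel:
    """Uniform sealed cylinder discretized into ``n_comp`` compartments.

    A validation geometry: its DC input impedance at one end has the closed
    cable-theory form R_inf * coth(L / lambda).
    """
    params = params or PassiveParams()
    Gm = params.Gm_other if Gm is None else Gm
    Cm = params.Cm_large_dendrite if Cm is None else Cm
    dx = length_um / n_comp
    r = diameter_um / 2.0
    area = math.pi * diameter_um * dx * _UM2_TO_CM2
    half = params.Ra * (dx / 2.0) * 1e4 / (math.pi * r * r)
    parent = np.arange(-1, n_comp - 1)
    g_ax = np.zeros(n_comp)
    g_ax[1:] = 1.0 / (2.0 * half)
    model = CompartmentalModel(
        parent=parent,
        g_axial=g_ax,
        area_cm2=np.full(n_comp, area),
        length_um=np.full(n_comp, dx),
        diameter_um=np.full(n_comp, diameter_um),
        stype=np.array(["dendrite"] * n_comp, dtype=object),
        section_id=np.zeros(n_comp, dtype=int),
        axial_half_res=np.full(n_comp, half),
        xyz=np.column_stack(
            [np.arange(n_comp) * dx + dx / 2, np.zeros(n_comp), np.zeros(n_comp)]
        ),
        meta={"params": params},
    )
    model.g_m = np.full(n_comp, Gm * area)
    model.c_m = np.full(n_comp, Cm * area * 1e-6)
    return model
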