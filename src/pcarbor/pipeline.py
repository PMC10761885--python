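"""Cohort-level orchestration: per-cell analyses, species statistics, ratios.

``run_pipeline`` drives the full comparison on a synthetic (or supplied)
cohort: morphometrics (including fractal dimension), the passive impedance
model (input resistance, independence analysis), per-species means ± sd,
human/mouse ratios of the cohort means, combinatorial capacity per species,
and unpaired two-sample t-tests per metric. It is deterministic for a given
(config, seed) pair.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .fractal import box_count_dimension, rasterize
from .independence import capacity, capacity_sci, independence_analysis
from .morphology import read_swc
from .morphometrics import morphometric_report
from .passive import (
    HUMAN_SPINES,
    MOUSE_SPINES,
    PassiveParams,
    assign_passive,
    discretize,
    rin_step_protocol,
    scaffold_spines,
)
from .synthetic import HUMAN, MOUSE, generate_cohort

__all__ = [
    "CohortReport",
    "default_config",
    "run_pipeline",
    "two_sample_ttest",
    "RATIO_METRICS",
]

#: metrics whose human/mouse cohort-mean ratios are reported
RATIO_METRICS = {
    "length": "total_dendritic_length",
    "spines": "spine_count_estimate",
    "dci": "dci",
    "surface": "dendritic_surface_area",
    "n_independent": "n_independent",
}

TTEST_METRICS = [
    "total_dendritic_length",
    "n_sections",
    "n_spiny",
    "spine_count_estimate",
    "max_branch_order",
    "dci",
    "fractal_dimension",
    "dendritic_surface_area",
    "rin_mohm",
    "n_independent",
]


def default_config() -> dict:
    return {
        "cohort": {"n_mouse": 19, "n_human": 6, "seed": 0},
        "morphometrics": {"spine_density": 2.0},
        "fractal": {"size": 1024},
        "model": {"max_seg_length": 5.0},
        "impedance": {"frequency_hz": 10.0, "threshold_mohm": 10.0, "stride": 20},
        "ttest": {"equal_var": True},
    }


@dataclass
class CohortReport:
    cells: pd.DataFrame  # one row per cell
    species_summary: pd.DataFrame  # mean ± sd per species and metric
    ratios: dict[str, float]  # human mean / mouse mean
    capacity: dict[str, dict]  # per species: n, K, scientific form
    ttests: dict[str, dict]  # per metric: t, p
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cells": self.cells.to_dict(orient="records"),
                "species_summary": self.species_summary.to_dict(orient="records"),
                "ratios": self.ratios,
                "capacity": self.capacity,
                "ttests": self.ttests,
                "config": self.config,
                "note": "no multiple-testing correction applied",
            },
            indent=1,
            default=float,
        )


def two_sample_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Unpaired two-sample t-test (pooled by default, Welch optional).

    Degenerate case (zero variance in both groups, equal means) returns
    (0.0, 1.0) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _analyze_cell(species, cid, seed, morph, cfg) -> dict:
    img = rasterize(morph, size=cfg["fractal"]["size"])
    fd = box_count_dimension(img).dimension
    rep = morphometric_report(
        morph,
        spine_density=cfg["morphometrics"]["spine_density"],
        fractal_dimension=fd,
    )
    # R_in on the spine-compensated (implicit) model, as in model validation
    base = discretize(morph, cfg["model"]["max_seg_length"])
    model = assign_passive(base, PassiveParams())
    rin = rin_step_protocol(model)
    # independence on the explicit-spine model, as in the spiny-model
    # impedance analysis
    spines = HUMAN_SPINES if species == "human" else MOUSE_SPINES
    explicit = PassiveParams(spine_mode="explicit")
    spiny_model = scaffold_spines(
        assign_passive(base, explicit), spines, seed=seed, params=explicit
    )
    imp = cfg["impedance"]
    ind = independence_analysis(
        spiny_model,
        stride=imp["stride"],
        frequency_hz=imp["frequency_hz"],
        threshold_mohm=imp["threshold_mohm"],
    )
    row = {"cell_id": cid, "species": species, "seed": seed}
    row.update(rep.to_dict())
    row.update(
        rin_mohm=rin,
        mean_costimulated=ind.mean_count,
        sd_costimulated=ind.sd_count,
        n_sources=ind.n_sources,
        n_spiny_dendrites=ind.n_spiny_dendrites,
        n_independent=ind.n_independent,
    )
    return row


def run_pipeline(config: dict | str | None = None, out_dir: str | None = None
                 ) -> CohortReport:
    """Run the full cohort comparison; optionally write CSV/JSON artifacts."""
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = default_config()
    for key, val in (config or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown config section {key!r}")
        cfg[key].update(val)

    cohort = cfg["cohort"]
    swc_dir = cohort.get("swc_dir")
    if swc_dir:
        cells = []
        for fn in sorted(os.listdir(swc_dir)):
            if fn.endswith(".swc"):
                species = "human" if fn.startswith("human") else "mouse"
                cells.append(
                    (species, fn[:-4], 0, read_swc(os.path.join(swc_dir, fn)))
                )
    else:
        cells, _ = generate_cohort(
            n_mouse=cohort["n_mouse"],
            n_human=cohort["n_human"],
            seed=cohort["seed"],
        )

    rows = [_analyze_cell(sp, cid, sd, m, cfg) for sp, cid, sd, m in cells]
    table = pd.DataFrame(rows)

    num = table.select_dtypes("number").columns
    summary = (
        table.groupby("species")[list(num)]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]

    means = table.groupby("species")[list(num)].mean()
    ratios = {}
    if {"human", "mouse"} <= set(means.index):
        for name, col in RATIO_METRICS.items():
            ratios[name] = float(means.loc["human", col] / means.loc["mouse", col])

    cap = {}
    for sp in means.index:
        n_ind = float(means.loc[sp, "n_independent"])
        n_round = int(np.floor(n_ind + 0.5))
        K = capacity(n_round)
        cap[sp] = {"n_independent": n_ind, "n": n_round,
                   "capacity": str(K), "capacity_sci": capacity_sci(K)}

    ttests = {}
    if {"human", "mouse"} <= set(table["species"].unique()):
        hu = table[table.species == "human"]
        mo = table[table.species == "mouse"]
        for col in TTEST_METRICS:
            if col in table.columns:
                t, p = two_sample_ttest(hu[col], mo[col],
                                        cfg["ttest"]["equal_var"])
                ttests[col] = {"t": t, "p": p}

    report = CohortReport(table, summary, ratios, cap, ttests, cfg)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "cells.csv"), index=False)
        summary.to_csv(os.path.join(out_dir, "species_summary.csv"), index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
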