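# pcarbor

Morphometrics, passive impedance modelling and combinatorial-capacity
estimation for cerebellar Purkinje cells, built around a mouse-versus-human
comparison. Human Purkinje cells are several-fold larger than mouse cells —
longer dendrites, more spines, more dendritic trunks — while keeping a similar
fractal organisation and similar firing behaviour. This package quantifies
what that size difference buys computationally: how many electrotonically
independent dendritic subunits a tree supports, and hence how many binary
input patterns K = 2^n it can in principle distinguish.

It is an analysis project: every computation lives in the library under
`src/pcarbor/`, the numbered scripts under `analysis/` drive the cohort-level
comparison, and a synthetic-morphology generator reproduces the published
cohort statistics so the whole pipeline runs with no downloads.

## What it computes

**Morphometrics** (`morphology`, `morphometrics`, `fractal`): SWC reading/
writing and validation, dendrograms with branch orders, diameter-based zone
classification (spiny < 1.6 µm, trunk 1.6–3.3 µm, main trunk > 3.3 µm, with
afferent targets aa/pf/cf/SC), spine estimates at 2 spines/µm, frustum surface
areas, box-counting fractal dimension of the planar projection, and the
dendritic complexity index

    DCI = (Σ branch-tip orders + N° branch tips)
          × (total dendritic length / N° primary dendrites).

**Passive model** (`passive`): compartmental discretization (default 5 µm),
axial coupling from R_a = 122 Ω·cm, leak G_m = 0.003 / 0.0003 S/cm²
(soma / elsewhere), E_leak = −61 mV, and the spine-compensation capacitance of
thin dendrites

    C_m(d) = 11.510294^(−1.376463·d) + 2.120503  µF/cm²,

or explicit two-compartment spines (neck C_m = 3, head C_m = 2 µF/cm²,
2 spines/µm) with a uniform dendritic C_m = 2 µF/cm². Transfer impedance is
solved sparsely in the frequency domain; R_in comes from a two-level somatic
voltage-clamp protocol.

**Independence and capacity** (`independence`): a 10 Hz current injected at
every 20th spiny dendrite; dendrites with transfer impedance ≥ 10 MΩ count as
co-stimulated; n = N / mean(count) independent elements; K = 2^round(n) in
exact integer arithmetic (30 × 30 µm ROI grids with seeded 30% spine
subsampling are also provided).

**Electrophysiology** (`ephys`, `synthetic`): spike detection and the feature
set (rate, ISI CV, AP amplitude/width, AHP depths, voltage base, sag ratio),
validation gates (spontaneous 5–50 Hz, ≤ 150 Hz at 0.5 nA, ≤ 200 Hz at 1 nA,
burst windows 9–10 / 4–6 / 3–4 spikes at 50 / 100 / 200 Hz), and generators
for ground-truth-annotated traces.

## Worked example

```python
from pcarbor.synthetic import MOUSE, HUMAN, generate_morphology
from pcarbor.morphometrics import morphometric_report
from pcarbor.passive import PassiveParams, assign_passive, discretize, rin_step_protocol

mouse = generate_morphology(MOUSE, seed=7)
rep = morphometric_report(mouse)
print(round(rep.total_dendritic_length), rep.n_spiny, rep.spine_count_estimate)
model = assign_passive(discretize(mouse, 5.0), PassiveParams())
print(round(rin_step_protocol(model), 1))
```

prints

```
2183 677 3938
16.7
```

— a 2.18 mm mouse dendritic tree with 677 spiny sections carrying ≈ 3900
spines at 2/µm, and an input resistance of 16.7 MΩ.

The cohort-level comparison (`python analysis/06_report.py --seed 0`) builds
19 mouse and 6 human cells and ends with

```
capacity per species:
  human: n = 20.8 -> K = 2^21 = 2.0e6
  mouse: n = 2.4 -> K = 2^2 = 4
```

with human/mouse cohort ratios of 6.8 (dendritic length), 6.7 (spines), 6.7
(surface area) and 8.5 (independent elements): the purely passive models
already reproduce the directional finding that the human tree supports
many-fold more independent dendritic subunits, while the absolute n values
stay below estimates from models with active membrane (see
`docs/methods.md`).

The analysis scripts in order: `01_simulate_cohort.py` (SWC cohort +
manifest), `02_morphometry.py`, `03_passive_impedance.py` (R_in versus
length, impedance profiles), `04_independence_capacity.py`,
`05_ephys_features.py`, `06_report.py` (full report with ratios and unpaired
t-tests). Each accepts `--seed` and `--out` and writes under `results/`.

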