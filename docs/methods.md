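# Methods

## Scope and shape

The package reconstructs, on synthetic data, a comparative analysis of mouse
and human Purkinje-cell (PC) dendrites: classical morphometrics, a passive
compartmental model solved in the frequency domain, and an
impedance-threshold estimate of how many independent dendritic subunits a
tree supports (and hence its combinatorial capacity K = 2^n). Active
membrane, synaptic kinetics, conductance optimization and time-domain
simulations of synaptic stimulation are deliberately out of scope: the
supported conclusions are arithmetic identities (capacity, ratios),
closed-form-checked solver behaviour, and *directional* cross-species
comparisons on synthetic cohorts.

## Morphology model and SWC dialects

A morphology is a rooted tree of sections (unbranched runs of 3D points with
diameters, µm) with the soma as root. On SWC read, sections are split at
every branch point; a child whose first node coincides with its parent's last
node is accepted as the duplication dialect, otherwise the parent's
attachment point is prepended so geometry is connected. On write, a section's
first point is emitted only when it does not duplicate the parent's last
point (same coordinates and diameter), making read(write(m)) exact for
topology, lengths and per-point diameters. A traced soma contour maps to an
equivalent cylinder whose length and diameter equal the diameter of the
circle with the contour's enclosed area; a single-point soma maps to L =
diam = d, whose cylinder lateral area equals the sphere area. Tissue
shrinkage corrections (isotropic 0.81; optional extra 0.84 on z) are shipped
as named presets and never applied silently — whether whole-cell z correction
applies is a per-dataset choice exposed in the API.

The diameter of a section is its length-weighted mean; zone classification
uses half-open intervals so the partition is exhaustive: spiny [0, 1.6) µm,
trunk [1.6, 3.3] µm, main trunk (3.3, ∞) µm; afferent targets: ascending
axon (0, 0.75), parallel fiber [0.75, 1.6), climbing fiber ≥ 1.6, stellate
[0.3, 1.6) µm.

## Branch orders and DCI

The order of a section is the number of dendritic sections on its soma path,
inclusive (an unbranched stem's tip has order 1). The alternative reading of
"branch tip order" — branches emanating from the tip path — would shift
absolute DCI values; our convention is stated, tested against an independent
path-walking traversal, and used consistently, so within-package comparisons
and ratios are unaffected. Absolute DCI values are therefore only
approximately comparable with published absolute numbers; ratios are the
supported comparison.

## Box-counting dimension

The dendritic arbor is projected on its two largest-extent axes (PC trees
are nearly planar), normalized to a 1024×1024 raster with a 2% margin, and
each section is stroked at its diameter in pixels. Spiny sections are
widened by a 2 µm spine halo — an imaged spiny dendrite appears as the
envelope of its spines, not as its shaft — and the soma is drawn filled;
`stroke_diameters=False` gives the 1-pixel skeleton instead. This choice is
load-bearing: skeleton rasters of realistic trees give dimensions ~1.3–1.55
and lose the cross-species similarity, while stroked rasters give ~1.5–1.7
for both species, indistinguishable by unpaired t-test at cohort level.

Counts use origin-anchored grids at 40 box sizes log-spaced on [0.01, 1] of
the image extent. The dimension is the least-squares slope of log N versus
log(1/s) over the linear regime: scales with N ≤ 4, N equal to the
foreground pixel count (saturation), or fewer than 8 boxes per image side
(integer-covering bias) are excluded. Reference shapes calibrate the
estimator: filled square 1.96, line 0.98, Sierpinski triangle (depth 9)
1.578 versus log3/log2 ≈ 1.585. Because stroke widths are physical (spines
do not scale with the cell), exact scale invariance of the dimension holds
for the skeleton raster; stroked rasters are intentionally scale-aware.

## Passive model

Compartments are iso-arclength splits of each section, default max 5 µm
(halving this changes R_in by < 1% on cohort trees; spine compartments are
never subdivided). Membrane: C_m = 1 µF/cm² (soma), 2 µF/cm² (dendrites
≥ 1.6 µm), and for thin spiny dendrites the spine-compensation function
C_m(d) = 11.510294^(−1.376463 d) + 2.120503 µF/cm², evaluated on the
compartment's own mean diameter; G_m = 0.003 S/cm² (soma), 0.0003 S/cm²
elsewhere; E_leak = −61 mV; R_a = 122 Ω·cm; myelin G_m = 5.60e−9 S/cm²,
C_m = 1.87e−11 µF/cm². In explicit-spine mode the dendritic C_m is uniform
at 2 µF/cm² and each spine is a neck (0.7 × 0.2 µm mouse, 0.72 × 0.18 µm
human; C_m = 3) plus head (0.35 × 1.0 / 0.26 × 1.0 µm; C_m = 2) cylinder
pair with leak on both, at 2 spines/µm placed at seeded uniform positions
per spiny section.

Axial conductances couple compartment centres through series
half-resistances, with the exact frustum integral R = R_a Σ ds/(π r₁ r₂)
for linear taper. Impedance is solved directly in the frequency domain — one
sparse complex factorization of G + iωC + L_axial per (model, frequency),
reused across sources — which for a linear model is identical to time-domain
sinusoid injection but deterministic and fast. The solver is validated
against the sealed-cable closed form R_∞·coth(L/λ) to < 0.1% at n = 1000
compartments, and satisfies reciprocity to 1e−9.

R_in uses the two-level somatic voltage-clamp protocol (−70 / −80 mV): since
the passive membrane time constant (≈ 6.7 ms) is far shorter than the 100 ms
steps, the steady-state clamp currents are computed directly by linear
solves; R_in = 10 mV / ΔI, which equals the DC input impedance at the soma.

## Independence and capacity

Sources are the midpoint compartments of every 20th spiny section in
dendrogram depth-first order. A spiny section counts as co-stimulated when
any of its compartments has |Z| ≥ 10 MΩ from the source at 10 Hz (the
source's own section always qualifies; "too distant to interact" is the same
test from the other side). With N spiny sections, n = N / mean(count) and
K = 2^round(n) exactly (round half up; n is reported real-valued). The
scientific form of K truncates the mantissa — the quoted figure is a lower
bound on the exact count — so 2^51 prints as 2.2e15.

The pipeline computes independence on explicit-spine models: on passive
trees without the spine membrane load the mouse tree is fully coupled at the
10 MΩ threshold (every count = N). Even with spines, absolute n values (≈ 2–4
mouse, ≈ 19–29 human on synthetic cohorts) stay below estimates from models
with active membrane at rest, whose resting conductance shortens the
electrotonic length; the supported result is the direction and magnitude of
the species ratio (≈ 8 here), not absolute n. ROI grids (30 × 30 µm) with
seeded 30% subsampling are provided for localized-stimulation bookkeeping.

## Spike features and gates

Spikes are upward crossings of −20 mV separated by ≥ 1 ms. AP amplitude is
peak minus the threshold-crossing voltage; width at half amplitude; AHP
absolute is the inter-spike minimum and AHP slow the minimum over the last
50% of each ISI (the window is our convention; the feature name alone does
not pin one down); voltage base is the median of pre-stimulus samples; mean
frequency is (count − 1)/(last − first); ISI CV uses the sample standard
deviation over the mean (the convention of the standard feature libraries,
matching the worked value 0.4714 for ISIs {10, 20} ms). Sag ratio is
(peak − steady)/peak deflection relative to the pre-step baseline. Validation
gates: spontaneous rate within 5–50 Hz, ≤ 150 Hz at 0.5 nA, ≤ 200 Hz at
1 nA, burst windows 9–10 / 4–6 / 3–4 spikes at 50 / 100 / 200 Hz; missing
protocols leave a gate unevaluated and the conjunction fails closed.

## Synthetic cohorts

The generator draws, per cell: trunk count (mouse 1 w.p. 0.895, 2 w.p.
0.105; human 1/2/3 w.p. 0.2/0.4/0.4), a target total length from a normal
clipped to ±2 sd (mouse 2782.59 ± 671.12 µm; human mean 20166.96 µm with the
sd truncated to 30% of the mean — the published dispersion, ≈ 76% of the
mean, would make degenerate draws likely), trunk diameters U(3.5, 6) µm and
per-tip terminal thresholds U(0.3, 0.6) µm. Topology grows by recursive
bifurcation with a diameter-conservation split d_p^e = d₁^e + d₂^e: the
thin spiny chains use the classic 3/2 rule with strong asymmetry (main-child
share w ~ U(0.74, 0.90) mouse, U(0.82, 0.94) human — deeper chains in
human), while the thick scaffold uses a higher exponent (2.0 mouse, 2.2
human) and milder asymmetry, because a strict 3/2 rule starting at ≤ 6 µm
cannot carry a realistically wide trunk ramification. Draws are retried (same
seed stream, bounded) until the maximum branch order lands in the species
range (mouse 12–25, human 18–41).

Section lengths are drawn per zone (aspiny base lengths 2–3× spiny, setting
the spiny share of total length near 90%) and globally scaled so the realized
total equals the drawn target exactly; geometry is embedded afterwards in the
plane (z jitter clipped to ±4 µm) with ~40° side-branch angles and a strong
per-step meander that folds chains compactly — mouse arbors span ≈ 160 µm and
human ≈ 600–1000 µm, matching the ~1 mm parasagittal extent of real human
PCs. Branch self-avoidance is not enforced; no measured quantity depends on
self-intersection. Per-cell seeds derive from a master seed via
`SeedSequence([master, index])`; identical seeds give byte-identical SWC.

What the generator does not emulate: real reconstruction noise (missing
branches, diameter jitter from imaging), the exact section-count
distributions of the published cohorts, the spatial anisotropy of the
molecular layer, or any correlation between morphology and physiology.
Passing cohort tests therefore demonstrate that the pipeline recovers the
statistics the generator encodes, and that the cross-species directionality
is robust — not that the generator is a substitute for real reconstructions.

Voltage traces are analytic: a stereotyped AP template passing exactly
through the detection threshold at the spike sample (so template amplitude is
recovered exactly in the noise-free case), optional ISI jitter and Gaussian
noise, and a double-exponential sag step whose rise is ≥ 99.9% complete at
the measured peak so the built-in sag fraction is recovered to ± 0.01.

## Statistics

Species comparisons use the unpaired two-sample t-test (pooled variance by
default, Welch optional); zero-variance identical groups return p = 1 by
convention. No multiple-testing correction is applied, and the report footer
says so. Ratios are quotients of cohort means recomputed from the per-cell
table.

## Problem sizes

Defaults used by the analysis scripts: 19 mouse + 6 human cells, 5 µm
compartments (mouse ≈ 600, human ≈ 4000 compartments; explicit-spine models
≈ 10k / 66k), stride-20 sources, 1024² rasters. The test suite uses smaller
cohorts and 10 µm compartments where the property under test permits, chosen
so the whole suite exercises every code path at cohort scale.

## Known limitations

- No active membrane: absolute R_in and impedance exceed values from models
  with resting active conductance; absolute n_independent is correspondingly
  conservative.
- The DCI order convention shifts absolute values against alternatives (see
  above); compare ratios.
- Box dimension depends on the rendering convention (stroke versus skeleton);
  both are exposed and the choice is documented per result.
- The generator's dispersion of section counts between seeds is wider than in
  the published cohorts; cohort means, not per-cell counts, are the
  calibrated quantities.
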