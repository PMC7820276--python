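# Methods

`pahmsc` re-implements, as a tested pipeline, the transcriptome and
phenotype analysis of a five-arm rat study of mesenchymal stem cell
(MSC) therapy in monocrotaline (MCT)-induced pulmonary hypertension:
conditions CON, MCT+Saline, MCT+AD, MCT+BM and MCT+UCB with two
biological replicates per condition on a single-channel expression
array.  Because no expression data are deposited for the original
study, the pipeline is driven by a synthetic-data generator that plants
known effects, so every stage can be validated against ground truth.

## Preprocessing

Linear intensities are converted to log2 (`log2(value + offset)`) and
quantile-normalized.  The reference distribution is the row-wise mean
of the per-sample sorted columns; each value is replaced by the
reference at its within-column rank.  Ties receive average ranks with
the reference linearly interpolated at the fractional rank.  This keeps
the grand mean exactly and is idempotent on tie-free data; when ties
are present, tied entries share the mean reference value over their
rank span (strict idempotence can then be perturbed in *other* columns
because the shared reference changes — a known property of every
rank-based tie rule, not specific to this implementation).

## The integrative differential-expression statistic

For a two-condition contrast, each gene gets

* a pooled-variance Student *t* (df = n₁ + n₂ − 2).  Pooled standard
  deviations are floored at the 1st percentile of the gene-wise pooled
  SDs (minimum 1e-8) so that degenerate two-replicate groups cannot
  produce infinite statistics;
* the log2-median-ratio (LMR): difference of group medians on the log2
  scale, equal to the log2 ratio of linear-scale medians.

**Empirical nulls.**  Sample labels within the contrast are permuted
and both statistics recomputed for every gene; the permuted values are
pooled across genes into one null vector per statistic.  For the
study's 2 vs 2 design the distinct non-identity label partitions are
enumerated exhaustively (two of them, with the balanced-design
complement symmetry deduplicated); resolution comes from pooling across
all genes, not from the number of splits.  Larger designs can use
`n_perm` random shuffles.  The pooled null is smoothed with a Gaussian
kernel (Silverman's rule on the sign-symmetrized sample, so that
exchanging test and reference labels leaves every p-value exactly
invariant) and the two-sided empirical p-value is the closed-form
mixture tail

    p = (1/M) Σᵢ [ Φ((−|s| − xᵢ)/h) + 1 − Φ((|s| − xᵢ)/h) ]

clamped to `[1/(M+1), 1]`, with `M` the pooled null size.

**Combination.**  The two p-values are mapped to signed z-scores
(`z = ±Φ⁻¹(1 − p/2)`, carrying the sign of the effect) and combined
with Stouffer's equal-weight rule `z_comb = (z_t + z_lmr)/√2`.  A sign
conflict between *t* and LMR (possible since medians and means can
disagree) attenuates `z_comb` naturally and is not special-cased.

With two replicates the group median equals the group mean, so *t* and
LMR share their numerator and the two z-scores are strongly dependent
(empirically, corr ≈ 0.9 under the null).  The independence closed form
`p = 2(1 − Φ(|z_comb|))` is therefore anti-conservative by an order of
magnitude in the tails.  The pipeline consequently calibrates `z_comb`
against its own permutation null by default: the permuted statistics of
every label split are pushed through the same p-value/z machinery, the
permuted `z_comb` values are pooled across genes, and the combined
p-value is the same KDE tail read off that pooled null
(`combined_null="permutation"`).  This keeps the combined p-values
uniform under the null whatever the dependence between the two
statistics.  The closed form remains available as
`combined_null="normal"` and as the `combine_stouffer` primitive.

**FDR.**  Storey q-values with the single-λ estimate
`π̂₀ = #{p > λ}/(m(1 − λ))` (λ = 0.5 by default; λ = 0 reduces exactly
to Benjamini–Hochberg).  A spline-smoothed π₀ is deliberately avoided:
a two-replicate permutation design produces too few distinct p-values
for a stable spline fit.

**Calling rule.**  A gene is a DEG when `q ≤ 0.05` and `|LMR| ≥ 0.58`;
0.58 is `round(log2(1.5), 2)`, i.e. a 1.5-fold change.  The four study
contrasts (MCT+Saline/CON and each MSC arm vs MCT+Saline) are handled
per-comparison, with no joint multiplicity step across contrasts.

The granularity of the two-split pooled null bounds the smallest
empirical p at `1/(2m + 1)`; single isolated genes can therefore never
reach `q ≤ 0.05` on their own, and calls emerge only when several genes
populate the extreme tail together.  This is a real (and conservative)
resolution limit of the exhausted 2 vs 2 design.

## Pattern groups, reversion and predominance

A DEG's disease call (up/down/none from MCT+Saline/CON) and a consensus
treatment call across the three MSC arms ("down" if at least one arm
calls down and none up, symmetrically for "up"; direct conflicts are
left unclassified and logged) place it on a 3×3 grid labelled G1–G8.
G1 (disease-up, treatment-down), G2 (disease-none, treatment-up) and G4
(disease-down, treatment-up) are fixed; the remaining five labels
follow a documented default map and are configurable.  Within groups,
rows sort by the up/none/down pattern over the four comparisons and
then by decreasing disease |log2 fold change|.

Reversion subsets keep, per arm, the G1 genes the arm pushes down and
the G4 genes it pushes up.  The predominance selection then keeps genes
significant — same FDR/LMR rule, same machinery — in *both* head-to-head
contrasts (UCB/AD and UCB/BM) with the sign matching the reversion
direction.

## Enrichment

Gene-set enrichment is a local one-sided hypergeometric tail
`P(X ≥ k)` over a GMT library, replacing the original study's web
service.  The background defaults to all genes on the matrix.  An EASE
variant (tail at `max(k − 1, 0)`) is offered; no multiple-testing
correction is applied to enrichment p-values, which are filtered at
raw p < 0.05 and exported as −log10(p) matrices.

## Network assembly

Interaction tables are supplied as SIF files (the five-database
collection step of the original analysis is abstracted to "one or more
SIF files with a source tag" so the module runs offline).  Human ids
are translated through a two-column orthology table; edges with
unmapped endpoints are dropped and counted.  The induced subgraph over
the selected genes keeps isolated genes as attribute-only nodes; node
attributes carry the disease and treatment log2 fold changes plus a
stacked significance code (e.g. `A|U`) naming the arms that called the
gene a DEG.  Layout, edge signs and hand-curated pathway edges are out
of scope; exports are SIF plus a node-attribute TSV that round-trips
exactly.

## Phenotype formulas

Scalar indices as used in the study's phenotype readouts: pulmonary
artery systolic pressure `4V² + RAP` (the right atrial pressure is an
explicit argument — no hidden default), percent medial wall thickness
`2·thickness/diameter·100`, fibrosis index `area/short diameter`,
PCNA-positive percentage, the 2^−ΔΔCt relative qPCR quantification
(fold changes rescaled so the control-group mean is exactly 1), and
signed percent change of a group mean relative to the untreated disease
group.  Group comparisons use the two-sided Mann–Whitney U test:
exact enumeration when the combined sample is ≤ 12 and tie-free, the
tie-corrected normal approximation otherwise (the study's 7 vs 7 groups
use the approximation by default; `exact=True` overrides).  Significance
is annotated with the study's three-symbol convention (*/$/# repeated
for p < 0.05/0.01/0.001 against CON, MCT+Saline and MCT+UCB).

Note: published percent changes are reproduced from the published group
means for TR max PG (AD, UCB) and PVAT (all arms).  The published
"28.96% reduction" for TR max PG under BM-MSC is inconsistent with the
published means (61.24 → 43.93 gives 28.26%); the implementation
computes from means and documents the discrepancy rather than matching
the printed value.

## The synthetic-data generator

`generate_expression` draws per-gene baselines N(8, 2²) on the log2
scale, plants ±`effect_size` shifts on disjoint random subsets
(defaults: 10% up, 10% down) in every MCT-exposed condition, and moves
reverted genes back toward baseline in the MSC arms.  Reversion is
assigned by nested prefixes over one shuffled order of the planted
genes, so the UCB arm (defaults: 70% full + 10% partial) reverts a
strict superset of AD (40% + 10%) and BM (35% + 10%); partial
magnitudes are uniform in [0.3, 0.7]×`effect_size`.  Measurement noise
is independent Gaussian on the log2 scale, `noise_sd = 0.3` — the
minimal structure the t-test assumes and the calibration level used
throughout (together with `effect_size = 2.0`).  Replicates default to
2 to match the study; more are allowed for power studies.  Everything
is driven by one `numpy` generator seed and serializes bit-identically.

The generator works at gene level by design (the probe→gene collapsing
of the real 60k-probe array is not modeled), has no dye or batch
structure, and its noise is homoscedastic — so passing tests demonstrate
correctness of the procedure under its own assumptions, not performance
on real microarray artifacts.  Phenotype tables are Gaussian around
per-group means seeded with the published echocardiographic values
(e.g. TR max PG 61.24 mmHg for MCT+Saline); histology and cell-count
means are realistic choices, with positivity, diameter and count
constraints enforced by clipping.

## Problem sizes and numerical choices

Validation runs use the study-scale matrix (1000 genes, 5 × 2 samples).
False-discovery control is measured over 200 independent null matrices;
planted-effect recovery at effect 2.0 / noise 0.3 requires ≥ 80%
recovery with direction always correct.  Degenerate inputs are handled
explicitly: zero-variance replicate pairs yield t = 0 (not NaN), p-value
clamps avoid infinite z-scores, λ above every p triggers a π₀ = 1
fallback with a warning, identical groups in the Mann–Whitney test
return p = 1 with a warning, and enrichment ties are broken by term id
for reproducibility.
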