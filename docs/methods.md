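# Methods

This note records the model behind each stage, the defaults and why,
what the synthetic generator does and does not emulate, and the design
choices made where the procedure was genuinely open.

## Design and notation

Sixteen samples in four groups — control (C), treated control (CT),
disease model (M), treated model (MT), four replicates each — measured
at two levels: protein LFQ intensities and phosphosite intensities
(site = protein accession + residue S/T/Y + position). All analysis
operates on *relative quantitative values* `R_ij = I_ij / mean_i(I_ij)`
(mean over a feature's non-missing samples), which removes per-feature
scale and makes the row mean exactly 1. Centralisation is per row
only; no column (sample-bias) normalisation is applied, since LFQ
intensities are assumed batch-corrected upstream.

## Phosphosite correction

When both levels are measured on the same cohort, a site's relative
value is divided by its parent protein's relative value per sample,
then re-centralised. Under a multiplicative model
`site = protein × 2^(site effect + noise)` this isolates the
site-level effect exactly in the noise-free limit (a property the
tests assert). Sites without a quantified parent pass through
uncorrected and are flagged; cells with a zero protein value become
missing rather than infinite.

## QC

Per-group RSD (sd/mean, n−1 denominator) summarised by the group
median with a pass bar of 0.2 — the conventional repeatability
criterion for LFQ replicates. Sample PCA is computed on log2(R) with
feature centering and no scaling (standard for LFQ, where features
already share a scale after centralisation); components follow the
deterministic sign convention that the largest-magnitude loading is
positive.

## Trend screening and clustering

* **ANOVA screen** (protein level): classical one-way ANOVA on log2(R)
  across the four groups, keep p < 0.05. Features that are constant
  everywhere get p = 1 — constant data carry no evidence.
* **k-means overview**: k = 6 on row-standardised log2 profiles,
  k-means++ with 10 restarts, labels relabelled by descending cluster
  size for determinism. This reproduces the heatmap-partition step;
  selection does not depend on it.
* **SD filter**: keep features with sd(log2 R) > 0.2 (protein) or
  > 0.5 (phosphosite), sd over all 16 samples with the n−1
  denominator. Computing the SD over samples rather than over the
  four group means was an open choice; samples retain replicate
  information and is the default here.
* **Fuzzy c-means**: standard alternating optimisation with
  memberships `u_ij ∝ (1/d_ij²)^(1/(m−1))` and `u^m`-weighted
  centroids, on row-standardised profiles. Defaults c = 5 (protein),
  c = 7 (phosphosite), fuzzifier m = 2 (the common Mfuzz-style
  default), tolerance 1e−6 on the centroid shift, 300 iterations max.
  Initialisation is k-means++-style distance-weighted seeding, which
  avoids the degenerate start of two coincident centroids on
  duplicated profiles. The objective is non-increasing per iteration
  (asserted in tests). A feature coinciding exactly with a centroid
  takes membership 1 there (the continuity limit).
* **Phosphosite path** skips the ANOVA/k-means pre-screen and applies
  the SD filter to all sites directly: site-level group structure is
  noisier and the k-means overview adds nothing to selection.

## Treatment-reversal selection

For each centroid, group means over (C, CT, M, MT) are reduced to
three differences: CT−C, MT−M, M−C. A cluster is selected iff
`sign(CT−C) = sign(MT−M) = −sign(M−C)` and every |difference| exceeds
ε = 0.05 (standardised centroid scale; ε guards against calling a
sign on numerical noise). A feature is selected when its argmax
cluster is selected **and its total membership mass across all
selected clusters** is ≥ 0.5. Summing over selected clusters (rather
than thresholding the single argmax membership) is deliberate: with c
larger than the number of natural trend shapes, fuzzy c-means places
near-duplicate centroids on one shape and splits each feature's
membership between them; the per-cluster membership then hovers near
1/(number of duplicates) even for unambiguous features, while the mass
on the selected *shape* stays near 1. The quantity of interest is how
much of a feature's membership lies on treatment-reversed shapes.

## Enrichment

Hypergeometric upper tail `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)` —
identical to the one-sided Fisher exact test on the 2×2 overlap table
(asserted against an independent computation to 1e−10). The universe
is the set of quantified (comparable) features at that level, not the
genome; for phosphosite selections the test is run on parent proteins
against the parent universe. Raw p < 0.05 is the primary criterion;
Benjamini–Hochberg values are always reported alongside. Only
over-representation is tested. Note the hypergeometric test is
discrete, so under a true null the fraction of terms at p < 0.05 sits
at or conservatively below 0.05 (a property test checks this band).

## Contrasts, networks, hubs, concordance

Fold change is the ratio of group means of *untransformed* relative
values, while the t-test runs on log2 values — both conventions
followed literally, as is common in LFQ pipelines. The t-test pools
variance by default (Welch optional). Calls: up iff FC > 1.5 and
p < 0.05; down iff FC < 1/1.5 and p < 0.05.

Interaction edges keep combined confidence score > 0.7 (a 0–999
integer column is auto-rescaled by /1000). The per-contrast
subnetwork is induced on that contrast's differential features
(protein calls plus parents of differential sites); isolated nodes are
retained. Average degree is the mean over all nodes *including
isolates* (configurable; the reference procedure is ambiguous on
this), and hubs are nodes with degree strictly above it. Proteins hub
in all three contrasts form the concordance table; each contributes
one row per differential site (sites inherit hub status from the
parent) or a protein-only row. A row is a reversal candidate iff its
M/C direction is called, opposed by MT/M, and CT/C equals MT/M —
judged on site directions where available, protein directions
otherwise. (We additionally require M/C and MT/M to be actual calls;
a triple like up/unchanged/unchanged is not a reversal.)

## Synthetic data

The generator emulates: log-normal LFQ intensities (log2 baseline
N(20, 2²)); planted four-group trend templates added on the log2
scale; replicate noise N(0, 0.2²) on log2; phosphosites as parent
intensity × 2^(site effect + noise) with residues S/T/Y at
86/12.5/1.5%; annotation terms of 10–40 members with one term per
template at ≥ 80% purity; an Erdős–Rényi background network
(density 0.05) with Beta(2, 10) confidence scores plus a planted
hub module of 10 template proteins wired at probability 0.9 with
scores in [0.75, 0.95]; optional MCAR missingness (default 0, since
the reference procedure never states a missing-data treatment).

Default templates are `(0, −0.8, +1, 0)` and `(0, +0.8, −1, 0)` over
(C, CT, M, MT): the model shifts a feature by ±1 log2 unit, treatment
returns the treated model to baseline, and treated controls shift by
∓0.8 in the direction treatment pushes. The CT effect is deliberately
non-zero and above log2(1.5): the reversal definition requires CT/C
and MT/M to move together, so a zero CT effect would make the selected
trend pattern — and the concordance table's reversal candidates —
unobtainable by construction; 0.8 keeps it "smaller than the disease
effect" while remaining callable at FC > 1.5 with 4 replicates of 0.2
noise. The Beta(2, 10) background scores concentrate well below the
0.7 confidence threshold, reflecting that most STRING-style combined
scores are low-confidence; high-confidence structure therefore comes
from the planted module. Defaults: 200 proteins, 400 sites, a quarter
of features per template (the rest null).

What the generator does **not** emulate: peptide-to-protein inference,
intensity-dependent missingness, correlated (batch) noise, shared
peptides, network topology beyond one dense module, or realistic
annotation overlap structure. Passing recovery tests therefore shows
the pipeline's logic is correct under the stated generative model, not
that real-data performance is guaranteed.

## Problem sizes and determinism

Tests and the acceptance script run the default 200-protein /
400-site / 16-sample configuration (seconds per run); Monte-Carlo
properties use 20–200 repetitions of annotation-only simulations.
Every random choice flows from a single integer seed
(`numpy.random.default_rng`); fixing the seed fixes all outputs
byte-for-byte, which the determinism tests assert.

## Known limitations

* The completeness criterion for "comparable" features defaults to
  ≥ 50% non-missing samples and is configurable; the reference count
  it mirrors is not derivable from first principles.
* With zero-variance corrected sites (noise-free proportional data)
  the phosphosite trend stage has nothing to cluster; the pipeline
  logs this and reports an empty selection rather than failing.
* Average node degree of a published network depends on the interaction
  database snapshot and the exact differential lists; only the rule
  (degree strictly above the subnetwork mean) is reproducible, not
  historical degree values.
* Percentages are reported with standard half-up rounding at one
  decimal; rounded percentages need not sum to exactly 100.
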