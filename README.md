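# phostrend

Four-group proteomic and phosphoproteomic differential-trend analysis:
find proteins and phosphosites whose disease-model change is *reversed
by treatment*, and rank the network hubs among them.

The package targets label-free quantification (LFQ) experiments with a
2×2 design — control (C), treated control (CT), disease model (M) and
treated model (MT) — as used, for example, in rodent studies of a
physical or pharmacological intervention. It is a library first
(`import phostrend`), with a thin `phostrend` command-line wrapper and
narrative scripts in `examples/`.

## Method

1. **Relative quantification.** Raw intensities are row-centralised,
   `R_ij = I_ij / mean_i(I_ij)`, so each feature's row mean is 1.
   Phosphosite relative values are divided by the parent protein's
   relative value per sample to remove the protein-abundance component
   from the modification signal.
2. **QC.** Per-group relative standard deviation (RSD = sd/mean;
   median < 0.2 is the conventional repeatability bar) and sample PCA
   on log2 relative values.
3. **Trend clustering.** Proteins are screened by one-way ANOVA
   (p < 0.05), given a k-means overview partition (k = 6), filtered on
   the SD of log2 relative values (> 0.2 protein, > 0.5 phosphosite;
   the site level skips the ANOVA/k-means pre-screen), and
   soft-clustered by fuzzy c-means (c = 5 protein / 7 phosphosite,
   fuzzifier m = 2) on row-standardised profiles. A cluster is
   selected when its centroid's group means satisfy
   `sign(CT−C) = sign(MT−M) = −sign(M−C)` — the model's change runs
   opposite to both treatment-associated changes.
4. **Enrichment.** Selected sets are tested for annotation-term
   over-representation with the hypergeometric upper tail
   (one-sided Fisher exact), `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`;
   Benjamini–Hochberg values are reported alongside raw p.
5. **Contrasts and hubs.** Each contrast (CT/C, M/C, MT/M) is
   summarised by `FC = mean_A(R)/mean_B(R)` and a two-sample t-test on
   log2 values; FC > 1.5 (or < 1/1.5) with p < 0.05 calls a feature
   up (down). Differential features are intersected with a
   confidence-filtered interaction network (combined score > 0.7);
   nodes whose degree strictly exceeds the subnetwork's average degree
   are hubs. Proteins that are hubs in all three contrasts enter the
   concordance table, where a row whose M/C direction is opposed by
   MT/M and matched by CT/C is a **treatment-reversal candidate**.

A synthetic-data generator (`phostrend.simulate`) plants trend
templates, enriched terms and a high-confidence hub module with full
ground truth, so every stage is testable without deposited raw data.

## Worked example

```python
import phostrend as pt

ds = pt.simulate_dataset(pt.SimulationConfig(seed=1))
rel = pt.relative_quantify(ds.proteome)
screen = pt.anova_screen(rel, alpha=0.05)
filtered = pt.log2_sd_filter(rel.subset(screen.passed), sd_min=0.2)
sc = pt.fuzzy_cmeans(filtered, c=5, seed=1)
sel = pt.select_trend_clusters(sc, rel.groups)
print(sel.cluster_table[["mean_C", "mean_CT", "mean_M", "mean_MT",
                         "selected", "direction"]].round(2))
```

prints

```
         mean_C  mean_CT  mean_M  mean_MT  selected           direction
cluster
0          0.08     1.17   -1.36     0.11      True  down-in-M-reversed
1         -0.05    -1.24    1.37    -0.08      True    up-in-M-reversed
2         -0.05    -1.24    1.37    -0.08      True    up-in-M-reversed
3          0.08     1.17   -1.36     0.11      True  down-in-M-reversed
4          0.08     1.17   -1.36     0.11      True  down-in-M-reversed
```

Each row is one fuzzy cluster's centroid averaged per group (on the
standardised log2 scale): clusters 1–2 rise in the model (M above C)
and fall back under treatment (MT near C, CT pushed the same way as
MT/M), clusters 0/3/4 mirror that — all five match the reversal rule
and are selected. On this seeded dataset the 106 selected proteins
recover the 100 planted trend features with precision 0.943 and recall
1.000 (`examples/02_trend_clustering.py`), and the full pipeline
(`examples/05_full_pipeline.py`) recovers the planted 10-protein hub
module in the concordance table with precision 1.00.

The same analysis from the shell:

```sh
phostrend simulate --out data/ --seed 1
phostrend run --data-dir data/ --out results/
```

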