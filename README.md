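# mhsgtr

Multi-omics integrative clustering for cancer-subtype identification, built
around motif high-order similarity graphs, t-SVD tensor regularization and
attention-weighted consensus graph fusion (the MHSGTR model family), with a
synthetic-data generator, survival/clinical evaluation statistics, and a
command-line pipeline.

## The problem

Patients with the same cancer type differ widely in prognosis and treatment
response. Clustering patients from matched omics profiles (mRNA expression,
DNA methylation, miRNA expression over a shared sample set) can expose
molecular subtypes, but similarity-graph methods that rely only on
*first-order* pairwise similarity are fragile: omics data are
high-dimensional and noisy, and spurious edges destabilise the spectral
embedding. Two ideas address this jointly:

1. **High-order (motif) similarity.** Two samples that are adjacent *and*
   jointly close many triangles with common neighbours are far more likely
   to share a subtype than two samples joined by a lone edge. Triangle
   (motif M4) counts over a thresholded similarity graph give a
   noise-robust, high-order affinity signal.
2. **Cross-omics coupling.** Stacking the per-omics affinity graphs into a
   third-order tensor and penalising its tensor nuclear norm (t-SVD/TNN)
   pulls complementary structure across omics together, while a per-sample
   attention mechanism weights each omics view adaptively when fusing the
   graphs into a single consensus similarity used for spectral clustering.

## The model

For each view `v` with data `X^v ∈ R^{N×d_v}`:

- a sparse autoencoder (hidden dims p1/p2, ReLU hidden layers, linear
  latent) encodes `Z^v`, with an L2,1 penalty `α‖W(1)‖_{2,1}` on the first
  layer for feature-level selection, and a linear **self-expressive layer**
  `Z^v ≈ C^v Z^v` (zero diagonal) whose coefficients `C^v ∈ R^{N×N}` double
  as an affinity graph;
- a **hybrid high-order graph** `A^v = η S^v + (1−η) M^v`, where
  `S^v_ij = exp(−‖x_i−x_j‖²/2σ²)` is the Gaussian-kernel similarity,
  thresholded at its median into binary/weighted adjacencies `W^{0,1}, W`,
  `(W_M)_ij = #{k : {i,j,k} is a triangle}` the motif-count matrix, and
  `M^v = W_M ∘ W` (min-max rescaled) the motif similarity; the term
  `λ3‖A^v − C^v‖_F²` injects the high-order structure into `C^v`.

Across views, the symmetrised `C^v` are stacked into `C′ = φ(C^1..C^V)`
(rotated to N×V×N) and regularised by the tensor nuclear norm `‖C′‖_*`
(mean of Fourier-slice matrix nuclear norms, realised by a periodic
tensor singular-value-thresholding prox). An attention map
`M = softmax(LeakyReLU(C W))` produces per-sample view weights on the
simplex; the fused graph `CF = Σ_v (m_v 1ᵀ) ∘ C^v` is f1-normalised into the
consensus `S` (unit diagonal, unit off-diagonal row sums), sharpened into a
DEC-style target `P = f2(S)`, and refined by `β·KL(P‖S)`. The joint loss

```
Σ_v [ (1/2n)‖X^v−X̃^v‖_F² + α‖W(1)‖_{2,1} + λ1‖Z^v−Z^vC^v‖_F²
      + λ2‖C^v‖_F² + λ3‖A^v−C^v‖_F² ] + ‖C′‖_* + β·KL(P‖S)
```

is minimised by full-batch Adam (pretraining at lr 1e-4 on the
reconstruction + sparsity terms, joint training at lr 1e-3). Subtypes come
from normalised spectral clustering of `S`, with `k` either fixed or chosen
by the largest Laplacian eigengap in a range (default 2–6). Found subtypes
are evaluated by the multi-group log-rank test (survival separation,
reported as −log10 p) and by clinical-label enrichment (chi-square for
categorical covariates, Kruskal–Wallis for numeric ones,
Benjamini–Hochberg FDR at adjusted p < 0.05).

## Worked example

Simulate a 3-cluster, 3-view cohort of 120 samples with cluster-linked
survival, then fit and evaluate:

```
mhsgtr simulate --n-samples 120 --n-clusters 3 --view-dims 150,100,80 \
                --seed 1 --out data
mhsgtr run --config config.yaml
```

with `config.yaml`:

```yaml
view_paths: [data/view1.tsv, data/view2.tsv, data/view3.tsv]
view_kinds: [raw, raw, raw]
survival_path: data/survival.tsv
clinical_path: data/clinical.tsv
clinical_types: {assoc_label: categorical, indep_label: categorical, age: numeric}
output_dir: out
train: {hidden_dims: [64, 32], pretrain_epochs: 30, train_epochs: 80,
        n_clusters: 3, seed: 1}
```

This prints:

```
MHSGTR fit summary
============================================================
samples: 120   views: 3   clusters (k): 3
cluster sizes: C1=39, C2=41, C3=40
graph mode: hybrid (eta=0.5)   hidden dims: (64, 32)
mean attention per view: 0.788, 0.205, 0.007
...
log-rank: chi2=36.231  p=1.36e-08  -log10(p)=7.87
```

The three recovered subtypes match the planted clusters exactly (ARI 1.0
against `data/true_labels.tsv`), separate the planted exponential survival
hazards at −log10(p) ≈ 7.9, and

```
mhsgtr evaluate --labels out/labels.tsv --survival data/survival.tsv \
    --clinical data/clinical.tsv \
    --clinical-types '{"assoc_label":"categorical","indep_label":"categorical","age":"numeric"}'
```

flags exactly the two cluster-associated clinical columns (the planted
categorical label and age) as enriched while the independent negative
control stays non-significant:

```
      label           test  statistic            p   p_adjusted  significant
assoc_label     chi-square  71.981194 8.661111e-15 2.598333e-14         True
indep_label     chi-square   2.228461 6.938222e-01 6.938222e-01        False
        age kruskal-wallis  11.254704 3.598090e-03 5.397135e-03         True
significant clinical labels (BH-adjusted p < 0.05): 2
```

The same workflow applies to real cohorts: point `view_paths` at your
mRNA/methylation/miRNA matrices (TSV/CSV, samples in rows or columns), set
`view_kinds` to `expression`/`methylation` to apply the standard filters
(drop features with missing values or >30% zeros, log2(x+1), non-zero
variance; probe averaging for methylation), and provide `sample,time,event`
survival and clinical tables. `mhsgtr ablate` reruns everything with the
per-view graph swapped between first-order, motif and hybrid similarity.

Library users can do the same in Python via
`MHSGTR(dataset, TrainConfig(...)).fit()`, which returns a results object
with `labels`, `consensus`, `attention`, the per-epoch loss `trace`,
`summary()` and evaluation helpers.

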