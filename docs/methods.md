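# Methods

## Overview

`mhsgtr` clusters a shared sample set from V matched omics views. The
method has three coupled parts: (1) per-view affinity learning — a sparse
autoencoder with a linear self-expressive layer whose coefficient matrix
`C^v` is the view's affinity graph; (2) high-order regularisation — each
`C^v` is pulled toward a hybrid graph `A^v` blending Gaussian-kernel
first-order similarity with triangle-motif similarity; (3) cross-view
fusion — the stacked `C^v` are regularised by a t-SVD tensor nuclear norm,
fused by per-sample attention weights into a consensus graph, normalised,
and sharpened with a KL self-training term before spectral clustering.

## Model components and assumptions

**Self-expressive affinity.** The latent codes are assumed to lie near a
union of low-dimensional subspaces, one per subtype, so each sample's code
is a linear combination of codes from its own subspace: `Z ≈ C Z`. The
diagonal of `C` is constrained to zero throughout (masked in every forward
pass), because `C = I` trivially minimises the fit term and carries no
grouping information. For downstream graph use, `C` is symmetrised as
`(|C| + |Cᵀ|)/2` — spectral methods need a symmetric nonnegative affinity —
while the raw `C` enters the losses.

**Motif similarity.** First-order similarity uses the Gaussian kernel
`s_ij = exp(−‖x_i−x_j‖²/2σ²)` on the view's data matrix. The bandwidth σ
defaults to the median pairwise Euclidean distance ("auto"), a scale-free
choice consistent with the median edge threshold. The threshold ε is the
median of the *off-diagonal upper-triangle* entries (the unit diagonal is
not an inter-sample similarity and would inflate a full-matrix median);
edges with `s_ij ≥ ε` are kept, ties included, so the binary graph has
density very close to 1/2. The motif matrix counts, per retained edge, the
triangles the two endpoints jointly close — computed as
`(W01 @ W01) * W01`, verified exactly against brute-force triple
enumeration — and is Hadamard-multiplied with the retained weights.
Because triangle counts are unbounded while `S` lives in (0,1], the motif
similarity is min-max rescaled to [0,1] before the convex blend
`A = ηS + (1−η)M`; this makes η a meaningful trade-off weight, and the
η = 1 / η = 0 endpoints coincide exactly with the pure first-order / pure
motif modes of the ablation harness.

**Tensor nuclear norm.** The TNN of the rotated stack (shape N×V×N; the
rotation (i,j,v)→(i,v,j) makes the omics mode a matrix dimension of the
frontal slices so the norm couples structure across omics) is defined in
the Fourier domain: FFT along the third mode, then the mean over
transformed slices of their matrix nuclear norms. With a single slice this
is exactly the matrix nuclear norm. The proximal map is slice-wise
singular-value soft-thresholding by τ: by Parseval for the unnormalised
DFT, `‖X−T‖_F² = (1/n3)Σ_t‖X̂_t−T̂_t‖_F²`, so the objective
`τ·TNN(X) + ½‖X−T‖_F²` separates over Fourier slices with the two 1/n3
factors cancelling; the prox-optimality property test (objective at the
prox ≤ objective at 100 random perturbations) pins this convention down.
Conjugate symmetry is enforced explicitly so the output is exactly real.

**Training-time realisation of ‖C′‖\_\*.** The nonsmooth TNN is handled by
an inexact proximal scheme: every `prox_every` epochs the symmetrised
`C^v` stack is passed through the t-SVT prox (threshold `tnn_weight`), and
a quadratic pull `½Σ_v‖C^v_sym − L^v‖_F²` toward the resulting low-rank
slices is added to the smooth objective until the next refresh. The raw
TNN value is logged each epoch as a diagnostic alongside the pull term.

**Attention and consensus.** The symmetrised graphs are concatenated
column-wise and linearly mapped by a trainable (N·V)×V matrix initialised
to all-ones, passed through LeakyReLU (negative slope 0.01, the common
default) and softmax-normalised *across views per sample*, so each sample's
V weights lie on the simplex; at the all-ones initialisation the weights
are exactly uniform. The fused graph row-scales each view's graph by its
sample's weight. The f1 normalisation `s_ij = (c_ij + c_ji)/(2 c_sum,i)`
(unit diagonal) yields unit off-diagonal row sums for symmetric input; the
self-training target is the standard sharpened distribution
`p_ij = (s_ij²/f_j)/Σ_{j'}(s_ij'²/f_j')` with `f_j` the column mass, and
the KL refinement `KL(P‖S)` is computed against the row-normalised
consensus with `P` held fixed between refreshes (every `target_refresh`
epochs), the usual self-training practice that avoids target chasing.

**Optimisation.** All parameters (per-view encoder/decoder weights, `C^v`,
attention matrix) are updated jointly by full-batch Adam — sample sizes in
the target application are a few hundred, so full-batch is natural.
Pretraining minimises only reconstruction + L2,1 per view at lr 1e-4;
joint training runs at lr 1e-3. Training is implemented in pure NumPy on a
compact reverse-mode autodiff core (`_autograd.py`); analytic gradients of
every loss term are tested against central finite differences at relative
error < 1e-4. `C^v` is warm-started at the view's target graph `A^v`
(zero diagonal): the alignment term anchors it there, and starting from a
small random matrix would waste most of the epoch budget traversing the
distance at first-order step sizes. All views share one initialisation
sub-seed, which keeps the objective exactly view-exchange symmetric:
identical views evolve identically and their attention weights remain
uniform, as the symmetry of the objective demands.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `hidden_dims` | (1024, 512) | encoder hidden/latent widths; desk-scale runs and tests use (64, 32) |
| `pretrain_lr`, `train_lr` | 1e-4, 1e-3 | Adam step sizes for the two phases |
| `alpha` | 0.01 | L2,1 feature-selection strength |
| `lambda1`, `lambda2` | 1.0, 0.1 | self-expression fit / Frobenius shrinkage of C |
| `lambda3` | 1.0 | pull of C toward the hybrid high-order graph |
| `eta` | 0.5 | first-order vs motif blend in A |
| `beta` | 0.1 | KL self-training weight |
| `tnn_weight` | 0.1 | t-SVT threshold τ realising the tensor nuclear norm |
| `prox_every`, `target_refresh` | 10, 10 | epochs between prox / target refreshes |
| `sigma` | "auto" | Gaussian-kernel bandwidth (median pairwise distance) |
| `n_clusters` | None | fixed k, or eigengap selection in [`k_min`,`k_max`] = [2,6] |

The loss weights are exposed rather than fixed: no single combination is
canonical, and a grid search on the target cohort is the intended usage.
The defaults above were chosen once as a balanced operating point for the
synthetic benchmark scale and are not re-tuned per dataset.

## Preprocessing

Expression views: features with any missing value or with a zero fraction
strictly above 30% are dropped (a feature exactly at 30% is kept); then
log2(x+1) — the pseudocount keeps the transform defined at the zeros the
30% rule retains — then zero-variance removal. Methylation views: optional
probe-to-gene averaging (arithmetic mean of duplicate probes), zero-variance
removal; array-level QC/normalisation is assumed done upstream. Sample
alignment keeps the intersection of sample IDs across views (lexicographic
order, deterministic), excluding samples without survival records when a
survival table is present. Missing clinical values are dropped per test,
never imputed.

## Evaluation statistics

Survival separation uses the multi-group log-rank test (lifelines), df =
k−1, reported as −log10 p; a tie-aware risk-set enumeration oracle in the
test suite pins the implementation to 1e-6. Clinical enrichment applies
chi-square (no continuity correction; expected counts below 5 raise a
warning, not a switch to exact tests) to categorical columns and
tie-corrected Kruskal–Wallis to numeric columns, with BH step-up across
the columns actually tested and significance at adjusted p < 0.05;
single-level columns are skipped and excluded from the family. Synthetic
validation uses the adjusted Rand index.

## Synthetic data: what it emulates, what it does not

The generator plants k clusters over n samples and V Gaussian views: a
fraction of features per view ("informative") carries cluster-specific
means whose per-feature RMS pairwise difference equals
`separation × noise_sd`; the rest are pure noise. Survival times are
exponential with per-cluster hazards and independent exponential censoring
(`censor_rate` sets the expected censored fraction); the clinical table
contains one cluster-tilted categorical column and a cluster-shifted age
(positive controls) plus one independent categorical column (negative
control for FDR calibration). Everything derives from one seed.

It does **not** emulate realistic omics marginals (counts,
methylation-beta bimodality), feature correlation structure, batch
effects, or — importantly — *non-metric* edge noise in the similarity
graphs. Because Gaussian-kernel similarity is a monotone function of
Euclidean distance, strong spurious similarities between otherwise-distant
samples cannot arise, and triads close automatically; this is exactly the
noise mode triangle-motif filtering is designed to remove. Passing the
recovery benchmark therefore demonstrates the pipeline's correctness and
end-to-end signal flow, not the real-data margin of motif over first-order
similarity.

## Benchmark problem sizes

The recovery benchmark uses n=150, k=3, V=3, view dims (200, 150, 100),
separation 3, informative fraction 0.3, hazards (1.0, 0.5, 0.25), encoder
dims (64, 32), 30 pretraining + 80 joint epochs, seeds 1–5 — a scale at
which one fit takes a couple of seconds. The ablation benchmark uses
n=120, separation 1.5 (the boundary where the first-order baseline begins
to fail; at much harsher noise all three strategies degrade together and
their ordering is dominated by run-to-run variance, while far above it all
three are perfect and indistinguishable). On this generator the observed
ordering is hybrid ≥ motif ≥ first-order largely through ties at ARI 1
plus occasional strict motif/hybrid wins; the motif-only graph can lose to
first-order under heavy noise because triangle weighting fragments
within-cluster connectivity — a known behaviour on metric-kernel graphs,
and the reason the hybrid blend (not the pure motif graph) is the default.

## Numerical choices and degenerate inputs

- Median threshold ties are retained (`≥`); an all-equal similarity matrix
  yields the complete graph.
- Coincident samples (zero median pairwise distance) fall back to unit
  bandwidth, giving an all-ones similarity.
- f1 normalisation raises on an all-zero off-diagonal row, naming the
  sample; during training a 1e-12 guard on row sums keeps the
  differentiable path finite (the warm-started `C` makes this guard inert
  in practice).
- KL uses the 0·log 0 := 0 convention; a support violation (p > 0 where
  s = 0) raises.
- L2,1 subgradient at an all-zero row is taken as 0 (via a 1e-300 floor
  inside the square root, which leaves all finite-weight gradients
  untouched).
- Spectral clustering symmetrises and clips its input, uses the symmetric
  normalised Laplacian, row-normalised k smallest eigenvectors and k-means
  with 20 restarts at a fixed seed; labels are canonicalised by first
  appearance, so identical fits give bit-identical label vectors.
- Disconnected graphs with more components than k produce a warning;
  k ≥ N is an error.

## Known limitations

- The training objective is nonconvex; different seeds can reach different
  local optima (the trace records every term so divergence is visible).
- The TNN enters via an inexact prox-pull scheme rather than a full
  ADMM/auxiliary-variable solver; with small `tnn_weight` the pull is mild
  regularisation, not exact constraint satisfaction.
- Hidden dims (1024, 512) at real-cohort scale imply large dense matrices
  in pure NumPy; fits at that scale are minutes, not seconds, per cohort.
- The attention weights of equally informative views can drift from
  uniform on finite data (softmax over learned logits is scale-sensitive);
  exact uniformity is guaranteed only under exact view-exchange symmetry.
- Whether the decoder consumes `Z` or `C Z` during joint training is a
  genuine design fork in the self-expressive autoencoder literature; this
  implementation uses `C Z` for joint training and `Z` for pretraining.
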