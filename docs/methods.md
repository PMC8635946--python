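# Methods

## Problem setting

A DTI dataset is the triplet `(S_d, S_t, Y)`: chemical similarity over `n`
drugs, sequence similarity over `m` targets, and a sparse binary interaction
matrix. Verified interactions are rare (the nuclear-receptor gold standard,
whose 54×26/90-positive shape the synthetic `nr_like` generator mirrors, has
90 positives against 1314 unknown pairs), and an absent entry means
*unverified*, not *absent*. The package therefore treats the problem as
positive–unlabeled: it screens unlabeled pairs for likely positives, revises
the training matrix, and only then fits the final predictor.

## Pipeline stages and their assumptions

**Similarity screening.** Assumes chemically similar drugs tend to share
targets. Propagation is single-step from the original matrix — a drug chain
a~b~c never reaches c unless a and c themselves clear the threshold — so the
revision cannot cascade. Known positives are never removed (`Y₁ ≥ Y`
elementwise, asserted as an invariant).

**Heterogeneous restart walk.** The transition matrix couples the two
similarity layers through interaction edges. A node with at least one
interaction sends mass `λ` across layers and `1−λ` within its own layer
(each block row-normalized); a node with no interactions stays within its
layer; any all-zero row (impossible under the validation rules, defensively
handled anyway) receives a self-loop so the matrix stays row-stochastic and
`Σp = 1` holds at every iteration. One walk per drug seed; the seed places
`η` on the drug node and `1−η` spread over its known targets (uniform for a
new drug). The iteration stops when the gap drops below `10⁻¹⁰`; with the
default restart probability this takes ~15–20 iterations, and the iterative
fixed point matches the dense closed form `c(I−(1−c)Wᵀ)⁻¹p₀` to ≤1e−8.

**WNN-GIP.** GIP kernels are undefined for all-zero profile matrices (the
bandwidth normalizer vanishes), so new drugs are first given
weighted-nearest-neighbor profiles with rank-based geometric decay
(`w = T^(rank−1)`; a raw-similarity weighting is config-selectable). The
Kronecker RLS prediction is computed spectrally; negative kernel eigenvalues
(possible for measured chemical similarities) are clipped to zero with a
logged warning. Elementwise the prediction is **not** monotone in `σ` —
eigenvector mixing can grow individual cells — but the Frobenius norm
shrinks monotonically, which is what the suite asserts.

**Fusion.** The three sources live on incompatible scales (binary,
sub-probability, RLS score), so each matrix is min–max normalized to [0,1]
before combination; a constant matrix maps to zeros by convention. Weights
are estimated by inner cross-validation: training positives are split into
`inner_folds` groups, each group is masked in turn, every source rescores
the masked dataset, and the masked positives are ranked against all
unlabeled pairs; `αᵢ ∝` mean AUPR. If every AUPR is zero the weights fall
back to equal with a warning. AVE (equal weights) and VOTE (per-source
binarization at a top fraction, then per-cell majority) are baselines, not
defaults.

**Revision and BLM-NII.** The top `ceil(f·n_unlabeled)` pairs by fused score
become positives (ties broken by score, then row, then column — fully
deterministic; the added sets nest as `f` grows). BLM-NII trains a per-drug
local RLS model over targets and a per-target model over drugs with the
combined kernels, substitutes NII profiles (similarity-weighted means of
training profiles, scaled by β) for entities with empty label vectors, and
combines the two sides by max (mean is config-selectable). By default it
consumes the *binarized* revised matrix; a continuous path (fused scores
with known positives clamped to 1) is available behind a flag.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_d`, `alpha_t` | 0.5 | weight of measured similarity vs GIP kernel |
| `gamma_scale` | 1.0 | GIP bandwidth multiplier (γ = scale / mean ‖yᵢ‖²) |
| `sigma`, `blm_sigma` | 1.0 | RLS regularization (global / local models) |
| `wnn_decay` | 0.7 | geometric decay T of WNN rank weights |
| `restart_c` | 0.7 | restart probability of the walk |
| `eta` | 0.5 | seed mass on the drug node vs its target profile |
| `jump_lambda` | 0.5 | cross-layer transition mass |
| `rwr_tol` | 1e−10 | walk stopping threshold |
| `theta_sim` | 0.7 | screening similarity threshold |
| `inner_folds` | 3 | inner CV folds for performance weights |
| `select_fraction` | 0.01 | fraction of unlabeled pairs promoted |
| `top_fraction` | 0.01 | thresholding fraction for confusion metrics |
| `nii_beta` | 1.0 | weight of inferred NII profiles |
| `n_folds` | 10 | outer CV folds |

Values without a field-standard convention (`alpha_*`, `sigma`, `theta_sim`,
`wnn_decay`, `jump_lambda`, `restart_c`, `eta`) are deliberate midpoints or
the values conventional in the GIP/WNN/heterogeneous-walk literature; all
are exposed in `RunConfig` and on the CLI.

## Evaluation protocol

Pair-wise k-fold cross-validation, stratified by label; drug-wise and
target-wise splits exist for new-entity scenarios. *All* held-out pairs are
masked to 0 in the training matrix, so a held-out pair's own label cannot
reach its score by construction — the suite verifies exact score equality
under label flips. Fold metrics: ROC AUC (Mann–Whitney with ties at ½),
step-wise PR AUC, and the four confusion percentages after calling the top
1% of ranked test pairs positive (`ceil`, deterministic tie-break).
Aggregates are fold means. Single-class folds are skipped with a warning.

## Synthetic data

The generator draws drug/target latent vectors (standard normal, dimension
8 by default), forms Gaussian-kernel similarities with bandwidth equal to
the median pairwise latent distance (scale-free), plants the top `density`
fraction of noisy latent inner products as true interactions, and hides a
uniform random `hide_fraction` of them. Shared latent factors make similar
drugs share targets, which is precisely the regularity screening, the walk,
and WNN-GIP exploit — so hidden positives are recoverable in principle, and
hidden and observed positives are exchangeable by construction.

The standard benchmark (60×30, density 0.05, 20% hidden, noise 0.1, seeds
1–10) is sized so the full pipeline, its ablations, and ten-fold CV all run
in seconds; it emulates the sparsity regime of the real gold standards, not
their scale. What it does **not** emulate: the heavy-tailed similarity
distributions of real chemical fingerprints, indefinite (non-PSD) measured
similarities, block structure from drug families, or identifier semantics.
Passing the recovery benchmark shows the machinery is sound and the fusion
beneficial under the model's own assumptions; it is not evidence about any
particular real dataset.

## Numerical choices

- Symmetric linear solves everywhere; no explicit inverses. The Kronecker
  RLS fast path agrees with the dense `(nm)×(nm)` oracle to ~1e−14.
- Similarity asymmetry ≤1e−8 is symmetrized with a warning; more is an
  error. Kernel eigenvalues below zero are clipped with a warning.
- All ranking cutoffs (`vote`, revision, thresholded metrics) use `ceil`
  and break ties by (score desc, row, column), so every output is
  bit-reproducible for a given seed; nothing is parallel or order-unstable.
- File output uses `%.17g`, making write→read round trips bit-exact.

## Known limitations

- The raw walk scores are comparable *within* a drug row but their scale
  varies across rows (sparse-profile drugs spread mass more evenly); a
  global ranking of the raw `Y₂` can even be worse than chance on the
  benchmark. The pipeline mitigates this by running the walk on the
  screening-revised matrix and fusing normalized scores; per-row
  recalibration would be a natural extension.
- Performance weights are inner-CV estimates from few positives; on
  benchmarks where all three sources are comparably strong they hover near
  uniform, and weighted fusion's edge over plain averaging at the fused
  output does not always survive the discrete top-1% revision step.
- VOTE binarizes at a fixed top fraction per source; with a binary `Y₁` the
  tie-break inside the screened positives is lexicographic, which is
  deterministic but arbitrary.
- Screening is drug-side only by default, mirroring the method's design; a
  target-side screen is a flag-enabled experiment (`wnn_targets` likewise
  extends WNN to new targets).
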