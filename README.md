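# dtifuse

Drug–target interaction (DTI) prediction by **weighted fusion of multisource
information**. Most DTI datasets list only verified interactions; every other
drug–target pair is *unlabeled*, not negative. `dtifuse` screens the unlabeled
pairs with three independent scorers, fuses their revised interaction matrices
with performance-based weights, promotes the top-scoring pairs to putative
positives, and hands the revised training matrix to a bipartite-local-model
predictor with neighbor-based interaction-profile inferring (BLM-NII).

The package is aimed at computational chemists and network-biology researchers
working with Yamanishi-style gold-standard data: a drug–drug chemical
similarity matrix `S_d`, a target–target sequence similarity matrix `S_t`, and
a sparse binary interaction matrix `Y` (drugs × targets).

## Method

1. **Similarity screening (Y₁).** For drug pairs with `S_d(a,b) ≥ θ`, each
   drug inherits the other's known targets as putative positives (single-step,
   no transitive closure).
2. **Random walk with restart (Y₂).** On the heterogeneous network with block
   transition matrix `W = [[W_TT, W_TD], [W_DT, W_DD]]`, iterate
   `p_{t+1} = (1−c) Wᵀ p_t + c p₀` until `‖p_{t+1} − p_t‖ ≤ 10⁻¹⁰`, one walk
   per drug seed `p₀ = [(1−η)u₀; η v₀]`; the target block of `p_∞` scores the
   drug against every target.
3. **WNN-GIP (Y₃).** Gaussian interaction-profile kernels
   `K(i,j) = exp(−γ‖y_i − y_j‖²)` are blended with the measured similarities,
   `K_d = α_d K_chemical + (1−α_d) K_GIP,d` (likewise `K_t`), after new drugs
   receive weighted-nearest-neighbor profiles `y_WNN = Σᵢ T^(rankᵢ−1) yᵢ`;
   prediction is regularized least squares over the Kronecker pair kernel,
   `ŷ = K(K+σI)⁻¹y`, via the per-side eigendecomposition fast path.
4. **Weighted fusion.** `Y_final = Σᵢ αᵢ · normalize(Yᵢ)` with `Σαᵢ = 1`;
   each `αᵢ` is proportional to the source's inner-cross-validation AUPR.
   Equal-weight averaging (AVE) and per-cell majority voting (VOTE) are
   provided as baselines.
5. **Revision + BLM-NII.** The top 1% of unlabeled pairs by `Y_final` become
   positives in the revised training matrix; BLM-NII scores every pair as the
   max of a drug-side and a target-side local RLS model, with NII profiles
   substituted for entities that have no known interactions.

Evaluation follows the standard protocol: pair-wise 10-fold cross-validation
with held-out pairs masked to 0 during training, AUC and AUPR, and
accuracy/sensitivity/specificity/precision after thresholding the ranked
predictions at the top 1%.

Because the curated gold-standard datasets are distributed under license, the
package ships a seeded latent-factor generator that plants recoverable
structure (similar drugs share targets) and hides a known fraction of true
positives — the standard benchmark used throughout the tests is
60 drugs × 30 targets, 5% density, 20% of positives hidden, seeds 1–10.

## Worked example

```sh
python examples/02_fusion_pipeline.py
```

```text
screening added 40 putative positives
fusion weights (sim, rs, ws): [0.155 0.485 0.359]
revision promoted 18 unlabeled pairs
sim       hidden-positive AUC 0.573  AUPR 0.021
rs        hidden-positive AUC 0.657  AUPR 0.023
ws        hidden-positive AUC 0.835  AUPR 0.040
fused     hidden-positive AUC 0.822  AUPR 0.040
pipeline  hidden-positive AUC 0.849  AUPR 0.066
```

On the seed-1 benchmark the screen proposes 40 putative positives, the
inner-CV weights favor the stronger sources, and the full chain ranks a
hidden true interaction above a random non-interaction ~85% of the time
(AUC 0.849) — better than any raw source matrix alone. AUPR is small in
absolute terms because only 18 of the 1728 evaluated pairs are true.

The same flow is available from the shell:

```sh
dtifuse simulate --seed 1 --out-dir data/
dtifuse predict  --interactions data/interactions.tsv \
                 --drug-sim data/drug_similarity.tsv \
                 --target-sim data/target_similarity.tsv \
                 --seed 1 --out-dir out/
dtifuse crossval --interactions data/interactions.tsv \
                 --drug-sim data/drug_similarity.tsv \
                 --target-sim data/target_similarity.tsv \
                 --method fused --folds 10 --seed 1 --out-dir cv/
```

`predict` writes every intermediate (`Y1_screen`, `Y2_rwr`, `Y3_wnn_gip`,
`Y_final`, `Y_revised`, `scores`) plus audit lists of the added pairs and the
resolved configuration; `crossval` writes a JSON report with per-fold
metrics. `--method {sim,rs,ws,fused}` switches between single-source
revision and the weighted fusion.

## Layout

- `src/dtifuse/` — library: `data` (containers + labeled TSV I/O),
  `kernels`, `wnn_gip`, `rwr`, `fusion`, `blm`, `pipeline`, `evaluation`,
  `synthetic`, `config`, `cli`.
- `examples/` — short narrative scripts, one per capability.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
- `tests/` — pytest suite with independent brute-force oracles.
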