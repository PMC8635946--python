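"""Run the full weighted-fusion pipeline and score hidden-positive recovery.

The chain: similarity screening (Y1) -> restart walk (Y2) and WNN-GIP (Y3)
on the screened matrix -> inner-CV performance weights -> fused Y_final ->
top-1% revision of the training matrix -> BLM-NII scores.
"""

import numpy as np

from dtifuse import RunConfig, auc_score, aupr_score, predict_pipeline
from dtifuse.synthetic import benchmark_spec, generate, recovery_labels

dataset, truth = generate(benchmark_spec(seed=1))
result = predict_pipeline(dataset, RunConfig(seed=1))

print(f"screening added {len(result.screen_added)} putative positives")
print("fusion weights (sim, rs, ws):", np.round(result.weights, 3))
print(f"revision promoted {len(result.revision_added)} unlabeled pairs")

mask, labels = recovery_labels(dataset, truth)
flat = mask.ravel()
for name, matrix in [*result.sources.items(),
                     ("fused", result.y_final),
                     ("pipeline", result.scores)]:
    v = matrix.values.astype(float).ravel()[flat]
    print(f"{name:9s} hidden-positive AUC {auc_score(v, labels):.3f}  "
          f"AUPR {aupr_score(v, labels):.3f}")
# AUC ~0.85 for the pipeline means a hidden interaction outranks a random
# non-interaction about 85% of the time; AUPR is low in absolute terms
# because only 18 of 1728 evaluated pairs are real.
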