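"""Generate a synthetic drug-target dataset with planted hidden positives.

The generator draws drug and target latent factors, builds Gaussian-kernel
similarity matrices from them, plants the top 5% of noisy latent affinities
as true interactions, and hides 20% of those positives — the recovery
targets every later stage is judged against.
"""

from dtifuse import dataset_stats, write_dataset
from dtifuse.synthetic import benchmark_spec, generate

dataset, truth = generate(benchmark_spec(seed=1))
stats = dataset_stats(dataset)

print(f"drugs x targets : {stats.n_drugs} x {stats.m_targets}")
print(f"true interactions: {truth.true_Y.sum()}")
print(f"observed (training) positives: {stats.n_interactions}")
print(f"hidden positives to recover  : {len(truth.hidden_pairs)}")
print(f"unlabeled pairs : {stats.n_unknown}")

paths = write_dataset(dataset, "scratch/example_dataset")
print("wrote:", *paths.values(), sep="\n  ")
# The observed matrix omits the hidden positives; they stay unlabeled, which
# is exactly the positive-unlabeled setting the fusion pipeline targets.
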