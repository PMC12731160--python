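"""Simulate a small multi-omics cohort and classify it end to end.

Generates 120 patients with two omics layers and planted class structure,
trains the graph model on a stratified 70% split, and prints test accuracy
and F1 scores.  High values mean the planted class signal was recovered
through the full graph-encode / gate / fuse pipeline.
"""

import numpy as np

from omicsfuse import (SimulationConfig, TrainConfig, compute_metrics, fit,
                       make_splits, predict_proba, simulate_multiomics)

dataset, truth = simulate_multiomics(SimulationConfig(
    n_samples=120, n_classes=2, n_features=(60, 40), n_informative=(8, 8),
    effect_size=2.0, shared_factor_dim=3, class_proportions=(0.5, 0.5),
    omics_names=("mrna", "mirna"), seed=0,
))
plan = make_splits(dataset.labels, test_fraction=0.3, n_repeats=1, seed=0)
train_idx, test_idx = plan.splits[0]

cfg = TrainConfig(hidden_dims=(32, 32, 16), epochs_pretrain=100,
                  epochs_main=150, lr=5e-3, k=4, seed=0)
model = fit(dataset, train_idx, cfg)
probs = predict_proba(model, dataset, test_idx)
metrics = compute_metrics(dataset.labels.y[test_idx], probs, binary=True)

print(f"test samples: {len(test_idx)}")
for name, value in metrics.items():
    print(f"{name}: {value:.3f}")
print("A value near 1.0 means the transductive classifier recovered the "
      "planted subtype structure on held-out patients.")
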