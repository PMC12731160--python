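"""Module ablations and omics-combination comparison on a small cohort.

Evaluates the full model against variants with the graph encoder replaced
by a linear layer, the gate removed, or the attention fusion replaced by
plain concatenation, and compares two-omics subsets against using all
omics.  Each row is a mean over repeated stratified splits.
"""

from omicsfuse import (SimulationConfig, TrainConfig, run_ablations,
                       run_omics_combinations, simulate_multiomics)

dataset, _ = simulate_multiomics(SimulationConfig(
    n_samples=150, n_classes=2, n_features=(40, 40, 30),
    n_informative=(6, 6, 6), effect_size=1.5, shared_factor_dim=3,
    factor_loading_sd=0.8, class_proportions=(0.5, 0.5), seed=3,
))
cfg = TrainConfig(hidden_dims=(16, 16, 8), epochs_pretrain=50, epochs_main=80,
                  lr=5e-3, k=3, dropout=0.2, ola_slots=8, ola_heads=2, seed=0)

abl = run_ablations(dataset, cfg, n_repeats=3, seed=0)
print("== ablations (mean ACC over 3 splits) ==")
print(abl[abl.metric == "acc"][["variant", "mean", "std"]].to_string(index=False))

combos = run_omics_combinations(dataset, cfg, n_repeats=3, seed=0)
acc = combos[combos.metric == "acc"].groupby("combination")["value"].mean()
print("\n== omics combinations (mean ACC) ==")
print(acc.to_string())
print("\nOn a cohort this small the module comparisons carry visible "
      "split-to-split noise; the stable pattern (run at the 300-sample "
      "fixture scale, e.g. scripts/acceptance.py) is that replacing the "
      "graph encoder costs the most, and that omics subsets missing an "
      "informative layer trail the full combination.")
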