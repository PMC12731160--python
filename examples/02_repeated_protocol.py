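"""Repeated stratified evaluation with mean +/- std reporting.

Runs the 5-repeat 70/30 protocol on the standard synthetic fixture and
prints the per-metric summary, plus the mean learned confidence on
correctly and incorrectly classified test samples (per-omics classifiers).
The confidence gap shows the true-class-probability head flagging
unreliable per-omics predictions.
"""

import numpy as np

from omicsfuse import TrainConfig, default_fixture, evaluate_protocol

dataset, truth = default_fixture(seed=1)
cfg = TrainConfig(hidden_dims=(64, 64, 32), epochs_pretrain=150,
                  epochs_main=200, lr=5e-3, k=5, seed=0)
res = evaluate_protocol(dataset, cfg, n_repeats=5, seed=0)

print("metric        mean    std")
for metric, (mean, std) in res["report"].summary().items():
    print(f"{metric:12s}  {mean:.3f}  {std:.3f}")

cc = [d["conf_correct"] for d in res["details"] if not np.isnan(d["conf_correct"])]
cw = [d["conf_wrong"] for d in res["details"] if not np.isnan(d["conf_wrong"])]
if cw:
    print(f"mean confidence, correct: {np.mean(cc):.3f}; "
          f"misclassified: {np.mean(cw):.3f}")
    print("Lower confidence on misclassified samples is the intended "
          "behavior of the TCP confidence head.")
else:
    print(f"mean confidence, correct: {np.mean(cc):.3f} "
          "(no misclassified samples in these repeats)")
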