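# Methods

## Model

`omicsfuse` performs supervised integration of M omics layers measured on
the same N samples (patients), for transductive classification into Q
classes and masking-based biomarker ranking.

**Patient-similarity graphs.** For each omics layer m with feature matrix
X^m (N x d_m), pairwise cosine similarity is computed between samples and
each sample keeps edges to its k most similar other samples (rank-based
top-k; ties broken toward the lower sample index). The binary adjacency S^m
is symmetrized by elementwise maximum with its transpose, so an edge
survives if either endpoint selected it. Self-loops are not stored; they
enter only through the S^m + I term of the convolution. k is the main
structural hyperparameter (sensible range 2-10): smaller k gives sparser,
more local graphs, larger k denser, noisier ones.

**Hybrid graph encoder.** Each omics layer is encoded by a three-layer
GCN-GAT-GCN stack:

    Z1 = ReLU(D^-1/2 (S+I) D^-1/2 X W1)          (graph convolution)
    Z2 = GAT(S, Z1)                               (single-head attention)
    Z  = ReLU(D^-1/2 (S+I) D^-1/2 Z2 W3)

with D the degree matrix of S + I. The attention layer computes
coefficients theta_ij = softmax_j(LeakyReLU(a^T [W x_i || W x_j])) over
each node's neighborhood (self included by default; LeakyReLU slope 0.2)
and aggregates ReLU(sum_j theta_ij W x_j). Each layer has its own weight
matrix — the only reading that type-checks across different widths.
Alternative layer orders (GAT-GAT-GCN etc.) are built from the same two
primitives for architecture comparisons, and a single linear layer replaces
the stack in the "no graph structure learning" ablation.

**Gating and TCP confidence.** The embedding Z of each omics layer is
refined twice and the refinements multiplied elementwise:

    Z_gate = sigmoid(l(Z)) ⊙ Z        (per-coordinate soft feature gate)
    Z_tcp  = sigmoid(t(Z)) ⊙ Z        (per-sample confidence scaling)
    Z~     = Z_gate ⊙ Z_tcp

The confidence head t is trained to regress the true-class probability
(TCP) of a per-omics linear classifier c: rho = softmax(c(Z)), target
rho[n, y_n]. A sample that this omics layer tends to misclassify gets a
low confidence and is down-weighted before fusion. The outer map of the
gate is the identity (the sigmoid multiply is the gate), and the confidence
head output is squashed through a sigmoid so it lives on the probability
scale of its target. The learned score — not the label-dependent oracle
TCP — is used everywhere, since labels are unavailable at test time.

**Omics-Linked Attention (OLA) fusion.** The refined embeddings are
concatenated (width d_c) and fused by external-memory attention: per head
e, the feature block z_e (width d_c/H) is scored against a learnable key
memory U_key (d_c/H x S slots), the N x S score matrix is normalized twice
(softmax down each column over samples, then L1 across each row over
slots), and the output is reconstructed from a value memory U_val. Head
outputs are concatenated and mapped through an output transform U_t; a
fully connected head produces the class logits. The attention map has
N x S entries, so cost grows linearly in the number of samples, unlike
N x N self-attention. Defaults: H = 4 heads, S = 64 slots, separate
key/value memories per head, no residual or layer norm (available as
flags). Alternative fusions for comparison: plain concatenation, standard
self-attention over samples, and a view-correlation network over per-omics
class distributions.

**Losses and two-stage training.** Stage 1 pretrains each encoder with a
linear classifier on its embedding against the class-weighted
cross-entropy L_GS summed over omics and samples (weights
w_q = N/(Q n_q); a no-op on balanced data). Stage 2 freezes the encoders
and jointly optimizes the gate, confidence, per-omics classifier, and
fusion parameters against

    L_total = L_GS + lambda1 (L_ce + L_mse) + lambda2 L_OLA

where L_ce is the cross-entropy of the per-omics distributions rho, L_mse
the squared error between the learned confidence and the (detached) TCP
target, and L_OLA the cross-entropy of the fused prediction. With frozen
encoders L_GS is constant, so stage 2 effectively minimizes
lambda1 L_GC + lambda2 L_OLA; the frozen embeddings are computed once and
reused every stage-2 epoch (mathematically identical, much faster). All
losses use sum reduction over samples and omics as written; a mean
reduction flag exists for large N. Optimizer: Adam, lr 1e-3 default, no
weight decay by default (a decoupled weight-decay option exists);
lambda1 = lambda2 = 1 by default with a grid-search utility over
{0.01, 0.1, 1, 10, 100}. Dropout (default 0.5) is applied to each encoder
layer's input during training only.

**Transductive prediction.** Test samples join the similarity graphs as
unlabeled nodes: graphs are rebuilt over train + eval samples (eval-eval
edges allowed by default; a flag restricts eval nodes to training
neighbors) and a gradient-free forward pass yields class probabilities.
Training itself uses graphs over the training samples only.

**Masking importance.** With a trained model fixed, the baseline macro-F1
is computed on the unmasked test set; then each feature column is zeroed
across the test rows (the similarity graph stays fixed; a rebuild flag
exists), the test set is re-classified, and importance = baseline minus
masked macro-F1. Features with positive importance are reported as
candidate biomarkers. Because a single flipped test sample changes
macro-F1 by a fixed quantum, single-model tables are noisy; the package's
canonical ranking therefore averages the tables of the repeated-split
protocol's models (`aggregate_importance`).

## Evaluation protocol

30% of samples are held out as a stratified test set; training uses the
remaining 70%; the whole procedure is repeated over five independent
random splits and metrics are reported as mean +/- standard deviation.
Metrics: accuracy, weighted F1 and macro F1 for multi-class tasks;
accuracy, F1 and ROC AUC (trapezoidal rank statistic, half credit for
ties) for binary tasks. Each repeat derives its own training seed from the
protocol seed, so repeats are independent but the protocol is exactly
reproducible.

## Synthetic data generator

The generator emulates preprocessed tumor multi-omics panels at desk
scale. The standard fixture: N = 300 samples, Q = 3 classes with
proportions (0.5, 0.3, 0.2), three layers ("mrna", "meth", "mirna") with
(200, 200, 100) features, 20 informative features each.

* **Class signal**: each informative feature receives class-level means
  spaced `effect_size * noise_sd` apart (default 1.5), using a random
  per-feature permutation of centered class scores; any two classes
  therefore differ by at least one effect size on every informative
  feature, while shift directions vary across features.
* **Cross-omics structure**: 5 latent factors shared by all layers load
  onto the informative features with loading sd
  `factor_loading_sd * noise_sd` (default 1.5). The factor variance per
  informative feature (~11x the white noise) is deliberately calibrated so
  that structured nuisance variation — latent programs, batch effects —
  dominates any single gene's class signal, as in real panels. At this
  calibration the fixture operates at the accuracy regime of real tumor
  classification tasks (fused accuracy ~0.95, single-layer ~0.9) instead
  of a saturated regime where every variant scores 1.0 and attribution and
  confidence comparisons degenerate.
* **Noise**: i.i.d. Gaussian by default; Student-t and zero-inflation
  variants are flags.

What the fixture does not emulate: methylation beta-value boundedness,
count-based miRNA distributions, feature-feature correlation beyond the
low-rank factors, missing values. Passing tests on this fixture show the
pipeline recovers planted structure under Gaussian assumptions; they do
not certify performance on real data.

## Problem sizes and numerical choices

The test suite and the reproduction script run the fixture protocol with
hidden widths (64, 64, 32), 150 pretraining and 200 main epochs at lr
5e-3 — the package's scaling of the larger defaults (400, 400, 200;
500/1000 epochs) to the 300-sample fixture, where wider networks only add
runtime. Observed fixture results: mean test accuracy 0.967 (5 splits,
data seed 1), ablations strictly lower (linear encoder 0.871, no gate
0.956, concatenation fusion 0.956), learned confidence 0.907 on correct vs
0.835 on misclassified per-omics predictions.

Numerical details: float64 throughout; softmax and masked attention use
max-shifted exponentials with -inf additive masking of non-neighbors;
cosine similarity raises an error on zero-norm samples; KNN ties break
toward lower sample index; argmax prediction ties break toward the lower
class index (numpy convention). Training raises a divergence error naming
the epoch if a loss becomes non-finite. Fixed seeds make simulation,
training, and evaluation bitwise reproducible on one platform.

## Known limitations

* The similarity graph is static; it is never refined during training.
* Masking importance on strongly redundant signal is conservative: when
  many informative features back the same decision and test margins are
  large, zeroing one feature rarely flips a prediction, so true features
  can score zero importance. The averaged ranking mitigates but does not
  remove this; see the biomarker example for a regime where attribution is
  sharp.
* Single attention head in the encoder's GAT layer; binary (unweighted)
  adjacency only.
* Sum-reduced losses make effective step sizes grow with N; use the mean
  reduction flag for cohorts much larger than the fixture.
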