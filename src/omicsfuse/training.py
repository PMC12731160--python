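"""Losses and the two-stage optimization of the full model.

Stage 1 pretrains each omics-specific graph encoder with a linear classifier
on its embedding, minimizing the (class-weighted) graph-structure loss
L_GS summed over omics and samples.  Stage 2 freezes the encoders and
jointly trains the gating/confidence heads and the attention fusion against

    L_total = L_GS + lambda1 * L_GC + lambda2 * L_OLA

where L_GC = L_ce + L_mse combines the per-omics classifier cross-entropy
with the squared error between the learned confidence and the true-class
probability, and L_OLA is the cross-entropy of the fused prediction.  With
the encoders frozen, L_GS is a constant in stage 2, so the optimized
quantity is effectively lambda1 * L_GC + lambda2 * L_OLA.

Prediction is transductive: test samples join the similarity graphs as
unlabeled nodes, and a gradient-free forward pass yields their class
probabilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .data_io import MultiOmicsDataset
from .encoders import OmicsEncoder
from .exceptions import ConfigError, TrainingDivergenceError
from .fusion import FUSIONS
from .gating import GateParams, refine_omics, tcp_targets
from .graphs import SimilarityGraph, build_graph


@dataclass
class TrainConfig:
    """All tunable knobs of one training run (CPU-only contract)."""

    k: int = 5
    lambda1: float = 1.0
    lambda2: float = 1.0
    lr: float = 1e-3
    weight_decay: float = 0.0
    epochs_pretrain: int = 500
    epochs_main: int = 1000
    hidden_dims: tuple[int, ...] = (400, 400, 200)
    ola_slots: int = 64
    ola_heads: int = 4
    ola_residual: bool = False
    seed: int = 0
    class_weighting: bool = True
    dropout: float = 0.5
    layer_order: str = "gcn-gat-gcn"
    fusion: str = "ola"
    gat_self_loop: bool = True
    standardize: bool = False
    reduction: str = "sum"   # "sum" (as the losses are written) or "mean"
    use_gate: bool = True
    test_links: bool = True  # allow test-test edges in the prediction graph

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ConfigError("lambda1 and lambda2 must be positive")
        if self.epochs_pretrain < 1 or self.epochs_main < 1:
            raise ConfigError("epoch counts must be >= 1")
        if self.reduction not in ("sum", "mean"):
            raise ConfigError(f"unknown reduction '{self.reduction}'")
        if self.fusion not in FUSIONS:
            raise ConfigError(f"unknown fusion '{self.fusion}'")
        self.hidden_dims = tuple(self.hidden_dims)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclass
class TrainedModel:
    """Fitted parameters plus everything needed to rerun prediction."""

    config: TrainConfig
    encoders: list[OmicsEncoder]
    gates: list[GateParams]
    fusion: object
    graphs: list[SimilarityGraph]
    train_idx: np.ndarray
    class_weights: np.ndarray
    loss_history: dict[str, list[dict[str, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def compute_class_weights(y: np.ndarray, n_classes: int,
                          enabled: bool = True) -> np.ndarray:
    """w_q = N / (Q * n_q); all-ones when disabled or perfectly balanced."""
    if not enabled:
        return np.ones(n_classes)
    counts = np.bincount(y, minlength=n_classes).astype(np.float64)
    if np.any(counts == 0):
        raise ConfigError("every class must appear in the training labels")
    return len(y) / (n_classes * counts)


def _log_softmax(logits: nn.Tensor) -> nn.Tensor:
    shift = nn.constant(logits.data.max(axis=1, keepdims=True))
    z = nn.add(logits, nn.mul(shift, nn.constant(-1.0)))
    lse = nn.log(nn.tensor_sum(nn.exp(z), axis=1, keepdims=True))
    return nn.add(z, nn.mul(lse, nn.constant(-1.0)))


def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.constant(np.asarray(x, dtype=np.float64))


def _reduce(total: nn.Tensor, n_terms: int, reduction: str) -> nn.Tensor:
    if reduction == "mean":
        return nn.mul(total, nn.constant(1.0 / n_terms))
    return total


def weighted_cross_entropy(logits: nn.Tensor, y: np.ndarray,
                           class_weights: np.ndarray,
                           reduction: str = "sum") -> nn.Tensor:
    """-sum_n w_{y_n} log softmax(logits)[n, y_n]."""
    n, q = logits.shape
    onehot = np.zeros((n, q))
    onehot[np.arange(n), y] = class_weights[y]
    lp = _log_softmax(logits)
    loss = nn.mul(nn.tensor_sum(nn.mul(lp, nn.constant(onehot))), nn.constant(-1.0))
    return _reduce(loss, n, reduction)


def graph_structure_loss(per_omics_logits: list, y: np.ndarray,
                         class_weights: np.ndarray,
                         reduction: str = "sum") -> nn.Tensor:
    """L_GS: class-weighted cross-entropy summed over omics and samples."""
    y = np.asarray(y, dtype=np.int64)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    total = None
    for logits in per_omics_logits:
        term = weighted_cross_entropy(_as_tensor(logits), y, class_weights, reduction)
        total = term if total is None else nn.add(total, term)
    return total


def gating_confidence_loss(rhos: list, confs: list, y: np.ndarray,
                           reduction: str = "sum") -> nn.Tensor:
    """L_GC = L_ce + L_mse over all omics.

    L_ce is the (unweighted) cross-entropy of each per-omics predictive
    distribution rho; L_mse regresses each learned confidence onto the
    true-class probability rho[n, y_n], which is treated as a fixed target
    (no gradient flows through it into the classifier).
    """
    y = np.asarray(y, dtype=np.int64)
    total = None
    for rho, conf in zip(rhos, confs):
        rho_t = _as_tensor(rho)
        conf_t = _as_tensor(conf)
        n, q = rho_t.shape
        onehot = np.zeros((n, q))
        onehot[np.arange(n), y] = 1.0
        ce = nn.mul(nn.tensor_sum(nn.mul(nn.log(rho_t), nn.constant(onehot))),
                    nn.constant(-1.0))
        target = nn.constant(tcp_targets(rho_t.data, y).reshape(-1, 1))
        diff = nn.add(conf_t, nn.mul(target, nn.constant(-1.0)))
        mse = nn.tensor_sum(nn.mul(diff, diff))
        term = nn.add(_reduce(ce, n, reduction), _reduce(mse, n, reduction))
        total = term if total is None else nn.add(total, term)
    return total


def total_loss(lgs, lgc, lola, cfg: TrainConfig) -> nn.Tensor:
    """L_total = L_GS + lambda1 * L_GC + lambda2 * L_OLA."""
    return nn.add(_as_tensor(lgs),
                  nn.add(nn.mul(_as_tensor(lgc), nn.constant(cfg.lambda1)),
                         nn.mul(_as_tensor(lola), nn.constant(cfg.lambda2))))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_finite(value: float, stage: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise TrainingDivergenceError(stage, epoch)


def fit(dataset: MultiOmicsDataset, train_idx, cfg: TrainConfig) -> TrainedModel:
    """Two-stage training on the given training subset (transductive)."""
    train_idx = np.asarray(train_idx, dtype=np.int64)
    y = dataset.labels.y[train_idx]
    n_classes = dataset.labels.n_classes
    if len(np.unique(y)) < 2:
        raise ConfigError("training subset must cover at least 2 classes")
    if cfg.k >= len(train_idx):
        raise ConfigError(f"k={cfg.k} must be smaller than the training set")

    rng = np.random.default_rng(cfg.seed)
    class_weights = compute_class_weights(y, n_classes, cfg.class_weighting)

    graphs = []
    x_train = []
    for om in dataset.omics:
        xm = om.values[train_idx]
        x_train.append(xm)
        graphs.append(build_graph(xm, cfg.k, om.omics_name,
                                  [om.sample_ids[i] for i in train_idx],
                                  standardize=cfg.standardize))

    encoders = [OmicsEncoder(rng, om.n_features, cfg.hidden_dims,
                             cfg.layer_order, cfg.dropout, cfg.gat_self_loop)
                for om in dataset.omics]
    h_out = encoders[0].dim_out
    stage1_heads = [
        (nn.parameter(nn.glorot(rng, h_out, n_classes)),
         nn.parameter(np.zeros((1, n_classes))))
        for _ in dataset.omics
    ]

    history: dict[str, list[dict[str, float]]] = {"stage1": [], "stage2": []}

    # ---- Stage 1: pretrain the graph encoders against L_GS ----
    params1 = [p for enc in encoders for p in enc.params()]
    params1 += [w for pair in stage1_heads for w in pair]
    opt1 = nn.Adam(params1, lr=cfg.lr, weight_decay=cfg.weight_decay)
    for epoch in range(cfg.epochs_pretrain):
        opt1.zero_grad()
        logits = []
        for enc, (W, b), g, xm in zip(encoders, stage1_heads, graphs, x_train):
            z = enc.forward(g, nn.constant(xm), training=True, rng=rng)[-1]
            logits.append(nn.add(nn.matmul(z, W), b))
        lgs = graph_structure_loss(logits, y, class_weights, cfg.reduction)
        _check_finite(float(lgs.data), "stage1", epoch)
        lgs.backward()
        opt1.step()
        history["stage1"].append({"epoch": epoch, "L_GS": float(lgs.data)})

    # ---- Stage 2: freeze encoders, train gating/confidence + fusion ----
    # The frozen embeddings are constant across stage-2 epochs (fixed graph,
    # fixed inputs, no dropout at inference), so compute them once.
    z_frozen = [
        nn.constant(enc.forward(g, nn.constant(xm), training=False)[-1].data)
        for enc, g, xm in zip(encoders, graphs, x_train)
    ]
    lgs_final = float(history["stage1"][-1]["L_GS"]) if history["stage1"] else 0.0

    gates = [GateParams(rng, h_out, n_classes) for _ in dataset.omics]
    fusion = FUSIONS[cfg.fusion](rng, [h_out] * len(dataset.omics), n_classes,
                                 **_fusion_kwargs(cfg))
    params2 = [p for gp in gates for p in gp.params()] + fusion.params()
    opt2 = nn.Adam(params2, lr=cfg.lr, weight_decay=cfg.weight_decay)
    for epoch in range(cfg.epochs_main):
        opt2.zero_grad()
        refined, rhos, confs = [], [], []
        for z, gp in zip(z_frozen, gates):
            parts = refine_omics(z, gp)
            refined.append(parts["Z_refined"] if cfg.use_gate else z)
            rhos.append(parts["rho"])
            confs.append(parts["conf"])
        lgc = gating_confidence_loss(rhos, confs, y, cfg.reduction)
        logits = fusion.forward(refined)
        lola = weighted_cross_entropy(logits, y, np.ones(n_classes), cfg.reduction)
        lt = total_loss(lgs_final, lgc, lola, cfg)
        _check_finite(float(lt.data), "stage2", epoch)
        # L_GS is constant under frozen encoders; only the trainable part
        # contributes gradients.
        lt.backward()
        opt2.step()
        history["stage2"].append({
            "epoch": epoch,
            "L_GS": lgs_final,
            "L_GC": float(lgc.data),
            "L_OLA": float(lola.data),
            "L_total": float(lt.data),
        })

    return TrainedModel(cfg, encoders, gates, fusion, graphs,
                        train_idx, class_weights, history)


def _fusion_kwargs(cfg: TrainConfig) -> dict:
    if cfg.fusion == "ola":
        return {"n_heads": cfg.ola_heads, "n_slots": cfg.ola_slots,
                "residual": cfg.ola_residual}
    return {}


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _combined_nodes(model: TrainedModel, eval_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train nodes first, then eval nodes not already in training."""
    train = model.train_idx
    extra = np.array([i for i in eval_idx if i not in set(train.tolist())],
                     dtype=np.int64)
    nodes = np.concatenate([train, extra])
    pos = {int(i): p for p, i in enumerate(nodes)}
    eval_pos = np.array([pos[int(i)] for i in eval_idx], dtype=np.int64)
    return nodes, eval_pos


def forward_detail(model: TrainedModel, dataset: MultiOmicsDataset,
                   eval_idx, graph_dataset: MultiOmicsDataset | None = None,
                   graphs: list[SimilarityGraph] | None = None) -> dict:
    """Gradient-free transductive pass over train + eval nodes.

    ``graph_dataset`` lets callers decouple the similarity graph from the
    model input (used by masking-based importance, where features are zeroed
    in the input but the graph is kept fixed); ``graphs`` short-circuits
    graph construction entirely when the caller has them precomputed.
    Returns probabilities, per-omics confidences and distributions for the
    eval rows.
    """
    cfg = model.config
    eval_idx = np.asarray(eval_idx, dtype=np.int64)
    nodes, eval_pos = _combined_nodes(model, eval_idx)
    if graphs is None:
        gsrc = graph_dataset if graph_dataset is not None else dataset
        graphs = build_prediction_graphs(model, gsrc, nodes)
    refined, rhos, confs = [], [], []
    for om, enc, gp, g in zip(dataset.omics, model.encoders, model.gates, graphs):
        xm = om.values[nodes]
        z = enc.forward(g, nn.constant(xm), training=False)[-1]
        parts = refine_omics(z, gp)
        refined.append(parts["Z_refined"] if cfg.use_gate else z)
        rhos.append(parts["rho"].data[eval_pos])
        confs.append(parts["conf"].data[eval_pos].ravel())
    logits = model.fusion.forward(refined)
    probs = nn.softmax_axis(logits, axis=1).data[eval_pos]
    return {"proba": probs, "rho": rhos, "conf": confs, "nodes": nodes,
            "eval_pos": eval_pos}


def build_prediction_graphs(model: TrainedModel, dataset: MultiOmicsDataset,
                            nodes: np.ndarray) -> list[SimilarityGraph]:
    """Similarity graphs over the combined train + eval node set.

    With ``test_links`` off, candidate neighbors of an eval node are
    restricted to training nodes (eval-eval edges removed before
    symmetrization side effects are reapplied).
    """
    cfg = model.config
    n_train = len(model.train_idx)
    graphs = []
    for om in dataset.omics:
        g = build_graph(om.values[nodes], cfg.k, om.omics_name,
                        standardize=cfg.standardize)
        if not cfg.test_links and len(nodes) > n_train:
            adj = g.adjacency.copy()
            adj[n_train:, n_train:] = 0.0
            g = SimilarityGraph(np.maximum(adj, adj.T), cfg.k, om.omics_name)
        graphs.append(g)
    return graphs


def predict_proba(model: TrainedModel, dataset: MultiOmicsDataset,
                  eval_idx, **kwargs) -> np.ndarray:
    """Class probabilities for the eval samples; rows sum to 1."""
    return forward_detail(model, dataset, eval_idx, **kwargs)["proba"]
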