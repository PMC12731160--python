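"""Repeated stratified evaluation, metrics, and masking-based importance.

The evaluation protocol holds out a stratified 30% test set, trains on the
rest, and repeats over independent random splits (five by default),
reporting mean and standard deviation of accuracy and F1 scores (plus ROC
AUC for binary tasks).  Prediction is transductive: the test samples join
the similarity graphs unlabeled.

Feature importance follows the masking principle: with a trained model
fixed, each feature column is zeroed in the test inputs (the similarity
graph is left untouched), the test set is re-classified, and the feature's
importance is the resulting drop in macro-F1 relative to the unmasked
baseline.  Features whose masking hurts the most rank as the strongest
candidate biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from . import nn
from .data_io import LabelVector, MultiOmicsDataset
from .exceptions import ConfigError, ValidationError
from .gating import refine_omics
from .training import (TrainConfig, TrainedModel, build_prediction_graphs,
                       fit, forward_detail, predict_proba, _combined_nodes)

LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class SplitPlan:
    """Stratified train/test index pairs for repeated evaluation."""

    n_repeats: int
    test_fraction: float
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int


@dataclass
class MetricsReport:
    """Per-repeat metric rows plus their mean and standard deviation."""

    rows: list[dict[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.insert(0, "repeat", range(len(df)))
        return df

    def summary(self) -> dict[str, tuple[float, float]]:
        df = pd.DataFrame(self.rows)
        return {c: (float(df[c].mean()), float(df[c].std(ddof=0)))
                for c in df.columns}

    def to_csv(self, path: str) -> None:
        df = self.to_frame()
        means = {c: df[c].mean() for c in df.columns if c != "repeat"}
        stds = {c: df[c].std(ddof=0) for c in df.columns if c != "repeat"}
        df = pd.concat([df, pd.DataFrame([
            {"repeat": "mean", **means}, {"repeat": "std", **stds},
        ])], ignore_index=True)
        df.to_csv(path, index=False)


def make_splits(labels: LabelVector, test_fraction: float = 0.3,
                n_repeats: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified random splits preserving class proportions in the test set."""
    if not (0.0 < test_fraction < 1.0):
        raise ConfigError(f"test_fraction {test_fraction} must be in (0, 1)")
    counts = np.bincount(labels.y, minlength=labels.n_classes)
    if counts.min() < 2:
        small = [labels.class_names[q] for q in np.flatnonzero(counts < 2)]
        raise ValidationError(f"classes too small to split: {small}")
    sss = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_fraction,
                                 random_state=seed)
    splits = [(np.sort(tr), np.sort(te))
              for tr, te in sss.split(np.zeros(len(labels.y)), labels.y)]
    return SplitPlan(n_repeats, test_fraction, splits, seed)


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    binary: bool = False) -> dict[str, float]:
    """ACC and F1 scores from argmax predictions; AUC for binary tasks."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    if binary and y_prob.shape[1] != 2:
        raise ConfigError("binary metrics need exactly 2 classes")
    y_pred = y_prob.argmax(axis=1)
    row = {
        "acc": float(accuracy_score(y_true, y_pred)),
        "f1_weighted": float(f1_score(y_true, y_pred, average="weighted",
                                      zero_division=0)),
        "f1_macro": float(f1_score(y_true, y_pred, average="macro",
                                   zero_division=0)),
    }
    if binary:
        row["auc"] = float(roc_auc_score(y_true, y_prob[:, 1]))
    return row


# ---------------------------------------------------------------------------
# The repeated-split protocol
# ---------------------------------------------------------------------------

def evaluate_protocol(dataset: MultiOmicsDataset, cfg: TrainConfig,
                      test_fraction: float = 0.3, n_repeats: int = 5,
                      seed: int = 0, keep_models: bool = False) -> dict:
    """Train/evaluate over repeated stratified splits.

    Each repeat gets its own training seed derived from ``seed`` so the
    repeats are independent but the whole protocol is reproducible.  Returns
    the metrics report plus per-repeat details (probabilities, per-omics
    confidences split by correctness) and, optionally, the fitted models.
    """
    binary = dataset.labels.n_classes == 2
    plan = make_splits(dataset.labels, test_fraction, n_repeats, seed)
    report = MetricsReport()
    details = []
    models = []
    for r, (train_idx, test_idx) in enumerate(plan.splits):
        rcfg = TrainConfig(**{**cfg.to_dict(), "seed": (seed + 1) * 1000 + r})
        model = fit(dataset, train_idx, rcfg)
        out = forward_detail(model, dataset, test_idx)
        y_true = dataset.labels.y[test_idx]
        report.rows.append(compute_metrics(y_true, out["proba"], binary))
        correct = out["proba"].argmax(axis=1) == y_true
        conf = np.mean(out["conf"], axis=0)  # mean over omics, per sample
        details.append({
            "train_idx": train_idx, "test_idx": test_idx,
            "proba": out["proba"], "correct": correct,
            "conf": conf,
            "conf_correct": float(conf[correct].mean()) if correct.any() else np.nan,
            "conf_wrong": float(conf[~correct].mean()) if (~correct).any() else np.nan,
        })
        if keep_models:
            models.append(model)
    return {"report": report, "details": details, "plan": plan,
            "models": models if keep_models else None}


# ---------------------------------------------------------------------------
# Masking-based feature importance
# ---------------------------------------------------------------------------

def feature_importance(model: TrainedModel, dataset: MultiOmicsDataset,
                       test_idx, rebuild_graph: bool = False) -> pd.DataFrame:
    """Importance of every feature as the macro-F1 drop under masking.

    The baseline macro-F1 is computed once on the unmasked test set.  Each
    feature column is then zeroed across the test rows only, the test set is
    re-classified, and importance = baseline - masked score.  By default the
    similarity graphs stay fixed at the unmasked data (``rebuild_graph``
    recomputes them per mask).  Ties sort by (omics_name, feature_id).
    """
    test_idx = np.asarray(test_idx, dtype=np.int64)
    y_true = dataset.labels.y[test_idx]
    nodes, eval_pos = _combined_nodes(model, test_idx)
    graphs = build_prediction_graphs(model, dataset, nodes)
    n_train = len(model.train_idx)
    # Frozen embeddings + refined features per omics for the unmasked input.
    x_nodes = [om.values[nodes] for om in dataset.omics]

    def omics_refined(m: int, xm: np.ndarray, graph) -> nn.Tensor:
        z = model.encoders[m].forward(graph, nn.constant(xm), training=False)[-1]
        parts = refine_omics(z, model.gates[m])
        return parts["Z_refined"] if model.config.use_gate else z

    base_refined = [omics_refined(m, x_nodes[m], graphs[m])
                    for m in range(dataset.n_omics)]

    def macro_f1(refined) -> float:
        probs = nn.softmax_axis(model.fusion.forward(refined), axis=1).data[eval_pos]
        return float(f1_score(y_true, probs.argmax(axis=1), average="macro",
                              zero_division=0))

    baseline = macro_f1(base_refined)
    mask_rows = eval_pos[eval_pos >= 0]  # positions of test samples in the node set
    records = []
    for m, om in enumerate(dataset.omics):
        for j, feat in enumerate(om.feature_ids):
            xm = x_nodes[m].copy()
            xm[mask_rows, j] = 0.0
            graph = graphs[m]
            if rebuild_graph:
                from .graphs import build_graph
                graph = build_graph(xm, model.config.k, om.omics_name,
                                    standardize=model.config.standardize)
            refined = list(base_refined)
            refined[m] = omics_refined(m, xm, graph)
            records.append((om.omics_name, feat, baseline - macro_f1(refined)))
    df = pd.DataFrame(records, columns=["omics", "feature_id", "importance"])
    return df.sort_values(["importance", "omics", "feature_id"],
                          ascending=[False, True, True]).reset_index(drop=True)


def aggregate_importance(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-feature importance over several models' tables.

    Single-model masking importance is quantized (one flipped test sample
    changes macro-F1 by a fixed step), so the ranking stabilizes
    substantially when averaged over the models of a repeated-split
    protocol.  Sorting matches :func:`feature_importance`.
    """
    stacked = pd.concat(tables, ignore_index=True)
    df = (stacked.groupby(["omics", "feature_id"], as_index=False)["importance"]
          .mean())
    return df.sort_values(["importance", "omics", "feature_id"],
                          ascending=[False, True, True]).reset_index(drop=True)


def identified_biomarkers(table: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Features whose masking measurably hurts (importance > threshold)."""
    return table[table["importance"] > threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Omics-combination and module-substitution runners
# ---------------------------------------------------------------------------

def run_omics_combinations(dataset: MultiOmicsDataset, cfg: TrainConfig,
                           n_repeats: int = 5, seed: int = 0,
                           min_size: int = 2) -> pd.DataFrame:
    """Full pipeline on every omics subset; long-format results."""
    names = [om.omics_name for om in dataset.omics]
    rows = []
    for size in range(min_size, len(names) + 1):
        for combo in combinations(names, size):
            sub = dataset.subset_omics(list(combo))
            res = evaluate_protocol(sub, cfg, n_repeats=n_repeats, seed=seed)
            for r, rep in enumerate(res["report"].rows):
                for metric, value in rep.items():
                    rows.append({"combination": "+".join(combo), "repeat": r,
                                 "metric": metric, "value": value})
    return pd.DataFrame(rows)


ABLATIONS = ("gsl", "gate", "ola")


def ablation_config(cfg: TrainConfig, component: str) -> TrainConfig:
    """Config with one module removed or substituted.

    ``gsl`` replaces the graph encoder stack with a single linear layer,
    ``gate`` drops the gating/confidence refinement from the fusion input,
    ``ola`` bypasses attention fusion with plain concatenation; fusion
    variants (``self_attention``, ``vcdn``) and any dash-separated layer
    order are also accepted.
    """
    d = cfg.to_dict()
    if component == "gsl":
        d["layer_order"] = "linear"
        d["hidden_dims"] = [cfg.hidden_dims[-1]]
    elif component == "gate":
        d["use_gate"] = False
    elif component == "ola":
        d["fusion"] = "concat"
    elif component in ("self_attention", "vcdn"):
        d["fusion"] = component
    elif "-" in component or component in ("gcn", "gat"):
        d["layer_order"] = component
    else:
        raise ConfigError(f"unknown ablation '{component}'")
    return TrainConfig(**d)


def run_ablations(dataset: MultiOmicsDataset, cfg: TrainConfig,
                  components=ABLATIONS, n_repeats: int = 5,
                  seed: int = 0) -> pd.DataFrame:
    """Mean metrics for the full model and each ablated variant."""
    rows = []
    variants = [("full", cfg)] + [(c, ablation_config(cfg, c)) for c in components]
    for name, vcfg in variants:
        res = evaluate_protocol(dataset, vcfg, n_repeats=n_repeats, seed=seed)
        for metric, (mean, std) in res["report"].summary().items():
            rows.append({"variant": name, "metric": metric,
                         "mean": mean, "std": std})
    return pd.DataFrame(rows)


def grid_search_lambdas(dataset: MultiOmicsDataset, cfg: TrainConfig,
                        grid=LAMBDA_GRID, n_repeats: int = 3,
                        seed: int = 0) -> pd.DataFrame:
    """Sweep the loss-weight pair over the grid; mean ACC per combination."""
    rows = []
    for l1 in grid:
        for l2 in grid:
            vcfg = TrainConfig(**{**cfg.to_dict(), "lambda1": l1, "lambda2": l2})
            res = evaluate_protocol(dataset, vcfg, n_repeats=n_repeats, seed=seed)
            mean_acc, std_acc = res["report"].summary()["acc"]
            rows.append({"lambda1": l1, "lambda2": l2,
                         "acc_mean": mean_acc, "acc_std": std_acc})
    return pd.DataFrame(rows)
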