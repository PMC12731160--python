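"""Split protocol, metrics oracles, and masking-based importance."""

import numpy as np
import pytest

from omicsfuse.data_io import LabelVector
from omicsfuse.evaluation import (ablation_config, compute_metrics,
                                  evaluate_protocol, feature_importance,
                                  identified_biomarkers, make_splits)
from omicsfuse.exceptions import ConfigError, ValidationError
from omicsfuse.simulate import SimulationConfig, simulate_multiomics
from omicsfuse.training import TrainConfig, fit


def labels_of(y, q):
    return LabelVector([f"s{i}" for i in range(len(y))], np.array(y),
                       [f"c{i}" for i in range(q)])


class TestMakeSplits:
    def test_balanced_counts_forced_by_stratification(self):
        y = [0] * 50 + [1] * 50
        plan = make_splits(labels_of(y, 2), 0.3, n_repeats=3, seed=0)
        for train, test in plan.splits:
            assert len(test) == 30
            assert np.bincount(np.array(y)[test]).tolist() == [15, 15]
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 100

    def test_deterministic_for_fixed_seed(self):
        y = [0] * 20 + [1] * 30 + [2] * 10
        p1 = make_splits(labels_of(y, 3), 0.3, 5, seed=9)
        p2 = make_splits(labels_of(y, 3), 0.3, 5, seed=9)
        for (a, b), (c, d) in zip(p1.splits, p2.splits):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_imbalanced_counts_match_stratified_allocation(self):
        y = [0] * 40 + [1] * 25 + [2] * 10
        plan = make_splits(labels_of(y, 3), 0.3, 5, seed=1)
        for _, test in plan.splits:
            counts = np.bincount(np.array(y)[test], minlength=3)
            # per-class allocation of 30% within rounding
            for q, n_q in enumerate([40, 25, 10]):
                assert abs(counts[q] - 0.3 * n_q) <= 1

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            make_splits(labels_of([0] * 10 + [1], 2), 0.3, 2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            make_splits(labels_of([0, 0, 1, 1], 2), 1.5, 1, seed=0)


def confusion_metrics_oracle(y_true, y_pred, q):
    """Macro/weighted F1 from explicit confusion-matrix arithmetic."""
    f1s, support = [], []
    for c in range(q):
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        support.append(np.sum(y_true == c))
    support = np.array(support, dtype=float)
    return float(np.mean(f1s)), float(np.average(f1s, weights=support))


def auc_rank_oracle(y_true, scores):
    """Pairwise comparison with half credit for ties."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1])
        probs = np.eye(3)[y]
        m = compute_metrics(y, probs)
        assert m == {"acc": 1.0, "f1_weighted": 1.0, "f1_macro": 1.0}

    def test_binary_auc_is_one_for_separated_scores(self):
        y = np.array([0, 0, 1, 1])
        p0 = np.array([0.9, 0.8, 0.4, 0.1])
        probs = np.column_stack([p0, 1 - p0])
        m = compute_metrics(y, probs, binary=True)
        assert m["auc"] == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_classes(self):
        y = np.array([0, 1, 2] * 10)
        probs = np.tile([0.5, 0.3, 0.2], (30, 1))
        m = compute_metrics(y, probs)
        assert m["acc"] == pytest.approx(1 / 3)
        macro, _ = confusion_metrics_oracle(y, probs.argmax(axis=1), 3)
        assert m["f1_macro"] == pytest.approx(macro)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_confusion_and_rank_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        probs = rng.dirichlet(np.ones(2), size=n)
        probs = np.round(probs, 1)  # create ties for the AUC tie rule
        probs = probs / probs.sum(axis=1, keepdims=True)
        m = compute_metrics(y, probs, binary=True)
        macro, weighted = confusion_metrics_oracle(y, probs.argmax(axis=1), 2)
        assert m["f1_macro"] == pytest.approx(macro)
        assert m["f1_weighted"] == pytest.approx(weighted)
        assert m["auc"] == pytest.approx(auc_rank_oracle(y, probs[:, 1]))

    def test_binary_flag_needs_two_classes(self):
        with pytest.raises(ConfigError):
            compute_metrics(np.array([0, 1, 2]), np.eye(3), binary=True)


FAST = dict(hidden_dims=(12, 12, 8), epochs_pretrain=40, epochs_main=60,
            lr=5e-3, k=3, dropout=0.2, ola_slots=8, ola_heads=2)


@pytest.fixture(scope="module")
def fitted_tiny():
    """An information-limited 2-omics problem where masking is sensitive."""
    cfg = SimulationConfig(
        n_samples=120, n_classes=2, n_features=(25, 25),
        n_informative=(4, 4), effect_size=1.0, shared_factor_dim=0,
        class_proportions=(0.5, 0.5), omics_names=("omA", "omB"), seed=21,
    )
    dataset, truth = simulate_multiomics(cfg)
    plan = make_splits(dataset.labels, 0.3, 1, seed=0)
    train_idx, test_idx = plan.splits[0]
    model = fit(dataset, train_idx, TrainConfig(seed=4, **FAST))
    return dataset, truth, model, test_idx


class TestFeatureImportance:
    def test_identically_zero_feature_has_zero_importance(self, fitted_tiny):
        dataset, truth, model, test_idx = fitted_tiny
        zeroed = dataset.omics[0].values.copy()
        zeroed[test_idx, 0] = 0.0
        from omicsfuse.data_io import MultiOmicsDataset, OmicsMatrix
        om0 = dataset.omics[0]
        mutated = MultiOmicsDataset(
            [OmicsMatrix(om0.omics_name, om0.sample_ids, om0.feature_ids, zeroed),
             dataset.omics[1]], dataset.labels)
        table = feature_importance(model, mutated, test_idx)
        row = table[(table.omics == "omA") & (table.feature_id == om0.feature_ids[0])]
        assert float(row.importance.iloc[0]) == 0.0

    def test_deterministic_recomputation(self, fitted_tiny):
        dataset, truth, model, test_idx = fitted_tiny
        t1 = feature_importance(model, dataset, test_idx)
        t2 = feature_importance(model, dataset, test_idx)
        assert t1.equals(t2)

    def test_informative_features_score_higher_on_average(self, fitted_tiny):
        dataset, truth, model, test_idx = fitted_tiny
        table = feature_importance(model, dataset, test_idx)
        diffs = []
        for om in dataset.omics:
            ids = {om.feature_ids[j]
                   for j in np.flatnonzero(truth.informative_mask[om.omics_name])}
            sub = table[table.omics == om.omics_name]
            inf = sub.feature_id.isin(ids)
            diffs.append(sub[inf].importance.mean() - sub[~inf].importance.mean())
        assert np.mean(diffs) > 0

    def test_sorted_descending_with_deterministic_ties(self, fitted_tiny):
        dataset, truth, model, test_idx = fitted_tiny
        table = feature_importance(model, dataset, test_idx)
        imp = table.importance.to_numpy()
        assert np.all(np.diff(imp) <= 1e-15)
        pos = identified_biomarkers(table)
        assert (pos.importance > 0).all()


def test_ablation_config_variants():
    cfg = TrainConfig(epochs_pretrain=1, epochs_main=1, hidden_dims=(8, 8, 4))
    assert ablation_config(cfg, "gsl").layer_order == "linear"
    assert ablation_config(cfg, "gsl").hidden_dims == (4,)
    assert ablation_config(cfg, "gate").use_gate is False
    assert ablation_config(cfg, "ola").fusion == "concat"
    assert ablation_config(cfg, "vcdn").fusion == "vcdn"
    assert ablation_config(cfg, "gat-gcn-gat").layer_order == "gat-gcn-gat"
    with pytest.raises(ConfigError):
        ablation_config(cfg, "bogus")


def test_protocol_report_shape_and_determinism(tiny_dataset):
    dataset, _ = tiny_dataset
    cfg = TrainConfig(seed=0, **FAST)
    r1 = evaluate_protocol(dataset, cfg, n_repeats=2, seed=5)
    r2 = evaluate_protocol(dataset, cfg, n_repeats=2, seed=5)
    assert r1["report"].rows == r2["report"].rows
    summary = r1["report"].summary()
    assert set(summary) >= {"acc", "f1_weighted", "f1_macro", "auc"}
    for mean, std in summary.values():
        assert 0.0 <= mean <= 1.0 and std >= 0.0
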