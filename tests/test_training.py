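"""Losses, class weighting, and the two-stage fit contract."""

import numpy as np
import pytest

from omicsfuse import nn
from omicsfuse.exceptions import ConfigError
from omicsfuse.training import (TrainConfig, compute_class_weights, fit,
                                gating_confidence_loss, graph_structure_loss,
                                predict_proba, total_loss,
                                weighted_cross_entropy)


def ce_loss_oracle(logits_list, y, w):
    """Per-sample loop of -w_y log softmax(logits)[y], summed over omics."""
    total = 0.0
    for logits in logits_list:
        for n, yn in enumerate(y):
            z = logits[n] - logits[n].max()
            p = np.exp(z) / np.exp(z).sum()
            total += -w[yn] * np.log(p[yn])
    return total


class TestGraphStructureLoss:
    def test_perfect_logits_vanish(self):
        y = np.array([0, 1, 2])
        logits = np.eye(3) * 1e4
        loss = graph_structure_loss([logits], y, np.ones(3))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_logits_closed_form(self):
        """M omics x N samples of uniform logits give M*N*ln(Q)."""
        y = np.array([0, 1, 2, 0, 1])
        logits = [np.zeros((5, 3))] * 2
        loss = graph_structure_loss(logits, y, np.ones(3))
        assert float(loss.data) == pytest.approx(2 * 5 * np.log(3), rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        y = rng.integers(0, 3, size=7)
        w = rng.uniform(0.5, 2.0, size=3)
        logits = [rng.standard_normal((7, 3)) for _ in range(2)]
        loss = graph_structure_loss(logits, y, w)
        assert float(loss.data) == pytest.approx(ce_loss_oracle(logits, y, w),
                                                 rel=1e-10)

    def test_weight_length_mismatch(self, rng):
        with pytest.raises(IndexError):
            graph_structure_loss([rng.standard_normal((4, 3))],
                                 np.array([0, 1, 2, 2]), np.ones(2))


class TestGatingConfidenceLoss:
    def test_perfect_case_vanishes(self):
        y = np.array([0, 1])
        rho = np.eye(2) * (1 - 1e-12) + 1e-12 / 2
        conf = np.ones((2, 1))
        loss = gating_confidence_loss([rho], [conf], y)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_mse_term_zero_when_conf_matches_tcp(self, rng):
        y = rng.integers(0, 3, size=5)
        rho = rng.dirichlet(np.ones(3), size=5)
        conf = rho[np.arange(5), y].reshape(-1, 1)
        loss = gating_confidence_loss([rho], [conf], y)
        ce = -np.log(rho[np.arange(5), y]).sum()
        assert float(loss.data) == pytest.approx(ce, rel=1e-10)

    def test_matches_combined_loop_oracle(self, rng):
        y = rng.integers(0, 4, size=6)
        rhos = [rng.dirichlet(np.ones(4), size=6) for _ in range(2)]
        confs = [rng.uniform(0, 1, size=(6, 1)) for _ in range(2)]
        loss = gating_confidence_loss(rhos, confs, y)
        expected = 0.0
        for rho, conf in zip(rhos, confs):
            for n, yn in enumerate(y):
                expected += -np.log(rho[n, yn])
                expected += (conf[n, 0] - rho[n, yn]) ** 2
        assert float(loss.data) == pytest.approx(expected, rel=1e-10)


def test_total_loss_arithmetic():
    cfg = TrainConfig(lambda1=1.0, lambda2=1.0, epochs_pretrain=1, epochs_main=1)
    assert float(total_loss(1.0, 2.0, 3.0, cfg).data) == pytest.approx(6.0)
    cfg10 = TrainConfig(lambda1=10.0, lambda2=10.0, epochs_pretrain=1, epochs_main=1)
    assert float(total_loss(0.5, 0.2, 0.1, cfg10).data) == pytest.approx(3.5)


def test_class_weights_balanced_is_identity():
    y = np.array([0, 0, 1, 1, 2, 2])
    np.testing.assert_allclose(compute_class_weights(y, 3), 1.0)
    np.testing.assert_allclose(compute_class_weights(y, 3, enabled=False), 1.0)
    imb = compute_class_weights(np.array([0, 0, 0, 1]), 2)
    np.testing.assert_allclose(imb, [4 / 6, 4 / 2])


def test_weighted_ce_mean_reduction(rng):
    y = rng.integers(0, 2, size=8)
    logits = nn.constant(rng.standard_normal((8, 2)))
    s = float(weighted_cross_entropy(logits, y, np.ones(2), "sum").data)
    m = float(weighted_cross_entropy(logits, y, np.ones(2), "mean").data)
    assert m == pytest.approx(s / 8, rel=1e-12)


FAST = dict(hidden_dims=(12, 12, 8), epochs_pretrain=40, epochs_main=60,
            lr=5e-3, k=3, dropout=0.2, ola_slots=8, ola_heads=2)


class TestFitContract:
    def test_same_seed_reproduces_history(self, tiny_dataset):
        dataset, _ = tiny_dataset
        idx = np.arange(40)
        cfg = TrainConfig(seed=3, **FAST)
        m1 = fit(dataset, idx, cfg)
        m2 = fit(dataset, idx, cfg)
        assert m1.loss_history == m2.loss_history

    def test_stage2_freezes_encoders(self, tiny_dataset):
        dataset, _ = tiny_dataset
        cfg = TrainConfig(seed=0, **FAST)
        model = fit(dataset, np.arange(40), cfg)
        # rerun stage 1 alone: encoder params must match the full run's
        cfg1 = TrainConfig(seed=0, **{**FAST, "epochs_main": 1})
        model1 = fit(dataset, np.arange(40), cfg1)
        for enc_a, enc_b in zip(model.encoders, model1.encoders):
            for pa, pb in zip(enc_a.params(), enc_b.params()):
                np.testing.assert_array_equal(pa.data, pb.data)

    def test_training_accuracy_on_separable_data(self, tiny_dataset):
        dataset, _ = tiny_dataset
        idx = np.arange(dataset.n_samples)
        cfg = TrainConfig(seed=1, **FAST)
        model = fit(dataset, idx, cfg)
        probs = predict_proba(model, dataset, idx)
        acc = (probs.argmax(axis=1) == dataset.labels.y[idx]).mean()
        assert acc >= 0.95

    def test_stage1_loss_nonincreasing_trend(self, tiny_dataset):
        """At lr <= 1e-3 and no dropout, stage-1 loss trends downward."""
        dataset, _ = tiny_dataset
        cfg = TrainConfig(seed=0, **{**FAST, "lr": 1e-3, "dropout": 0.0})
        model = fit(dataset, np.arange(40), cfg)
        losses = [r["L_GS"] for r in model.loss_history["stage1"]]
        violations = sum(b > a * 1.05 for a, b in zip(losses, losses[1:]))
        assert violations == 0
        assert losses[-1] < losses[0]

    def test_predict_rows_sum_to_one_and_order_equivariance(self, tiny_dataset):
        dataset, _ = tiny_dataset
        cfg = TrainConfig(seed=2, **FAST)
        model = fit(dataset, np.arange(40), cfg)
        eval_idx = np.arange(40, 60)
        probs = predict_proba(model, dataset, eval_idx)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        rev = predict_proba(model, dataset, eval_idx[::-1])
        np.testing.assert_allclose(rev, probs[::-1], atol=1e-12)

    def test_k_must_be_smaller_than_training_set(self, tiny_dataset):
        dataset, _ = tiny_dataset
        cfg = TrainConfig(seed=0, **{**FAST, "k": 10})
        with pytest.raises(ConfigError):
            fit(dataset, np.arange(8), cfg)


def test_config_validation_and_yaml_round_trip(tmp_path):
    with pytest.raises(ConfigError):
        TrainConfig(lambda1=0.0)
    with pytest.raises(ConfigError):
        TrainConfig(fusion="nope")
    cfg = TrainConfig(k=4, lambda1=0.1, hidden_dims=(8, 8, 4),
                      epochs_pretrain=2, epochs_main=2)
    p = tmp_path / "cfg.yaml"
    import yaml
    p.write_text(yaml.safe_dump(cfg.to_dict()))
    back = TrainConfig.from_yaml(str(p))
    assert back == cfg
    with pytest.raises(ConfigError):
        TrainConfig.from_yaml(str(p), lambda2=-1)
    p2 = tmp_path / "bad.yaml"
    p2.write_text("not_a_key: 1\n")
    with pytest.raises(ConfigError):
        TrainConfig.from_yaml(str(p2))
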