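"""Gating and true-class-probability (TCP) confidence refinement.

Each omics embedding Z is refined twice before fusion.  A sigmoid gate
sigma(l(Z)) rescales each latent coordinate into (0, 1), performing soft
feature selection; a confidence head t(Z) -> sigma -> [0, 1] scales whole
samples by how reliable this omics layer looks for them.  The confidence
head is trained to regress the true-class probability of a per-omics
classifier c(Z): a sample the classifier gets wrong has low TCP, so its
contribution from that omics is down-weighted in the fusion.  The refined
embedding is the elementwise product of the two refinements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ValidationError


@dataclass
class RefinedEmbedding:
    """Inference-time view of one omics layer's refined features."""

    Z_gate: np.ndarray
    Z_tcp: np.ndarray
    Z_refined: np.ndarray
    conf: np.ndarray       # per-sample confidence in [0, 1]
    rho: np.ndarray        # N x Q per-omics predictive distribution


class GateParams:
    """Gate projection l, confidence head t, per-omics classifier c."""

    def __init__(self, rng: np.random.Generator, dim: int, n_classes: int):
        self.l_W = nn.parameter(nn.glorot(rng, dim, dim))
        self.l_b = nn.parameter(np.zeros((1, dim)))
        self.t_W = nn.parameter(nn.glorot(rng, dim, 1, shape=(dim, 1)))
        self.t_b = nn.parameter(np.zeros((1, 1)))
        self.c_W = nn.parameter(nn.glorot(rng, dim, n_classes))
        self.c_b = nn.parameter(np.zeros((1, n_classes)))

    def params(self) -> list[nn.Tensor]:
        return [self.l_W, self.l_b, self.t_W, self.t_b, self.c_W, self.c_b]


def gate_features(Z: nn.Tensor, params: GateParams) -> nn.Tensor:
    """sigma(l(Z)) ⊙ Z — elementwise sigmoid gate (outer map is identity)."""
    gate = nn.sigmoid(nn.add(nn.matmul(Z, params.l_W), params.l_b))
    return nn.mul(gate, Z)


def confidence_weight(Z: nn.Tensor, params: GateParams) -> tuple[nn.Tensor, nn.Tensor]:
    """Per-sample scores sigma(t(Z)) in [0, 1] and the row-scaled embedding."""
    scores = nn.sigmoid(nn.add(nn.matmul(Z, params.t_W), params.t_b))  # N x 1
    return scores, nn.mul(scores, Z)


def refine_embedding(Z_gate: nn.Tensor, Z_tcp: nn.Tensor) -> nn.Tensor:
    """Combine the two refinements elementwise."""
    if Z_gate.shape != Z_tcp.shape:
        raise ValidationError(
            f"shape mismatch: {Z_gate.shape} vs {Z_tcp.shape}"
        )
    return nn.mul(Z_gate, Z_tcp)


def omics_predictive_distribution(Z: nn.Tensor, params: GateParams) -> nn.Tensor:
    """rho = softmax(c(Z)) for one omics layer."""
    return nn.softmax_axis(nn.add(nn.matmul(Z, params.c_W), params.c_b), axis=1)


def tcp_targets(rho: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Probability each sample's classifier assigns to its true class."""
    rho = np.asarray(rho, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if y.min() < 0 or y.max() >= rho.shape[1]:
        raise ValidationError("class index out of range for rho")
    return rho[np.arange(len(y)), y]


def refine_omics(Z: nn.Tensor, params: GateParams) -> dict[str, nn.Tensor]:
    """Full refinement pass; returns all intermediates as tracked tensors."""
    z_gate = gate_features(Z, params)
    conf, z_tcp = confidence_weight(Z, params)
    return {
        "Z_gate": z_gate,
        "Z_tcp": z_tcp,
        "Z_refined": refine_embedding(z_gate, z_tcp),
        "conf": conf,
        "rho": omics_predictive_distribution(Z, params),
    }


def refined_embedding_numpy(Z: np.ndarray, params: GateParams) -> RefinedEmbedding:
    """Inference helper returning plain arrays."""
    parts = refine_omics(nn.constant(Z), params)
    return RefinedEmbedding(
        Z_gate=parts["Z_gate"].data,
        Z_tcp=parts["Z_tcp"].data,
        Z_refined=parts["Z_refined"].data,
        conf=parts["conf"].data.ravel(),
        rho=parts["rho"].data,
    )
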