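"""Per-omics graph encoders: stacked GCN and GAT layers.

The default encoder is the three-layer GCN-GAT-GCN hybrid: a graph
convolution smooths each sample's features over its similarity neighborhood,
a single-head graph attention layer re-weights neighbors by learned
relevance, and a final convolution consolidates the result into the latent
embedding Z.  Alternative layer orders (for architecture comparisons) are
built from the same two layer primitives, and a plain linear map stands in
for the whole module in the "no graph structure learning" ablation.

All layers run on the dense adjacency; the graphs here have at most a few
thousand nodes, where dense numpy is faster than sparse bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .exceptions import ConfigError
from .graphs import SimilarityGraph

LEAKY_SLOPE = 0.2  # LeakyReLU slope in the attention logits (GAT convention)


@dataclass
class OmicsEmbedding:
    """Latent matrices from the encoder: one per layer, Z = last."""

    Z1: np.ndarray
    Z2: np.ndarray
    Z: np.ndarray
    omics_name: str


class GCNLayer:
    """ReLU(D^-1/2 (S+I) D^-1/2 X W) with D the degree matrix of S+I."""

    kind = "gcn"

    def __init__(self, rng: np.random.Generator, dim_in: int, dim_out: int):
        self.W = nn.parameter(nn.glorot(rng, dim_in, dim_out))

    def params(self) -> list[nn.Tensor]:
        return [self.W]

    def forward(self, graph: SimilarityGraph, X: nn.Tensor) -> nn.Tensor:
        A = nn.constant(graph.normalized_adjacency())
        return nn.relu(nn.matmul(nn.matmul(A, X), self.W))


class GATLayer:
    """Single-head graph attention with softmax-normalized coefficients.

    Attention logits are LeakyReLU(a^T [W x_i || W x_j]) over each node's
    neighborhood; by default the node itself is part of its neighborhood,
    mirroring the self-loop treatment of the convolution layers.
    """

    kind = "gat"

    def __init__(self, rng: np.random.Generator, dim_in: int, dim_out: int,
                 self_loop: bool = True):
        self.W = nn.parameter(nn.glorot(rng, dim_in, dim_out))
        self.a = nn.parameter(nn.glorot(rng, 2 * dim_out, 1, shape=(2 * dim_out, 1)))
        self.self_loop = self_loop

    def params(self) -> list[nn.Tensor]:
        return [self.W, self.a]

    def _mask(self, graph: SimilarityGraph) -> np.ndarray:
        mask = graph.adjacency.copy()
        if self.self_loop:
            np.fill_diagonal(mask, 1.0)
        return mask

    def forward_with_coeffs(self, graph: SimilarityGraph,
                            X: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = nn.matmul(X, self.W)                       # N x h
        d = h.shape[1]
        f = nn.matmul(h, nn.slice_rows(self.a, 0, d))        # source term, N x 1
        g = nn.matmul(h, nn.slice_rows(self.a, d, 2 * d))    # target term, N x 1
        logits = nn.leaky_relu(nn.add(f, nn.transpose(g)), LEAKY_SLOPE)
        mask = self._mask(graph)
        # Masked softmax per row: -inf additive mask kills non-neighbors
        # before the exp (avoiding overflow there), shifted by the row max
        # over the neighborhood (treated as a constant).
        neg_mask = np.where(mask > 0, 0.0, -np.inf)
        shifted = np.where(mask > 0, logits.data, -np.inf)
        row_max = nn.constant(shifted.max(axis=1, keepdims=True))
        e = nn.exp(nn.add(nn.add(logits, nn.constant(neg_mask)),
                          nn.mul(row_max, nn.constant(-1.0))))
        coeffs = nn.div(e, nn.tensor_sum(e, axis=1, keepdims=True))
        out = nn.relu(nn.matmul(coeffs, h))
        return out, coeffs

    def forward(self, graph: SimilarityGraph, X: nn.Tensor) -> nn.Tensor:
        out, _ = self.forward_with_coeffs(graph, X)
        return out


class LinearLayer:
    """Affine map + ReLU; the encoder replacement in the no-GSL ablation."""

    kind = "linear"

    def __init__(self, rng: np.random.Generator, dim_in: int, dim_out: int):
        self.W = nn.parameter(nn.glorot(rng, dim_in, dim_out))
        self.b = nn.parameter(np.zeros((1, dim_out)))

    def params(self) -> list[nn.Tensor]:
        return [self.W, self.b]

    def forward(self, graph: SimilarityGraph, X: nn.Tensor) -> nn.Tensor:
        return nn.relu(nn.add(nn.matmul(X, self.W), self.b))


class OmicsEncoder:
    """A stack of graph layers for one omics layer.

    ``layer_order`` is a dash-separated sequence over {gcn, gat, linear},
    default ``"gcn-gat-gcn"``.  Hidden widths map one-to-one onto layers.
    """

    def __init__(self, rng: np.random.Generator, dim_in: int,
                 hidden_dims: tuple[int, ...] = (400, 400, 200),
                 layer_order: str = "gcn-gat-gcn",
                 dropout: float = 0.5, gat_self_loop: bool = True):
        kinds = layer_order.lower().split("-")
        if len(kinds) != len(hidden_dims):
            raise ConfigError(
                f"layer_order '{layer_order}' needs {len(kinds)} hidden dims, "
                f"got {len(hidden_dims)}"
            )
        self.layer_order = layer_order
        self.dropout = dropout
        self.layers: list[GCNLayer | GATLayer | LinearLayer] = []
        d = dim_in
        for kind, h in zip(kinds, hidden_dims):
            if kind == "gcn":
                self.layers.append(GCNLayer(rng, d, h))
            elif kind == "gat":
                self.layers.append(GATLayer(rng, d, h, self_loop=gat_self_loop))
            elif kind == "linear":
                self.layers.append(LinearLayer(rng, d, h))
            else:
                raise ConfigError(f"unknown layer kind '{kind}'")
            d = h
        self.dim_out = d

    def params(self) -> list[nn.Tensor]:
        out: list[nn.Tensor] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, graph: SimilarityGraph, X: nn.Tensor,
                training: bool = False,
                rng: np.random.Generator | None = None) -> list[nn.Tensor]:
        """Run the stack; returns every layer's output (last = embedding Z)."""
        outs: list[nn.Tensor] = []
        h = X
        for layer in self.layers:
            if training and self.dropout > 0:
                h = nn.dropout(h, self.dropout, rng, training=True)
            h = layer.forward(graph, h)
            outs.append(h)
        return outs


def encode_omics(graph: SimilarityGraph, X: np.ndarray,
                 encoder: OmicsEncoder, omics_name: str = "") -> OmicsEmbedding:
    """Inference-mode pass through the encoder, all layer outputs retained."""
    outs = encoder.forward(graph, nn.constant(X), training=False)
    zs = [o.data for o in outs]
    z1 = zs[0]
    z2 = zs[1] if len(zs) > 1 else zs[-1]
    return OmicsEmbedding(z1, z2, zs[-1], omics_name)
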