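"""Cross-omics fusion by Omics-Linked Attention (OLA).

OLA is external-memory attention: instead of the N x N map of
self-attention, each sample row attends over S learnable memory slots
(U_key), and the output is reconstructed from a paired value memory
(U_val), giving an N x S attention map — linear in the number of samples.
The raw scores are normalized twice, first a softmax down each column
(over samples), then an L1 normalization across each row (over slots),
which removes sensitivity to the input scale.  Multi-head OLA splits the
concatenated feature vector into H contiguous blocks, runs one memory pair
per block, concatenates the head outputs and maps them back through an
output transform U_t.  A fully connected head on the fused features gives
the class logits.

Minimal alternative fusions (plain concatenation, standard self-attention,
and a view-correlation network over per-omics class distributions) are
provided for the module-substitution experiments.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .exceptions import ConfigError, ValidationError


def concat_omics(refined: list[nn.Tensor]) -> nn.Tensor:
    """Column-wise concatenation of the refined per-omics embeddings."""
    n_rows = {t.shape[0] for t in refined}
    if len(n_rows) != 1:
        raise ValidationError(f"row-count mismatch across omics: {sorted(n_rows)}")
    if len(refined) == 1:
        return refined[0]
    return nn.concat(refined, axis=1)


def double_normalize(A_raw: nn.Tensor) -> nn.Tensor:
    """Softmax down each column, then L1-normalize each row.

    The column softmax makes every column a distribution over the N samples;
    the row L1 step then makes every row a distribution over the S slots.
    Entries stay strictly positive, so the row sums never vanish.
    """
    col = nn.softmax_axis(A_raw, axis=0)
    return nn.div(col, nn.tensor_sum(col, axis=1, keepdims=True))


class OLAMemory:
    """Per-head key/value memories plus the output transform."""

    def __init__(self, rng: np.random.Generator, d_concat: int,
                 n_heads: int = 4, n_slots: int = 64):
        if n_heads < 1 or d_concat % n_heads != 0:
            raise ConfigError(
                f"head count {n_heads} must divide feature width {d_concat}"
            )
        self.H = n_heads
        self.S = n_slots
        self.d_head = d_concat // n_heads
        self.U_key = [nn.parameter(nn.glorot(rng, self.d_head, n_slots))
                      for _ in range(n_heads)]
        self.U_val = [nn.parameter(nn.glorot(rng, n_slots, self.d_head))
                      for _ in range(n_heads)]
        self.U_t = nn.parameter(nn.glorot(rng, d_concat, d_concat))

    def params(self) -> list[nn.Tensor]:
        return [*self.U_key, *self.U_val, self.U_t]


def ola_multihead(Z_concat: nn.Tensor, memory: OLAMemory) -> nn.Tensor:
    """Split -> per-head double-normalized memory attention -> concat -> U_t."""
    d = Z_concat.shape[1]
    if d != memory.H * memory.d_head:
        raise ConfigError(
            f"feature width {d} incompatible with {memory.H} heads of {memory.d_head}"
        )
    heads = []
    for e in range(memory.H):
        lo, hi = e * memory.d_head, (e + 1) * memory.d_head
        z_e = _slice_cols(Z_concat, lo, hi)
        A = double_normalize(nn.matmul(z_e, memory.U_key[e]))
        heads.append(nn.matmul(A, memory.U_val[e]))
    fused = heads[0] if memory.H == 1 else nn.concat(heads, axis=1)
    return nn.matmul(fused, memory.U_t)


def _slice_cols(t: nn.Tensor, lo: int, hi: int) -> nn.Tensor:
    return nn.transpose(nn.slice_rows(nn.transpose(t), lo, hi))


class ClassifierHead:
    """Fully connected map from fused features to class logits."""

    def __init__(self, rng: np.random.Generator, dim_in: int, n_classes: int):
        self.W = nn.parameter(nn.glorot(rng, dim_in, n_classes))
        self.b = nn.parameter(np.zeros((1, n_classes)))

    def params(self) -> list[nn.Tensor]:
        return [self.W, self.b]

    def forward(self, Y: nn.Tensor) -> nn.Tensor:
        return nn.add(nn.matmul(Y, self.W), self.b)


def fuse_and_classify(Y_fused: nn.Tensor, head: ClassifierHead) -> nn.Tensor:
    """Logits from the fused representation; softmax rows are the predictions."""
    return head.forward(Y_fused)


# ---------------------------------------------------------------------------
# Fusion modules with a shared interface: forward(refined list) -> logits.
# ---------------------------------------------------------------------------

class OLAFusion:
    """Default fusion: concat -> multi-head OLA -> classifier head."""

    name = "ola"

    def __init__(self, rng: np.random.Generator, dims: list[int], n_classes: int,
                 n_heads: int = 4, n_slots: int = 64, residual: bool = False):
        d_concat = sum(dims)
        self.memory = OLAMemory(rng, d_concat, n_heads=n_heads, n_slots=n_slots)
        self.head = ClassifierHead(rng, d_concat, n_classes)
        self.residual = residual

    def params(self) -> list[nn.Tensor]:
        return [*self.memory.params(), *self.head.params()]

    def forward(self, refined: list[nn.Tensor]) -> nn.Tensor:
        z = concat_omics(refined)
        y = ola_multihead(z, self.memory)
        if self.residual:
            y = nn.add(y, z)
        return fuse_and_classify(y, self.head)


class ConcatFusion:
    """No-attention baseline: concatenate and classify directly."""

    name = "concat"

    def __init__(self, rng: np.random.Generator, dims: list[int], n_classes: int):
        self.head = ClassifierHead(rng, sum(dims), n_classes)

    def params(self) -> list[nn.Tensor]:
        return self.head.params()

    def forward(self, refined: list[nn.Tensor]) -> nn.Tensor:
        return fuse_and_classify(concat_omics(refined), self.head)


class SelfAttentionFusion:
    """Standard scaled dot-product self-attention over samples (baseline)."""

    name = "self_attention"

    def __init__(self, rng: np.random.Generator, dims: list[int], n_classes: int):
        d = sum(dims)
        self.Wq = nn.parameter(nn.glorot(rng, d, d))
        self.Wk = nn.parameter(nn.glorot(rng, d, d))
        self.Wv = nn.parameter(nn.glorot(rng, d, d))
        self.head = ClassifierHead(rng, d, n_classes)
        self._scale = 1.0 / np.sqrt(d)

    def params(self) -> list[nn.Tensor]:
        return [self.Wq, self.Wk, self.Wv, *self.head.params()]

    def forward(self, refined: list[nn.Tensor]) -> nn.Tensor:
        z = concat_omics(refined)
        q, k, v = (nn.matmul(z, W) for W in (self.Wq, self.Wk, self.Wv))
        scores = nn.mul(nn.matmul(q, nn.transpose(k)), nn.constant(self._scale))
        attn = nn.softmax_axis(scores, axis=1)
        return fuse_and_classify(nn.matmul(attn, v), self.head)


class VCDNFusion:
    """View-correlation baseline: outer products of per-omics distributions."""

    name = "vcdn"

    def __init__(self, rng: np.random.Generator, dims: list[int], n_classes: int):
        self.per_view = [
            (nn.parameter(nn.glorot(rng, d, n_classes)),
             nn.parameter(np.zeros((1, n_classes))))
            for d in dims
        ]
        self.n_classes = n_classes
        self.head = ClassifierHead(rng, n_classes ** len(dims), n_classes)

    def params(self) -> list[nn.Tensor]:
        out = [w for pair in self.per_view for w in pair]
        return [*out, *self.head.params()]

    def forward(self, refined: list[nn.Tensor]) -> nn.Tensor:
        probs = [nn.softmax_axis(nn.add(nn.matmul(z, W), b), axis=1)
                 for z, (W, b) in zip(refined, self.per_view)]
        cross = probs[0]
        for p in probs[1:]:
            # Row-wise outer product, flattened: N x (Q^j) ⊗ N x Q.
            left = _repeat_cols(cross, self.n_classes)
            right = _tile_cols(p, cross.shape[1])
            cross = nn.mul(left, right)
        return fuse_and_classify(cross, self.head)


def _repeat_cols(t: nn.Tensor, times: int) -> nn.Tensor:
    """[a b] -> [a a.. b b..] (each column repeated ``times`` consecutively)."""
    cols = [_slice_cols(t, j, j + 1) for j in range(t.shape[1])]
    return nn.concat([c for col in cols for c in [col] * times], axis=1)


def _tile_cols(t: nn.Tensor, times: int) -> nn.Tensor:
    """[a b] -> [a b a b ..] (whole block tiled ``times`` times)."""
    return nn.concat([t] * times, axis=1)


FUSIONS = {
    "ola": OLAFusion,
    "concat": ConcatFusion,
    "self_attention": SelfAttentionFusion,
    "vcdn": VCDNFusion,
}
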