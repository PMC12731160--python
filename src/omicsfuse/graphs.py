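"""Patient-similarity graph construction.

Each omics layer gets its own graph: nodes are samples, pairwise similarity
is the cosine between feature vectors, and each node keeps edges to its k
most similar other samples.  The binary adjacency is then symmetrized (an
edge survives if either endpoint selected it) so the symmetric degree
normalization of the convolution layers is well defined.  Self-loops are not
stored in the adjacency; they enter only through the S + I normalization of
the GCN propagation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MultiOmicsDataset
from .exceptions import ConfigError, ValidationError


@dataclass
class SimilarityGraph:
    """Binary KNN adjacency for one omics layer, plus the (S+I) degrees."""

    adjacency: np.ndarray
    k: int
    omics_name: str
    degree: np.ndarray = field(init=False)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.degree = self.adjacency.sum(axis=1) + 1.0  # S + I degrees

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def normalized_adjacency(self) -> np.ndarray:
        """D^-1/2 (S + I) D^-1/2 with D the degree matrix of S + I."""
        s_loop = self.adjacency + np.eye(self.n_nodes)
        dinv = 1.0 / np.sqrt(self.degree)
        return dinv[:, None] * s_loop * dinv[None, :]

    def neighborhoods(self, include_self: bool = True) -> list[np.ndarray]:
        """Per-node neighbor index arrays, optionally with the node itself."""
        out = []
        for i in range(self.n_nodes):
            nb = np.flatnonzero(self.adjacency[i] > 0)
            if include_self and i not in nb:
                nb = np.sort(np.append(nb, i))
            out.append(nb)
        return out


def cosine_similarity_matrix(X: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """Pairwise cosine similarity between the rows of X.

    Raises ``ValidationError`` for a zero-norm row (cosine undefined), naming
    the offending sample when IDs are supplied.
    """
    X = np.asarray(X, dtype=np.float64)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        i = int(np.flatnonzero(norms == 0)[0])
        name = sample_ids[i] if sample_ids else f"row {i}"
        raise ValidationError(f"zero-norm feature vector for sample {name}")
    sim = (X / norms[:, None]) @ (X / norms[:, None]).T
    sim = np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return (sim + sim.T) / 2.0


def knn_adjacency(sim: np.ndarray, k: int, omics_name: str = "") -> SimilarityGraph:
    """Top-k neighbor selection per row, then symmetrization by elementwise max.

    Ties at the k-th similarity are broken toward the lower column index.
    The diagonal is never a candidate and stays zero.
    """
    sim = np.asarray(sim, dtype=np.float64)
    n = sim.shape[0]
    if not (1 <= k <= n - 1):
        raise ConfigError(f"k={k} out of range [1, {n - 1}] for {n} samples")
    masked = sim.copy()
    np.fill_diagonal(masked, -np.inf)
    adj = np.zeros((n, n))
    # Stable argsort on the negated similarities keeps the lower index first
    # among ties, giving a deterministic tie rule.
    order = np.argsort(-masked, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, :k].ravel()] = 1.0
    adj = np.maximum(adj, adj.T)
    return SimilarityGraph(adj, k, omics_name)


def build_graph(X: np.ndarray, k: int, omics_name: str = "",
                sample_ids: list[str] | None = None,
                standardize: bool = False) -> SimilarityGraph:
    """Cosine KNN graph for one omics matrix.

    ``standardize`` optionally z-scores each feature column before the
    similarity computation; the default works on the data as given.
    """
    X = np.asarray(X, dtype=np.float64)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return knn_adjacency(cosine_similarity_matrix(X, sample_ids), k, omics_name)


def build_graphs(dataset: MultiOmicsDataset, k: int | dict[str, int],
                 standardize: bool = False) -> list[SimilarityGraph]:
    """One independent similarity graph per omics layer.

    ``k`` may be a single neighbor count or a per-omics mapping.
    """
    graphs = []
    for om in dataset.omics:
        kk = k[om.omics_name] if isinstance(k, dict) else k
        graphs.append(build_graph(om.values, kk, om.omics_name,
                                  om.sample_ids, standardize=standardize))
    return graphs


def export_edge_list(graph: SimilarityGraph, sample_ids: list[str], path: str) -> None:
    """Write the undirected edges as a (source_id, target_id) TSV."""
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\n")
        src, dst = np.nonzero(np.triu(graph.adjacency))
        for i, j in zip(src, dst):
            fh.write(f"{sample_ids[i]}\t{sample_ids[j]}\n")
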