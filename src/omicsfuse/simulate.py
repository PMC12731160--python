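"""Synthetic aligned multi-omics data with planted class structure.

The generator emulates the shape of preprocessed tumor multi-omics panels
(a few hundred patients, a few hundred real-valued features per layer,
unbalanced classes) at desk scale.  Signal enters two ways:

* **informative features** — for each omics layer, a chosen subset of
  features receives a class-dependent Gaussian mean shift of
  ``effect_size * noise_sd`` along a class-specific random direction;
* **shared factors** — a low-rank latent factor matrix common to all
  layers, loaded onto the informative features, induces the cross-omics
  correlation structure that the fusion stage is meant to exploit.

Everything else is i.i.d. Gaussian noise.  The ground truth (which
features are informative, the class of each sample, the factor loadings)
is returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import LabelVector, MultiOmicsDataset, OmicsMatrix, write_dataset_dir
from .exceptions import ConfigError

DEFAULT_OMICS_NAMES = ("mrna", "meth", "mirna")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults define the standard fixture: 300 samples, 3 unbalanced classes
    (50/30/20%), three omics layers of 200/200/100 features with 20
    informative features each, a mean-shift of 1.5 noise standard
    deviations, and 5 shared cross-omics factors.
    """

    n_samples: int = 300
    n_classes: int = 3
    n_features: tuple[int, ...] = (200, 200, 100)
    n_informative: tuple[int, ...] = (20, 20, 20)
    effect_size: float = 1.5
    noise_sd: float = 1.0
    shared_factor_dim: int = 5
    factor_loading_sd: float = 1.5
    class_proportions: tuple[float, ...] = (0.5, 0.3, 0.2)
    omics_names: tuple[str, ...] = DEFAULT_OMICS_NAMES
    heavy_tail_df: float | None = None   # Student-t noise when set
    dropout_rate: float = 0.0            # zero-inflation applied after noise
    seed: int = 0

    def __post_init__(self):
        self.n_features = tuple(self.n_features)
        self.n_informative = tuple(self.n_informative)
        self.class_proportions = tuple(self.class_proportions)
        self.omics_names = tuple(self.omics_names)
        if len(self.n_informative) != len(self.n_features):
            raise ConfigError("n_informative and n_features length mismatch")
        if any(i > f for i, f in zip(self.n_informative, self.n_features)):
            raise ConfigError("n_informative exceeds n_features")
        if len(self.class_proportions) != self.n_classes:
            raise ConfigError("class_proportions length must equal n_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigError("class_proportions must sum to 1")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if len(self.omics_names) != len(self.n_features):
            raise ConfigError("omics_names and n_features length mismatch")


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated dataset."""

    informative_mask: dict[str, np.ndarray]
    class_assignment: np.ndarray
    factor_loadings: dict[str, np.ndarray]
    config: SimulationConfig = field(repr=False)

    def to_json(self, path: str) -> None:
        payload = {
            "informative_mask": {k: v.astype(int).tolist()
                                 for k, v in self.informative_mask.items()},
            "class_assignment": self.class_assignment.tolist(),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.config.__dict__.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_multiomics(cfg: SimulationConfig) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Draw one dataset; fixed seed gives bitwise-identical output."""
    rng = np.random.default_rng(cfg.seed)
    n, q = cfg.n_samples, cfg.n_classes

    # Class assignment: exact proportions up to rounding, then shuffled.
    counts = np.floor(np.asarray(cfg.class_proportions) * n).astype(int)
    counts[: n - counts.sum()] += 1
    classes = np.repeat(np.arange(q), counts)
    rng.shuffle(classes)

    factors = rng.standard_normal((n, cfg.shared_factor_dim)) \
        if cfg.shared_factor_dim > 0 else None

    sample_ids = [f"s{i:04d}" for i in range(n)]
    matrices = []
    masks: dict[str, np.ndarray] = {}
    loadings: dict[str, np.ndarray] = {}
    for name, d, d_inf in zip(cfg.omics_names, cfg.n_features, cfg.n_informative):
        mask = np.zeros(d, dtype=bool)
        mask[rng.choice(d, size=d_inf, replace=False)] = True
        # Each informative feature gets class-level means spaced exactly
        # effect_size * noise_sd apart (a random permutation of centered
        # class scores per feature), so any two classes differ by at least
        # one effect_size on every informative feature while the shift
        # directions still vary across features.
        scores = np.arange(q, dtype=np.float64) - (q - 1) / 2.0
        dirs = np.column_stack([rng.permutation(scores) for _ in range(d_inf)])
        X = _noise(rng, (n, d), cfg) * cfg.noise_sd
        X[:, mask] += cfg.effect_size * cfg.noise_sd * dirs[classes]
        if factors is not None:
            # Loading sd defaults to 1.5 * noise_sd: the factor (nuisance)
            # variance per informative feature is then about an order of
            # magnitude above the white noise, so structured variation --
            # latent programs, batch -- dominates any single gene's class
            # signal, as in real tumor panels.
            load = rng.standard_normal((cfg.shared_factor_dim, d_inf)) \
                * cfg.factor_loading_sd * cfg.noise_sd
            X[:, mask] += factors @ load
            loadings[name] = load
        else:
            loadings[name] = np.zeros((0, d_inf))
        if cfg.dropout_rate > 0:
            X[rng.random((n, d)) < cfg.dropout_rate] = 0.0
        masks[name] = mask
        matrices.append(OmicsMatrix(
            name, list(sample_ids),
            [f"{name}_f{j:04d}" for j in range(d)], X,
        ))

    labels = LabelVector(list(sample_ids), classes,
                         [f"class_{c}" for c in range(q)])
    dataset = MultiOmicsDataset(matrices, labels)
    truth = SyntheticTruth(masks, classes.copy(), loadings, cfg)
    return dataset, truth


def _noise(rng: np.random.Generator, shape: tuple[int, int],
           cfg: SimulationConfig) -> np.ndarray:
    if cfg.heavy_tail_df is not None:
        df = cfg.heavy_tail_df
        t = rng.standard_t(df, size=shape)
        return t / np.sqrt(df / (df - 2.0))  # unit variance
    return rng.standard_normal(shape)


def default_fixture(seed: int = 0) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """The standard synthetic fixture used across the test protocol."""
    return simulate_multiomics(SimulationConfig(seed=seed))


def write_simulation(cfg: SimulationConfig, out_dir: str) -> None:
    """Materialize the dataset directory layout plus truth.json."""
    import os

    dataset, truth = simulate_multiomics(cfg)
    write_dataset_dir(dataset, out_dir)
    truth.to_json(os.path.join(out_dir, "truth.json"))
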