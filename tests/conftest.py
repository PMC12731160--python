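import numpy as np
import pytest

from omicsfuse.data_io import LabelVector, MultiOmicsDataset, OmicsMatrix
from omicsfuse.simulate import SimulationConfig, simulate_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """60 samples, 2 omics, 2 classes, clearly separable; fast to fit."""
    cfg = SimulationConfig(
        n_samples=60, n_classes=2, n_features=(30, 20),
        n_informative=(5, 5), effect_size=2.5, shared_factor_dim=2,
        class_proportions=(0.5, 0.5), omics_names=("omA", "omB"), seed=7,
    )
    dataset, truth = simulate_multiomics(cfg)
    return dataset, truth


def make_matrix(rng, name="om", n=6, d=4):
    return OmicsMatrix(
        name,
        [f"s{i}" for i in range(n)],
        [f"f{j}" for j in range(d)],
        rng.standard_normal((n, d)),
    )


@pytest.fixture
def toy_multiomics(rng):
    """3 omics x 8 samples with deterministic labels, for plumbing tests."""
    n = 8
    mats = [make_matrix(rng, f"om{m}", n=n, d=5 + m) for m in range(3)]
    labels = LabelVector([f"s{i}" for i in range(n)],
                         np.array([0, 1, 0, 1, 0, 1, 0, 1]),
                         ["ctrl", "case"])
    return MultiOmicsDataset(mats, labels)
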