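import numpy as np
import pytest

from connectogin import FCMatrix, ModelConfig, SimConfig, build_graph, make_fc_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_fc(rng: np.random.Generator, n: int, subject_id: str = "s") -> FCMatrix:
    """A random symmetric zero-diagonal Fisher-z matrix for tests."""
    z = rng.standard_normal((n, n)) * 0.4
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id=subject_id, z=z)


def random_adjacency(rng: np.random.Generator, n: int, density: float = 0.4,
                     signed: bool = False) -> np.ndarray:
    """A random symmetric weighted adjacency with zero diagonal."""
    w = rng.random((n, n))
    if signed:
        w = w - 0.5
    mask = rng.random((n, n)) < density
    a = np.tril(w * mask, -1)
    return a + a.T


@pytest.fixture
def small_model_config():
    return ModelConfig(input_dim=6, n_layers=2, hidden_dim=5,
                       dropout_rate=0.0, dtype="float64")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, strongly separable cohort used across training tests."""
    cfg = SimConfig(n_subjects_per_group=15, n_rois=24, n_timepoints=120,
                    planted_rois=tuple(range(1, 7)), delta=0.35, seed=99)
    fcs, truth = make_fc_cohort(cfg)
    graphs = [build_graph(fc, label) for fc, label in fcs]
    return graphs, truth, cfg
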