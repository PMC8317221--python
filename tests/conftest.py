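import numpy as np
import pytest

from eegfbn.cohort import CouplingSpec, VARGroundTruth, make_var_model


@pytest.fixture(scope="session")
def bivariate_model() -> VARGroundTruth:
    """VAR(1) with a11 = a22 = 0.5, a21 = 0.5, a12 = 0: the unidirectional
    two-channel model whose PDC/DTF at f = 0 are known in closed form."""
    spec = CouplingSpec(
        density=0.0,
        edges=((0, 1, 0.5),),
        self_range=(0.5, 0.5),
        allow_negative=False,
    )
    return make_var_model(2, 1, spec, seed=0, sampling_rate=128.0)


@pytest.fixture
def random_graph_weights():
    """Factory for random 8-node directed weight matrices (zero diagonal)."""

    def make(seed: int, n: int = 8, density: float = 0.5) -> np.ndarray:
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 1.0, size=(n, n))
        w *= rng.random((n, n)) < density
        np.fill_diagonal(w, 0.0)
        return w

    return make
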