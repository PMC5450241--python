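import numpy as np
import pandas as pd
import pytest

from craniodev.normalize import NormalizationFactors
from craniodev.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 4x4x4 study, 400 genes, planted effects at |log2FC| = 1."""
    cfg = SimulationConfig(
        n_genes=400, de_fraction=0.1, effect_size_log2=1.0, seed=7
    )
    counts, samples, truth = simulate_experiment(cfg)
    return cfg, counts, samples, truth


@pytest.fixture()
def nb_matrix():
    """Plain NB matrix, no group structure: 200 genes x 8 samples."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4.0, 1.2, 200)
    lam = rng.gamma(10.0, mu[:, None] / 10.0, (200, 8))
    y = rng.poisson(lam)
    return pd.DataFrame(
        y,
        index=[f"g{i:03d}" for i in range(200)],
        columns=[f"s{j}" for j in range(8)],
    )


def unit_factors(counts: pd.DataFrame) -> NormalizationFactors:
    return NormalizationFactors.unit(counts)
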