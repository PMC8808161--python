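import numpy as np
import pandas as pd
import pytest

from sepstrat import SimConfig, generate_cohort, normalize_log2, size_factors


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A scaled-down cohort for fast unit tests: same structure, fewer genes
    and samples, same planted-effect strengths."""
    base = dict(
        n_er_discovery=80,
        n_er_validation=40,
        n_icu=30,
        n_healthy=15,
        n_genes=2000,
        markers_per_endotype=60,
        n_severity_genes=60,
        n_mortality_genes=40,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the generator's default study conditions."""
    counts, meta, truth = generate_cohort(SimConfig(seed=11))
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_cohort():
    counts, meta, truth = generate_cohort(small_config())
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    counts, meta, truth = small_cohort
    factors = size_factors(counts)
    return normalize_log2(counts, factors), factors


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_counts(rng, n_genes=50, n_samples=6, mean=20.0):
    k = rng.poisson(mean, size=(n_genes, n_samples))
    return pd.DataFrame(
        k,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
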