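import numpy as np
import pytest

from metabopls import (
    BucketGrid,
    BucketTable,
    SimConfig,
    build_bucket_table,
    normalize_constant_sum,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_grid():
    return BucketGrid()


@pytest.fixture(scope="session")
def example_cohort_table(default_grid):
    """Default 12-vs-11 simulated cohort, bucketed and normalized."""
    spectra, truth = simulate_cohort(SimConfig(seed=42))
    table = normalize_constant_sum(build_bucket_table(spectra, default_grid))
    return table, truth


@pytest.fixture(scope="session")
def null_cohort_table(default_grid):
    """12-vs-11 cohort with no planted effects."""
    spectra, truth = simulate_cohort(SimConfig(planted_fold_changes={}, seed=7))
    table = normalize_constant_sum(build_bucket_table(spectra, default_grid))
    return table, truth


@pytest.fixture
def tiny_table():
    """3-vs-3 single-bin table carrying the textbook pooled-t example."""
    values = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
    return BucketTable(
        sample_ids=[f"s{i}" for i in range(6)],
        groups=["treated"] * 3 + ["control"] * 3,
        bin_centers_ppm=np.array([1.005]),
        matrix=values,
        normalized=True,
    )


def make_separated_table(n_per_class=8, p=40, gap=6.0, seed=0, noise=0.05):
    """Two essentially noise-free, widely separated classes."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=noise, size=(2 * n_per_class, p))
    X[:n_per_class, : p // 2] += gap
    return BucketTable(
        sample_ids=[f"s{i}" for i in range(2 * n_per_class)],
        groups=["treated"] * n_per_class + ["control"] * n_per_class,
        bin_centers_ppm=np.linspace(4.0, 1.0, p),
        matrix=X - X.min() + 0.1,
        normalized=True,
    )
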