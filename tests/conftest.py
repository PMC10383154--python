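import numpy as np
import pytest

from pgxstrat.classify import ClassifierSpec
from pgxstrat.containers import GroupLabelSet
from pgxstrat.simulate import (
    GroupSpec,
    SimulationConfig,
    simulate_genotypes,
    simulate_group_frequencies,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Three moderately diverged groups, 120 variants, 10 planted divergent."""
    config = SimulationConfig(
        n_variants=120,
        n_divergent=10,
        groups=[
            GroupSpec("popA", 120, 0.05),
            GroupSpec("popB", 100, 0.05),
            GroupSpec("popC", 80, 0.05),
        ],
        divergent_delta=0.5,
        seed=11,
    )
    truth = simulate_group_frequencies(config)
    genotypes, labels = simulate_genotypes(truth, config)
    return config, truth, genotypes, labels


@pytest.fixture(scope="session")
def separable_clusters():
    """Two tight point clouds at PC coordinates -5 and +5 (sd 0.1)."""
    rng = np.random.default_rng(42)
    n = 60
    scores = np.vstack(
        [rng.normal(-5, 0.1, (n, 5)), rng.normal(5, 0.1, (n, 5))]
    )
    samples = [f"s{i:03d}" for i in range(2 * n)]
    labels = GroupLabelSet(
        labels={s: ("left" if i < n else "right") for i, s in enumerate(samples)}
    )
    return scores, samples, labels


@pytest.fixture
def fast_spec():
    return ClassifierSpec(method="knn", n_search_draws=5, seed=0)
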