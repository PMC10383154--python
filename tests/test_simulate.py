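import numpy as np
import pytest

from pgxstrat.containers import VariantRecord
from pgxstrat.simulate import (
    AdmixedGroupSpec,
    GroundTruth,
    GroupSpec,
    SimulationConfig,
    default_cohort_config,
    hudson_fst,
    simulate_genotypes,
    simulate_group_frequencies,
    synthetic_annotation,
)


def _two_group_config(**kwargs):
    defaults = dict(
        n_variants=200,
        n_divergent=0,
        groups=[GroupSpec("a", 50, 0.1), GroupSpec("b", 50, 0.1)],
        seed=1,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def test_seed_determinism():
    config = _two_group_config()
    t1 = simulate_group_frequencies(config)
    t2 = simulate_group_frequencies(config)
    np.testing.assert_array_equal(t1.frequencies, t2.frequencies)
    g1, _ = simulate_genotypes(t1, config)
    g2, _ = simulate_genotypes(t2, config)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)

    other = _two_group_config(seed=2)
    g3, _ = simulate_genotypes(simulate_group_frequencies(other), other)
    assert not np.array_equal(g1.dosages, g3.dosages)


def test_zero_divergence_limit():
    """As F -> 0 the group frequencies collapse onto the ancestral ones."""
    config = SimulationConfig(
        n_variants=1000,
        n_divergent=0,
        groups=[GroupSpec(n, 10, 1e-4) for n in ("a", "b", "c")],
        seed=0,
    )
    truth = simulate_group_frequencies(config)
    deviation = np.abs(truth.frequencies - truth.ancestral_frequencies)
    assert deviation.max() < 0.02


def test_planted_variants_reach_divergence_delta():
    config = _two_group_config(n_divergent=20, divergent_delta=0.5)
    truth = simulate_group_frequencies(config)
    assert len(truth.divergent_variant_ids) == 20
    ids = [v.id for v in truth.variants]
    for vid in truth.divergent_variant_ids:
        j = ids.index(vid)
        col = truth.frequencies[:, j]
        assert col.max() - col.min() >= 0.5


def test_fixed_frequency_gives_fixed_genotypes():
    """A group at frequency 1.0 yields dosage 2 for every sample."""
    config = _two_group_config(n_variants=1)
    truth = GroundTruth(
        variants=[VariantRecord("chr1", 100, "A", "G", rsid="rs1")],
        group_names=["a", "b"],
        frequencies=np.array([[1.0], [0.0]]),
        divergent_variant_ids=set(),
        admixed_proportions={},
    )
    genotypes, labels = simulate_genotypes(truth, config)
    in_a = [i for i, s in enumerate(genotypes.samples) if labels.labels[s] == "a"]
    in_b = [i for i, s in enumerate(genotypes.samples) if labels.labels[s] == "b"]
    assert (genotypes.dosages[in_a, 0] == 2).all()
    assert (genotypes.dosages[in_b, 0] == 0).all()


def test_group_frequencies_within_binomial_error():
    config = SimulationConfig(
        n_variants=1,
        n_divergent=0,
        groups=[GroupSpec("a", 500, 0.1), GroupSpec("b", 500, 0.1)],
        seed=3,
    )
    truth = GroundTruth(
        variants=[VariantRecord("chr1", 100, "A", "G", rsid="rs1")],
        group_names=["a", "b"],
        frequencies=np.array([[0.2], [0.8]]),
        divergent_variant_ids=set(),
        admixed_proportions={},
    )
    genotypes, labels = simulate_genotypes(truth, config)
    for name, p in (("a", 0.2), ("b", 0.8)):
        idx = [i for i, s in enumerate(genotypes.samples)
               if labels.labels[s] == name]
        freq = genotypes.dosages[idx, 0].mean() / 2
        se = np.sqrt(p * (1 - p) / (2 * 500))
        assert abs(freq - p) <= 3 * se


def test_admixed_mixture_expectation():
    """50/50 ancestry over p=0 and p=1 parents gives mean dosage ~1."""
    n = 2000
    config = SimulationConfig(
        n_variants=1,
        n_divergent=0,
        groups=[GroupSpec("a", 1, 0.1), GroupSpec("b", 1, 0.1)],
        admixed_groups=[AdmixedGroupSpec("mix", n, (1.0, 1.0))],
        seed=4,
    )
    truth = GroundTruth(
        variants=[VariantRecord("chr1", 100, "A", "G", rsid="rs1")],
        group_names=["a", "b"],
        frequencies=np.array([[0.0], [1.0]]),
        divergent_variant_ids=set(),
        admixed_proportions={"mix": np.full((n, 2), 0.5)},
    )
    genotypes, labels = simulate_genotypes(truth, config)
    idx = [i for i, s in enumerate(genotypes.samples) if labels.labels[s] == "mix"]
    mean_dosage = genotypes.dosages[idx, 0].mean()
    se = np.sqrt(0.5 / n)  # Var[Binomial(2, 0.5)] = 0.5
    assert abs(mean_dosage - 1.0) <= 3 * se


def test_fst_calibration_short():
    config = SimulationConfig(
        n_variants=2000,
        n_divergent=0,
        groups=[GroupSpec("a", 10, 0.1), GroupSpec("b", 10, 0.1)],
        seed=0,
    )
    truth = simulate_group_frequencies(config)
    fst = hudson_fst(truth.frequencies[0], truth.frequencies[1])
    assert fst == pytest.approx(0.1, abs=0.03)


def test_synthetic_annotation_marks_planted_variants():
    config = _two_group_config(n_divergent=10, divergent_delta=0.5)
    truth = simulate_group_frequencies(config)
    annotation = synthetic_annotation(truth)
    tox = annotation[annotation["association_type"] == "toxicity"]
    assert set(tox["variant_id"]) == truth.divergent_variant_ids
    assert set(tox["mode_of_effect"]) == {"dominant", "recessive"}
    rest = annotation[annotation["association_type"] != "toxicity"]
    assert (rest["mode_of_effect"] == "unknown").all()


def test_default_cohort_structure():
    config = default_cohort_config(scale=0.1)
    assert len(config.groups) == 4
    assert len(config.admixed_groups) == 1
    sizes = [g.size for g in config.groups]
    assert max(sizes) > 5 * min(sizes)  # deliberately unbalanced


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(groups=[GroupSpec("a", 5, 0.1)], n_variants=0),
        dict(groups=[GroupSpec("a", 5, 0.1)], n_variants=10, n_divergent=11),
        dict(groups=[GroupSpec("a", 5, 0.1)], divergent_delta=1.0),
        dict(groups=[GroupSpec("a", 5, 0.1)], ancestral_freq_range=(0.0, 0.9)),
        dict(groups=[]),
    ],
)
def test_config_validation(kwargs):
    defaults = dict(n_variants=10, n_divergent=0, seed=0)
    defaults.update(kwargs)
    with pytest.raises(ValueError):
        SimulationConfig(**defaults)


def test_group_spec_rejects_bad_fst():
    with pytest.raises(ValueError):
        GroupSpec("a", 5, 0.0)
    with pytest.raises(ValueError):
        GroupSpec("a", 5, 1.0)
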