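import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from pgxstrat.containers import GenotypeMatrix, VariantRecord
from pgxstrat.pca import PCAModel, fit_pca, rank_divergent
from pgxstrat.simulate import (
    GroupSpec,
    SimulationConfig,
    simulate_genotypes,
    simulate_group_frequencies,
)


def _random_matrix(n_samples, n_variants, seed):
    rng = np.random.default_rng(seed)
    # polymorphic by construction: keep redrawing constant columns
    dosages = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
    for j in range(n_variants):
        while len(np.unique(dosages[:, j])) == 1:
            dosages[:, j] = rng.integers(0, 3, size=n_samples)
    variants = [
        VariantRecord("chr1", 100 + j, "A", "G", rsid=f"rs{j}")
        for j in range(n_variants)
    ]
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _oracle_standardize(dosages):
    mean = dosages.mean(axis=0)
    p = mean / 2.0
    return (dosages - mean) / np.sqrt(2 * p * (1 - p))


def _oracle_eigen(dosages, k):
    """Independent full eigendecomposition of the standardized Gram matrix."""
    Xs = _oracle_standardize(dosages)
    evals, evecs = np.linalg.eigh(Xs.T @ Xs)
    order = np.argsort(evals)[::-1][:k]
    weights = evecs[:, order]
    scores = Xs @ weights
    return scores, weights


@pytest.mark.parametrize("shape", [(30, 20), (60, 100), (100, 100)])
def test_matches_full_eigendecomposition(shape):
    """Truncated fit equals a brute-force eigendecomposition up to sign."""
    matrix = _random_matrix(*shape, seed=shape[0])
    k = 5
    model = fit_pca(matrix, n_pcs=k)
    scores, weights = _oracle_eigen(matrix.dosages, k)
    for i in range(k):
        sign = np.sign(np.dot(weights[:, i], model.weights[:, i]))
        np.testing.assert_allclose(model.weights[:, i], sign * weights[:, i],
                                   atol=1e-6)
        np.testing.assert_allclose(model.scores[:, i], sign * scores[:, i],
                                   atol=1e-6)


def test_reconstruction_identity(small_cohort):
    """PC_i = sum_j weight_ij * standardized dosage_ij on a fitted model."""
    _, _, genotypes, _ = small_cohort
    model = fit_pca(genotypes, n_pcs=6)
    Xs = model.standardized(genotypes)
    np.testing.assert_allclose(Xs @ model.weights, model.scores,
                               atol=1e-6 * np.abs(model.scores).max())


def test_scores_orthogonal(small_cohort):
    _, _, genotypes, _ = small_cohort
    model = fit_pca(genotypes, n_pcs=6)
    corr = np.corrcoef(model.scores, rowvar=False)
    off = corr - np.diag(np.diag(corr))
    assert np.abs(off).max() < 1e-6


def test_explained_variance_shares_monotone(small_cohort):
    _, _, genotypes, _ = small_cohort
    model = fit_pca(genotypes, n_pcs=6)
    evr = model.explained_variance_ratio
    assert np.all(evr[:-1] >= evr[1:] - 1e-12)
    assert np.all((evr >= 0) & (evr <= 1))


def test_two_point_rank_one_structure():
    """Opposite fixed genotypes with a jitter sample: PC1 captures ~all variance."""
    n = 10
    dosages = np.vstack([np.zeros((n, 8)), np.full((n, 8), 2.0)])
    dosages[0, 0] = 1  # break exact monomorphism of the split
    variants = [VariantRecord("chr1", 1 + j, "A", "G") for j in range(8)]
    matrix = GenotypeMatrix(
        samples=[f"s{i}" for i in range(2 * n)], variants=variants,
        dosages=dosages,
    )
    model = fit_pca(matrix, n_pcs=2)
    assert model.explained_variance_ratio[0] > 0.98
    # two groups land on two well-separated PC1 values
    left, right = model.scores[:n, 0], model.scores[n:, 0]
    assert abs(left.mean() - right.mean()) > 5 * (left.std() + right.std() + 1e-9)


def test_monomorphic_variants_dropped():
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(20, 6)).astype(float)
    dosages[:, 2] = 1.0
    variants = [VariantRecord("chr1", 1 + j, "A", "G") for j in range(6)]
    matrix = GenotypeMatrix(samples=[f"s{i}" for i in range(20)],
                            variants=variants, dosages=dosages)
    model = fit_pca(matrix, n_pcs=3)
    assert model.n_dropped_monomorphic == 1
    assert len(model.variants) == 5


def test_missing_dosages_mean_imputed():
    matrix = _random_matrix(30, 10, seed=9)
    holey = GenotypeMatrix(
        samples=matrix.samples, variants=matrix.variants,
        dosages=matrix.dosages.copy(),
    )
    holey.dosages[0, 0] = np.nan
    model = fit_pca(holey, n_pcs=3)  # must not raise; reconstruction holds
    Xs = model.standardized(holey)
    np.testing.assert_allclose(Xs @ model.weights, model.scores, atol=1e-8)


def test_sign_convention_largest_weight_positive(small_cohort):
    _, _, genotypes, _ = small_cohort
    model = fit_pca(genotypes, n_pcs=4)
    for k in range(model.n_pcs):
        j = np.abs(model.weights[:, k]).argmax()
        assert model.weights[j, k] > 0


def _toy_model(weight_rows):
    weights = np.array(weight_rows, dtype=float)
    n_variants, k = weights.shape
    variants = [VariantRecord("chr1", 1 + j, "A", "G", rsid=f"rs{j}")
                for j in range(n_variants)]
    return PCAModel(
        samples=["s"], variants=variants,
        scores=np.zeros((1, k)), weights=weights,
        mean=np.zeros(n_variants), scale=np.ones(n_variants),
        explained_variance_ratio=np.linspace(0.5, 0.1, k),
    )


def test_rank_divergent_dominance():
    model = _toy_model([[3.0, 0.1], [0.2, 0.4]])
    ranked = rank_divergent(model)
    assert ranked["variant_id"].tolist() == ["chr1:1:A:G", "chr1:2:A:G"]
    assert ranked["divergence_score"].tolist() == [3.0, 0.4]


def test_rank_divergent_tie_preserves_input_order():
    model = _toy_model([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
    ranked = rank_divergent(model, pcs=(1,))
    assert ranked["variant_id"].tolist() == [f"chr1:{j + 1}:A:G" for j in range(3)]


def test_rank_divergent_validates_pcs():
    model = _toy_model([[1.0, 0.0]])
    with pytest.raises(ValueError):
        rank_divergent(model, pcs=())
    with pytest.raises(ValueError):
        rank_divergent(model, pcs=(3,))


def test_rank_divergent_joins_annotation():
    model = _toy_model([[2.0, 0.0], [1.0, 0.0]])
    annotation = pd.DataFrame(
        {
            "variant_id": ["chr1:1:A:G"],
            "rsid": ["rs0"],
            "gene": ["GENE1"],
            "drugs": ["drugX"],
            "evidence_level": ["1A"],
            "association_type": ["toxicity"],
            "mode_of_effect": ["dominant"],
            "effect_allele": ["G"],
        }
    )
    ranked = rank_divergent(model, annotation=annotation)
    assert ranked.loc[0, "gene"] == "GENE1"
    assert pd.isna(ranked.loc[1, "gene"])


def test_recovery_improves_with_planted_divergence():
    """Mean rank of planted variants falls as the planted gap grows."""
    deltas = [0.2, 0.4, 0.6, 0.8]
    mean_ranks = []
    for delta in deltas:
        config = SimulationConfig(
            n_variants=220, n_divergent=20,
            groups=[GroupSpec("a", 200, 0.05), GroupSpec("b", 200, 0.05)],
            divergent_delta=delta, seed=7,
        )
        truth = simulate_group_frequencies(config)
        genotypes, _ = simulate_genotypes(truth, config)
        ranked = rank_divergent(fit_pca(genotypes, n_pcs=3))
        planted = ranked["variant_id"].isin(truth.divergent_variant_ids)
        mean_ranks.append(float(ranked.loc[planted, "rank"].mean()))
    rho = spearmanr(deltas, mean_ranks).statistic
    assert rho < -0.8
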