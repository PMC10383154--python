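"""Genotype PCA with per-variant allele weights and divergence ranking.

Dosages are standardized per variant with the EIGENSTRAT/PLINK
convention: mean-centered and scaled by sqrt(2 p (1 - p)), with p the
alternate-allele frequency estimated from called genotypes and missing
dosages mean-imputed after that estimate. The principal-component score
of sample i on PC k is the weighted sum of its standardized dosages,

    PC_ik = sum_j AlleleWeight_jk * x_ij ,

so the allele weight of a variant measures how strongly it drives
between-sample divergence along that PC. The decomposition is an exact
SVD for cohorts up to ``exact_threshold`` samples and a seeded randomized
truncated SVD above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .containers import GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    samples: list[str]
    variants: list[VariantRecord]
    scores: np.ndarray            # (n_samples, n_pcs)
    weights: np.ndarray           # (n_variants, n_pcs)
    mean: np.ndarray              # per-variant dosage mean
    scale: np.ndarray             # per-variant sqrt(2 p (1-p))
    explained_variance_ratio: np.ndarray
    n_dropped_monomorphic: int = 0

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]

    def standardized(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Standardize a dosage matrix with this model's parameters."""
        index = {v.id: j for j, v in enumerate(matrix.variants)}
        try:
            cols = [index[v.id] for v in self.variants]
        except KeyError as exc:
            raise ValueError(f"matrix lacks fitted variant {exc}") from exc
        X = matrix.dosages[:, cols].copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            col[~np.isfinite(col)] = self.mean[j]
        return (X - self.mean) / self.scale

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.n_pcs)}
        return pd.DataFrame({"sample_id": self.samples, **cols})

    def weights_frame(self) -> pd.DataFrame:
        cols = {f"weight_PC{k + 1}": self.weights[:, k] for k in range(self.n_pcs)}
        return pd.DataFrame(
            {
                "variant_id": [v.id for v in self.variants],
                "rsid": [v.rsid for v in self.variants],
                **cols,
            }
        )


def fit_pca(
    genotypes: GenotypeMatrix,
    n_pcs: int = 25,
    seed: int = 0,
    exact_threshold: int = 2000,
) -> PCAModel:
    """Fit a truncated genotype PCA.

    Monomorphic variants (zero variance after imputation) are dropped
    with a logged count. The sign of each PC is fixed so that its
    largest-magnitude allele weight is positive, making results
    reproducible across solvers (PC signs are otherwise arbitrary).
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if genotypes.n_samples < n_pcs + 1:
        raise ValueError(
            f"need at least n_pcs+1={n_pcs + 1} samples, got {genotypes.n_samples}"
        )
    X = genotypes.dosages.copy()
    n_called = np.isfinite(X).sum(axis=0)
    if np.any(n_called == 0):
        raise ValueError("variants with no called genotypes cannot be standardized")
    mean = np.nanmean(X, axis=0)
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))

    keep = np.nanvar(X, axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic variants before PCA", n_dropped)
    if keep.sum() < n_pcs:
        raise ValueError(
            f"only {int(keep.sum())} usable variants for {n_pcs} PCs"
        )
    variants = [v for v, k in zip(genotypes.variants, keep) if k]
    X = X[:, keep]
    mean, scale = mean[keep], scale[keep]

    inds = np.where(~np.isfinite(X))
    X[inds] = mean[inds[1]]
    Xs = (X - mean) / scale

    total_var = float(np.sum(Xs**2))
    if genotypes.n_samples <= exact_threshold:
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    else:
        U, s, Vt = randomized_svd(
            Xs, n_components=n_pcs, n_iter=7, random_state=seed
        )
    weights = Vt.T                      # (n_variants, n_pcs)
    scores = U * s                      # == Xs @ weights
    flip = weights[np.abs(weights).argmax(axis=0), np.arange(weights.shape[1])] < 0
    weights[:, flip] *= -1
    scores[:, flip] *= -1
    evr = s**2 / total_var

    return PCAModel(
        samples=list(genotypes.samples),
        variants=variants,
        scores=scores,
        weights=weights,
        mean=mean,
        scale=scale,
        explained_variance_ratio=evr,
        n_dropped_monomorphic=n_dropped,
    )


def rank_divergent(
    model: PCAModel,
    annotation: pd.DataFrame | None = None,
    pcs: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Rank variants by allele-weight magnitude over the selected PCs.

    The divergence score of a variant is the maximum |allele weight| over
    the selected PCs (1-based); per-PC weights are also reported so other
    combining rules remain recoverable. The sort is descending and
    stable, preserving input order among ties. Annotation columns are
    joined by rsID first, positional id as fallback.
    """
    if not pcs:
        raise ValueError("at least one PC must be selected")
    bad = [k for k in pcs if not (1 <= k <= model.n_pcs)]
    if bad:
        raise ValueError(f"PCs {bad} outside fitted range 1..{model.n_pcs}")
    df = model.weights_frame()
    sel = np.abs(model.weights[:, [k - 1 for k in pcs]])
    df["divergence_score"] = sel.max(axis=1)
    df = df.sort_values("divergence_score", ascending=False, kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if annotation is not None:
        ann = annotation.drop_duplicates("rsid")
        joined = df.merge(
            ann.drop(columns=["variant_id"]), on="rsid", how="left"
        )
        # positional fallback for rows without an rsID match
        unmatched = joined["gene"].isna()
        if unmatched.any():
            by_id = annotation.drop_duplicates("variant_id").set_index("variant_id")
            for i in joined.index[unmatched]:
                vid = joined.at[i, "variant_id"]
                if vid in by_id.index:
                    for col in by_id.columns:
                        if col != "rsid":
                            joined.at[i, col] = by_id.at[vid, col]
        df = joined
    return df.reset_index(drop=True)
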