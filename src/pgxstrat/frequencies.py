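"""Per-group alternate-allele frequencies and Hardy-Weinberg fractions.

Frequencies are computed from called alleles only: for each (variant,
group) cell the frequency is the dosage sum over non-missing calls divided
by twice the number of non-missing calls. A cell with no called genotypes
is flagged (``n_called == 0``, frequency NaN) rather than imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GroupLabelSet

logger = logging.getLogger(__name__)


def group_allele_frequencies(
    genotypes: GenotypeMatrix, labels: GroupLabelSet
) -> pd.DataFrame:
    """Alternate-allele frequency per (variant, group).

    Returns a DataFrame with columns variant_id, rsid, group, allele
    (the alternate allele whose frequency is reported), freq, n_called.
    Samples without a label are excluded with a logged count.
    """
    labeled = [s for s in genotypes.samples if s in labels.labels]
    n_unlabeled = genotypes.n_samples - len(labeled)
    if n_unlabeled:
        logger.info("excluding %d unlabeled samples", n_unlabeled)
    if not labeled:
        raise ValueError("no labeled samples in genotype matrix")
    index = {s: i for i, s in enumerate(genotypes.samples)}
    rows = []
    for group in labels.groups():
        members = [index[s] for s in labeled if labels.labels[s] == group]
        if not members:
            continue
        sub = genotypes.dosages[members, :]
        called = np.isfinite(sub)
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.nansum(sub, axis=0) / (2.0 * n_called)
        freq[n_called == 0] = np.nan
        for j, v in enumerate(genotypes.variants):
            rows.append(
                {
                    "variant_id": v.id,
                    "rsid": v.rsid,
                    "group": group,
                    "allele": v.alt,
                    "freq": freq[j],
                    "n_called": int(n_called[j]),
                }
            )
    return pd.DataFrame(rows)


def hw_fractions(p):
    """Hardy-Weinberg genotype fractions for effect-allele frequency ``p``.

    Returns ``(hom, het, other)`` = (p^2, 2p(1-p), (1-p)^2); accepts a
    scalar or array. ``hom + het + other == 1`` identically.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    hom = p**2
    het = 2 * p * (1 - p)
    other = (1 - p) ** 2
    if p.ndim == 0:
        return float(hom), float(het), float(other)
    return hom, het, other


def pooled_frequency(freqs: pd.DataFrame) -> pd.Series:
    """Sample-size-weighted pooled frequency per variant across groups."""
    def _pool(sub: pd.DataFrame) -> float:
        w = sub["n_called"].to_numpy(dtype=float)
        f = sub["freq"].to_numpy(dtype=float)
        mask = np.isfinite(f) & (w > 0)
        if not mask.any():
            return np.nan
        return float(np.sum(w[mask] * f[mask]) / np.sum(w[mask]))

    return freqs.groupby("variant_id", sort=False).apply(_pool, include_groups=False)
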