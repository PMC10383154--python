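"""Predicted excess adverse drug reactions between groups.

For a toxicity-associated variant with effect-allele frequencies p_a and
p_b in two groups, the expected excess number of adverse reactions per
1000 treated patients in group a relative to group b is, under
Hardy-Weinberg genotype fractions,

    recessive (two effect alleles needed):
        1000 * (p_a^2 - p_b^2)
    dominant (one or two effect alleles needed):
        1000 * [(p_a^2 - p_b^2) + (2 p_a (1 - p_a) - 2 p_b (1 - p_b))]

The dominant form is algebraically the carrier-frequency difference,
1000 * [(1 - (1 - p_a)^2) - (1 - (1 - p_b)^2)]. Values are kept signed
internally (antisymmetric in the two groups); reports carry both the
continuous value and a rounded integer magnitude with the direction of
excess spelled out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("dominant", "recessive")


def excess_adr(p_a: float, p_b: float, mode: str) -> float:
    """Signed excess adverse reactions per 1000 treated, group a vs b.

    Positive values mean more reactions expected in group a. Accepts
    scalars or arrays; frequencies must lie in [0, 1].
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if np.any((p_a < 0) | (p_a > 1)) or np.any((p_b < 0) | (p_b > 1)):
        raise ValueError("effect-allele frequencies must lie in [0, 1]")
    if mode == "recessive":
        out = 1000.0 * (p_a**2 - p_b**2)
    else:
        out = 1000.0 * (
            (p_a**2 - p_b**2) + (2 * p_a * (1 - p_a) - 2 * p_b * (1 - p_b))
        )
    return float(out) if out.ndim == 0 else out


def reported_magnitude(excess: float) -> int:
    """Integer magnitude for reporting: round half away from zero."""
    return int(math.floor(abs(excess) + 0.5))


@dataclass(frozen=True)
class ADRPrediction:
    variant_id: str
    rsid: str
    drugs: str
    mode: str
    group: str
    reference: str
    p_group: float
    p_reference: float
    excess_per_1000: float  # signed; positive = excess in `group`

    @property
    def direction(self) -> str:
        if self.excess_per_1000 == 0:
            return "none"
        return self.group if self.excess_per_1000 > 0 else self.reference

    @property
    def reported(self) -> int:
        return reported_magnitude(self.excess_per_1000)


def _oriented_frequency(row: pd.Series, effect_allele: str) -> float:
    """Frequency of the effect allele given the table's stored allele."""
    if row["allele"] == effect_allele:
        return float(row["freq"])
    return 1.0 - float(row["freq"])


def adr_table(
    freqs: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_group: str,
) -> list[ADRPrediction]:
    """Excess-ADR predictions for every toxicity variant and non-reference group.

    Uses annotation rows with ``association_type == "toxicity"`` and a
    known mode of effect; rows with unknown mode are skipped with a
    logged count, as are annotated variants absent from the frequency
    table. Frequencies are oriented to the annotated effect allele (the
    stored allele's frequency is complemented when the effect allele is
    the other allele of the pair).
    """
    groups = sorted(set(freqs["group"]))
    if reference_group not in groups:
        raise ValueError(
            f"reference group {reference_group!r} absent from frequency table"
        )
    tox = annotation[annotation["association_type"] == "toxicity"]
    n_unknown = int((tox["mode_of_effect"] == "unknown").sum())
    if n_unknown:
        logger.info("skipping %d toxicity rows with unknown mode of effect", n_unknown)
    tox = tox[tox["mode_of_effect"].isin(MODES)]

    by_variant = {vid: sub.set_index("group") for vid, sub in freqs.groupby("variant_id")}
    predictions: list[ADRPrediction] = []
    n_missing = 0
    for _, ann in tox.iterrows():
        sub = by_variant.get(ann["variant_id"])
        if sub is None and ann["rsid"]:
            match = freqs[freqs["rsid"] == ann["rsid"]]
            sub = match.set_index("group") if len(match) else None
        if sub is None or reference_group not in sub.index:
            n_missing += 1
            continue
        p_ref = _oriented_frequency(sub.loc[reference_group], ann["effect_allele"])
        for group in sub.index:
            if group == reference_group:
                continue
            p_grp = _oriented_frequency(sub.loc[group], ann["effect_allele"])
            predictions.append(
                ADRPrediction(
                    variant_id=ann["variant_id"],
                    rsid=ann["rsid"],
                    drugs=ann["drugs"],
                    mode=ann["mode_of_effect"],
                    group=group,
                    reference=reference_group,
                    p_group=p_grp,
                    p_reference=p_ref,
                    excess_per_1000=excess_adr(p_grp, p_ref, ann["mode_of_effect"]),
                )
            )
    if n_missing:
        logger.warning(
            "%d toxicity variants absent from the frequency table were skipped",
            n_missing,
        )
    return predictions


def predictions_frame(predictions: list[ADRPrediction]) -> pd.DataFrame:
    """Tabular view matching the adr CLI output columns."""
    return pd.DataFrame(
        [
            {
                "variant_id": p.variant_id,
                "rsid": p.rsid,
                "drug": p.drugs,
                "mode": p.mode,
                "group": p.group,
                "reference": p.reference,
                "p_group": p.p_group,
                "p_reference": p.p_reference,
                "excess_per_1000_continuous": p.excess_per_1000,
                "excess_per_1000_reported": p.reported,
                "direction": p.direction,
            }
            for p in predictions
        ]
    )
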