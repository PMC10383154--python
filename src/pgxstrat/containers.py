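"""Core in-memory containers shared across the pipeline.

The pipeline operates on a diploid dosage matrix (samples x variants, values
0/1/2 with explicit missingness), a per-sample group label table, and
pandas DataFrames for the tabular artifacts (annotation and frequency
tables). Dosages are stored as float64 with NaN marking missing calls so
that downstream linear algebra can mean-impute without a separate mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant keyed by GRCh38-style ``chrom:pos:ref:alt``.

    Positions are 1-based (VCF convention). ``rsid`` is the dbSNP
    identifier when known, otherwise the empty string.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, variant_id: str, rsid: str = "") -> "VariantRecord":
        parts = variant_id.split(":")
        if len(parts) != 4:
            raise ValueError(
                f"variant id must be chrom:pos:ref:alt, got {variant_id!r}"
            )
        chrom, pos, ref, alt = parts
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt, rsid=rsid)


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage matrix.

    ``dosages[i, j]`` is the count of alternate alleles (0, 1 or 2) for
    sample ``i`` at variant ``j``; NaN marks a missing genotype.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subset_variants(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in indices],
            dosages=self.dosages[:, indices],
        )

    def subset_samples(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in indices],
            variants=list(self.variants),
            dosages=self.dosages[indices, :],
        )


@dataclass
class GroupLabelSet:
    """Per-sample group label from a finite vocabulary."""

    labels: dict[str, str]
    vocabulary: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("label set must be nonempty")
        observed = sorted(set(self.labels.values()))
        if not self.vocabulary:
            self.vocabulary = tuple(observed)
        else:
            unknown = set(observed) - set(self.vocabulary)
            if unknown:
                raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")

    def group_of(self, sample: str) -> str:
        return self.labels[sample]

    def for_samples(self, samples: list[str]) -> np.ndarray:
        """Label array aligned to ``samples``; unlabeled samples raise."""
        return np.array([self.labels[s] for s in samples], dtype=object)

    def groups(self) -> list[str]:
        return list(self.vocabulary)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]
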