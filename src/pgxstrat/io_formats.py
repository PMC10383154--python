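"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF 4.2 (GT-only, diploid, biallelic); labels,
annotation tables and frequency tables travel as TSV with fixed headers.
Multiallelic VCF records are rejected by default (with a count) because
splitting them silently would change allele-frequency semantics; an
optional ``split_multiallelic`` flag splits each alternate allele into its
own biallelic record instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeMatrix, GroupLabelSet, VariantRecord

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "variant_id",
    "rsid",
    "gene",
    "drugs",
    "evidence_level",
    "association_type",
    "mode_of_effect",
    "effect_allele",
]
EVIDENCE_LEVELS = {"1A", "1B", "2A", "2B", "3", "4"}
ASSOCIATION_TYPES = {"efficacy", "dosage", "toxicity", "other"}
MODES_OF_EFFECT = {"dominant", "recessive", "unknown"}

FREQUENCY_COLUMNS = ["variant_id", "rsid", "group", "allele", "freq", "n_called"]


class VCFParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def _check_vcf_header(path: str | Path) -> None:
    """Cheap pre-check so malformed headers fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 and not line.startswith("##fileformat=VCF"):
                raise VCFParseError(
                    f"{path}: line 1: expected '##fileformat=VCF...' header"
                )
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VCFParseError(
                        f"{path}: line {lineno}: malformed #CHROM header line"
                    )
                return
            if not line.startswith("#"):
                raise VCFParseError(
                    f"{path}: line {lineno}: data line before #CHROM header"
                )
    raise VCFParseError(f"{path}: no #CHROM header line found")


def read_vcf(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a diploid VCF into a dosage matrix.

    Dosage is the alternate-allele count per call (0/1/2); ``./.`` becomes
    NaN. Multiallelic records are dropped with a logged count unless
    ``split_multiallelic`` is set, in which case each ALT becomes its own
    biallelic record.
    """
    _check_vcf_header(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                n_multi += 1
                continue
            targets = list(enumerate(alts, start=1))
        else:
            targets = [(1, alts[0])]
        genotypes = rec.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in targets:
            dosages = np.full(len(samples), np.nan)
            for i, gt in enumerate(genotypes):
                alleles = gt[:-1]
                if len(alleles) != 2:
                    raise VCFParseError(
                        f"non-diploid genotype for sample {samples[i]} at "
                        f"{rec.CHROM}:{rec.POS}"
                    )
                if alleles[0] < 0 or alleles[1] < 0:
                    continue  # missing
                dosages[i] = sum(1 for a in alleles if a == alt_index)
            rsid = rec.ID if rec.ID and rec.ID != "." else ""
            variants.append(
                VariantRecord(rec.CHROM, rec.POS, rec.REF, alt, rsid=rsid)
            )
            rows.append(dosages)
    if n_multi:
        logger.info("dropped %d multiallelic records", n_multi)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage matrix as an uncompressed GT-only VCF 4.2."""
    contigs = []
    for v in matrix.variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxstrat\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            gts = [
                _GT_STRINGS.get(d, "./.") if np.isfinite(d) else "./."
                for d in matrix.dosages[:, j]
            ]
            rsid = v.rsid if v.rsid else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t{rsid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_labels(path: str | Path) -> GroupLabelSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise SchemaError(
            f"{path}: expected columns sample_id, group; got {list(df.columns)}"
        )
    return GroupLabelSet(labels=dict(zip(df["sample_id"], df["group"])))


def write_labels(labels: GroupLabelSet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.labels), "group": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a PharmGKB-style variant annotation TSV with schema checks."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing annotation columns {missing}")
    df = df[ANNOTATION_COLUMNS]
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        if row["evidence_level"] not in EVIDENCE_LEVELS:
            raise SchemaError(
                f"{path}: row {row_number}: unknown evidence level "
                f"{row['evidence_level']!r}"
            )
        if row["association_type"] not in ASSOCIATION_TYPES:
            raise SchemaError(
                f"{path}: row {row_number}: unknown association type "
                f"{row['association_type']!r}"
            )
        if row["mode_of_effect"] not in MODES_OF_EFFECT:
            raise SchemaError(
                f"{path}: row {row_number}: unknown mode of effect "
                f"{row['mode_of_effect']!r}"
            )
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_frequencies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"variant_id": str, "rsid": str, "group": str, "allele": str},
    )
    missing = [c for c in FREQUENCY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing frequency columns {missing}")
    df = df[FREQUENCY_COLUMNS]
    bad = df[(df["freq"] < 0) | (df["freq"] > 1)]
    if len(bad):
        raise SchemaError(f"{path}: frequencies outside [0,1] in rows {list(bad.index)}")
    if df.duplicated(["variant_id", "group"]).any():
        raise SchemaError(f"{path}: duplicate (variant, group) rows")
    return df


def write_frequencies(freqs: pd.DataFrame, path: str | Path) -> None:
    out = freqs[FREQUENCY_COLUMNS].copy()
    out["freq"] = out["freq"].map(lambda x: f"{x:.6f}")
    out.to_csv(path, sep="\t", index=False)


def intersect_variants(
    genotypes: GenotypeMatrix, annotation: pd.DataFrame
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Restrict the genotype matrix to annotated variants.

    rsID is the primary join key; the positional chrom:pos:ref:alt id is
    the fallback for variants without an rsID match. Returns the submatrix
    plus a kept/dropped count report; zero overlap is an error.
    """
    ann_rsids = set(annotation["rsid"]) - {""}
    ann_ids = set(annotation["variant_id"]) - {""}
    keep = [
        j
        for j, v in enumerate(genotypes.variants)
        if (v.rsid and v.rsid in ann_rsids) or v.id in ann_ids
    ]
    report = {
        "kept": len(keep),
        "dropped": genotypes.n_variants - len(keep),
        "annotation_rows": len(annotation),
    }
    if not keep:
        raise ValueError(
            "no overlap between genotype variants and annotation "
            f"({genotypes.n_variants} genotype variants, {len(annotation)} annotation rows)"
        )
    logger.info("variant intersection: kept %(kept)d, dropped %(dropped)d", report)
    return genotypes.subset_variants(keep), report
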