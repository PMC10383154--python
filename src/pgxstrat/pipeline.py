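"""End-to-end orchestration: simulate/read -> intersect -> freqs -> pca ->
classify -> divergence -> adr, with one global seed and persisted stage
outputs.

Each stage writes its result as plain TSV under the run directory so any
stage can be re-run in isolation from its persisted inputs; a
machine-readable ``summary.json`` records seeds, record counts, the best
classifier accuracy, the top divergent variants and the ADR table path.
Stage seeds are derived deterministically from the global seed by hashing
the stage name, so re-running a single stage reproduces its output
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import ClassifierSpec, best_report, confusion_analysis, sweep_pcs
from .containers import GenotypeMatrix, GroupLabelSet
from .frequencies import group_allele_frequencies
from .io_formats import (
    intersect_variants,
    read_annotation,
    read_labels,
    read_vcf,
    write_annotation,
    write_frequencies,
    write_labels,
    write_vcf,
)
from .pca import fit_pca, rank_divergent
from .simulate import (
    SimulationConfig,
    default_cohort_config,
    simulate_genotypes,
    simulate_group_frequencies,
    synthetic_annotation,
)

logger = logging.getLogger(__name__)

STAGES = ("genotypes", "intersect", "freqs", "pca", "classify", "divergence", "adr")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    vcf_path: str | None = None
    labels_path: str | None = None
    annotation_path: str | None = None
    n_pcs: int = 25
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    pc_sweep: tuple[int, int] = (2, 25)
    divergence_pcs: tuple[int, ...] = (1, 2)
    adr_reference_group: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        simulating = self.simulation is not None
        supplied = self.vcf_path is not None
        if simulating == supplied:
            raise ValueError(
                "exactly one genotype source required: a simulation config "
                "or a VCF path"
            )
        if supplied and self.labels_path is None:
            raise ValueError("a labels TSV is required with a supplied VCF")


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Small simulated run that finishes in minutes on one CPU."""
    sim = default_cohort_config(scale=0.12, seed=derive_seed(seed, "genotypes"))
    sim.n_variants = 800
    sim.n_divergent = 20
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        simulation=sim,
        n_pcs=10,
        classifier=ClassifierSpec(method="knn", n_search_draws=5, seed=seed),
        pc_sweep=(2, 6),
        divergence_pcs=(1, 2),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a flat YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = None
    if "simulation" in raw:
        from .simulate import AdmixedGroupSpec, GroupSpec

        s = raw.pop("simulation")
        sim = SimulationConfig(
            n_variants=s.get("n_variants", 6000),
            n_divergent=s.get("n_divergent", 60),
            groups=[GroupSpec(**g) for g in s.get("groups", [])],
            admixed_groups=[
                AdmixedGroupSpec(
                    name=a["name"], size=a["size"],
                    dirichlet_alpha=tuple(a["dirichlet_alpha"]),
                )
                for a in s.get("admixed_groups", [])
            ],
            ancestral_freq_range=tuple(s.get("ancestral_freq_range", (0.05, 0.95))),
            divergent_delta=s.get("divergent_delta", 0.5),
            seed=s.get("seed", raw.get("seed", 0)),
        )
    spec = ClassifierSpec(**raw.pop("classifier", {}))
    pc_sweep = tuple(raw.pop("pc_sweep", (2, 25)))
    divergence_pcs = tuple(raw.pop("divergence_pcs", (1, 2)))
    return PipelineConfig(
        simulation=sim, classifier=spec, pc_sweep=pc_sweep,
        divergence_pcs=divergence_pcs, **raw,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in STAGES},
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                summary["stages"][name] = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # -- genotypes -----------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        truth = simulate_group_frequencies(sim)
        genotypes, labels = simulate_genotypes(truth, sim)
        annotation = synthetic_annotation(truth)
        write_vcf(genotypes, out / "genotypes.vcf")
        write_labels(labels, out / "labels.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        truth.frequency_table().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        summary["stages"]["genotypes"] = {
            "source": "simulated",
            "n_samples": genotypes.n_samples,
            "n_variants": genotypes.n_variants,
            "n_divergent": len(truth.divergent_variant_ids),
        }
    else:
        genotypes = read_vcf(config.vcf_path)
        labels = read_labels(config.labels_path)
        annotation = (
            read_annotation(config.annotation_path)
            if config.annotation_path
            else None
        )
        summary["stages"]["genotypes"] = {
            "source": config.vcf_path,
            "n_samples": genotypes.n_samples,
            "n_variants": genotypes.n_variants,
        }

    # -- intersect -----------------------------------------------------
    if annotation is not None:
        genotypes, report = intersect_variants(genotypes, annotation)
        summary["stages"]["intersect"] = report
    else:
        summary["stages"]["intersect"] = {"skipped": "no annotation supplied"}

    # -- freqs ---------------------------------------------------------
    freqs = group_allele_frequencies(genotypes, labels)
    write_frequencies(freqs, out / "frequencies.tsv")
    summary["stages"]["freqs"] = {"rows": len(freqs)}

    # -- pca -----------------------------------------------------------
    n_pcs = min(config.n_pcs, genotypes.n_samples - 1, genotypes.n_variants)
    model = fit_pca(genotypes, n_pcs=n_pcs, seed=derive_seed(config.seed, "pca"))
    model.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False,
                                float_format="%.6g")
    model.weights_frame().to_csv(out / "weights.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    np.savetxt(out / "evar.tsv", model.explained_variance_ratio, fmt="%.6g")
    summary["stages"]["pca"] = {
        "n_pcs": model.n_pcs,
        "dropped_monomorphic": model.n_dropped_monomorphic,
        "explained_variance_ratio_pc1": float(model.explained_variance_ratio[0]),
    }

    # -- classify ------------------------------------------------------
    spec = config.classifier
    lo, hi = config.pc_sweep
    hi = min(hi, model.n_pcs)
    reports = sweep_pcs(model.scores, model.samples, labels, spec, (lo, hi))
    best = best_report(reports)
    confusion_analysis(best).to_json(out / "confusion.json", orient="records")
    best.row_percentages().to_csv(out / "confusion.tsv", sep="\t",
                                  float_format="%.2f")
    summary["stages"]["classify"] = {
        "method": spec.method,
        "best_n_pcs": best.n_pcs,
        "best_mean_accuracy_pct": round(100 * best.mean_accuracy, 2),
        "sd_accuracy_pct": round(100 * best.sd_accuracy, 2),
        "sweep": {r.n_pcs: round(100 * r.mean_accuracy, 2) for r in reports},
    }

    # -- divergence ----------------------------------------------------
    ranking = rank_divergent(model, annotation, pcs=config.divergence_pcs)
    ranking.to_csv(out / "ranked_variants.tsv", sep="\t", index=False,
                   float_format="%.6g")
    summary["stages"]["divergence"] = {
        "top_variants": ranking["variant_id"].head(10).tolist(),
    }

    # -- adr -----------------------------------------------------------
    if annotation is not None:
        from .adr import adr_table, predictions_frame

        reference = config.adr_reference_group or max(
            labels.groups(), key=lambda g: len(labels.members(g))
        )
        predictions = adr_table(freqs, annotation, reference)
        frame = predictions_frame(predictions)
        frame.to_csv(out / "adr.tsv", sep="\t", index=False, float_format="%.6g")
        summary["stages"]["adr"] = {
            "reference_group": reference,
            "rows": len(frame),
            "path": str(out / "adr.tsv"),
        }
    else:
        summary["stages"]["adr"] = {"skipped": "no annotation supplied"}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
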