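"""Synthetic cohorts with group-stratified allele frequencies.

The generator emulates the statistical structure of a large, diverse
biobank cohort: several self-identified groups of unequal size whose
allele frequencies have drifted from a shared ancestral frequency
(Balding-Nichols Beta model indexed by a per-group FST), one broad admixed
group whose members mix the non-admixed groups' gene pools, and a small
planted set of strongly group-divergent variants among thousands of
background variants.

Model
-----
For variant j an ancestral frequency ``p_j ~ Uniform(ancestral_freq_range)``
is drawn once. Each non-admixed group g with divergence parameter ``F_g``
then draws

    p_gj ~ Beta( p_j (1 - F_g) / F_g ,  (1 - p_j)(1 - F_g) / F_g )

so that E[p_gj] = p_j and Var[p_gj] = F_g p_j (1 - p_j). Genotypes are
``Binomial(2, p_gj)``. Admixed samples draw per-sample ancestry
proportions from a Dirichlet over the non-admixed groups and each of
their two allele copies picks a parental group independently, which makes
the dosage ``Binomial(2, sum_g w_g p_gj)`` for ancestry weights w.

Variants are simulated without linkage disequilibrium (independent across
sites); there is no recombination map and no phenotype model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GroupLabelSet, VariantRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GroupSpec:
    """A non-admixed group: name, sample count, and FST-style divergence."""

    name: str
    size: int
    fst: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.name}: size must be >= 1")
        if not (0.0 < self.fst < 1.0):
            raise ValueError(f"group {self.name}: fst must lie in (0, 1)")


@dataclass(frozen=True)
class AdmixedGroupSpec:
    """An admixed group whose ancestry mixes the non-admixed groups.

    ``dirichlet_alpha`` gives one concentration per non-admixed group (in
    config order); per-sample ancestry proportions are Dirichlet draws.
    Small alphas give broadly dispersed ancestries, large alphas
    concentrate every sample near the normalized mean weights.
    """

    name: str
    size: int
    dirichlet_alpha: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"admixed group {self.name}: size must be >= 1")
        if any(a < 0 for a in self.dirichlet_alpha) or sum(self.dirichlet_alpha) <= 0:
            raise ValueError(
                f"admixed group {self.name}: Dirichlet concentrations must be "
                "nonnegative with positive sum"
            )

    @property
    def mean_weights(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, dtype=float)
        return a / a.sum()


@dataclass
class SimulationConfig:
    n_variants: int = 6000
    n_divergent: int = 60
    groups: list[GroupSpec] = field(default_factory=list)
    admixed_groups: list[AdmixedGroupSpec] = field(default_factory=list)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    divergent_delta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0 <= self.n_divergent <= self.n_variants):
            raise ValueError("n_divergent must lie in [0, n_variants]")
        if not self.groups:
            raise ValueError("at least one non-admixed group is required")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be an interval within (0, 1)")
        if not (0.0 <= self.divergent_delta < 1.0):
            raise ValueError("divergent_delta must lie in [0, 1)")
        for adm in self.admixed_groups:
            if len(adm.dirichlet_alpha) != len(self.groups):
                raise ValueError(
                    f"admixed group {adm.name}: need one Dirichlet concentration "
                    f"per non-admixed group ({len(self.groups)})"
                )

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def n_samples(self) -> int:
        return sum(g.size for g in self.groups) + sum(
            a.size for a in self.admixed_groups
        )


def default_cohort_config(scale: float = 1.0, seed: int = 0) -> SimulationConfig:
    """Five-group cohort with one broad admixed group.

    Group proportions mirror a large US biobank after majority-group
    down-sampling (four non-admixed groups of very unequal size plus one
    broad multi-ancestry group); ``scale=1.0`` gives ~6500 samples, a
    tenth of that cohort. Divergence parameters are continental-scale
    (FST around 0.1).
    """
    def n(x: int) -> int:
        return max(int(round(x * scale)), 10)

    return SimulationConfig(
        n_variants=6000,
        n_divergent=60,
        groups=[
            GroupSpec("groupA", n(2000), 0.08),
            GroupSpec("groupB", n(2128), 0.12),
            GroupSpec("groupC", n(1730), 0.10),
            GroupSpec("groupD", n(297), 0.14),
        ],
        admixed_groups=[
            AdmixedGroupSpec("multi", n(357), (1.0, 1.0, 1.0, 1.0)),
        ],
        divergent_delta=0.5,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """The simulated truth: variants, per-group frequencies, planted set."""

    variants: list[VariantRecord]
    group_names: list[str]
    frequencies: np.ndarray  # (n_groups, n_variants)
    divergent_variant_ids: set[str]
    admixed_proportions: dict[str, np.ndarray]  # group -> (size, n_groups)
    ancestral_frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frequencies.shape != (len(self.group_names), len(self.variants)):
            raise ValueError("frequency array inconsistent with groups x variants")
        if np.any((self.frequencies < 0) | (self.frequencies > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        ids = {v.id for v in self.variants}
        if not self.divergent_variant_ids <= ids:
            raise ValueError("divergent variant ids not a subset of variant ids")

    def frequency_table(self) -> pd.DataFrame:
        rows = []
        for g, name in enumerate(self.group_names):
            for j, v in enumerate(self.variants):
                rows.append(
                    {
                        "variant_id": v.id,
                        "rsid": v.rsid,
                        "group": name,
                        "allele": v.alt,
                        "freq": self.frequencies[g, j],
                        "divergent": v.id in self.divergent_variant_ids,
                    }
                )
        return pd.DataFrame(rows)


def _synthesize_variants(n: int, rng: np.random.Generator) -> list[VariantRecord]:
    chroms = [f"chr{1 + (j % 22)}" for j in range(n)]
    positions = {}
    variants = []
    for j in range(n):
        chrom = chroms[j]
        positions[chrom] = positions.get(chrom, 10_000) + int(rng.integers(500, 5000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        variants.append(
            VariantRecord(chrom, positions[chrom], str(ref), str(alt),
                          rsid=f"rs9{j + 1:07d}")
        )
    return variants


def simulate_group_frequencies(config: SimulationConfig) -> GroundTruth:
    """Draw per-group allele frequencies under the Balding-Nichols model.

    The ``n_divergent`` planted variants are redrawn (rejection sampling,
    up to 1000 attempts each) until the maximum pairwise group difference
    reaches ``divergent_delta``; if rejection fails, frequencies are
    assigned directly (one group at 0.9, the others at 0.1).
    """
    rng = np.random.default_rng([config.seed, 0])
    n_groups = len(config.groups)
    variants = _synthesize_variants(config.n_variants, rng)
    ancestral = rng.uniform(*config.ancestral_freq_range, size=config.n_variants)

    freqs = np.empty((n_groups, config.n_variants))
    for g, spec in enumerate(config.groups):
        f = spec.fst
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        freqs[g] = rng.beta(a, b)

    divergent_idx = rng.choice(
        config.n_variants, size=config.n_divergent, replace=False
    )
    for j in divergent_idx:
        ok = freqs[:, j].max() - freqs[:, j].min() >= config.divergent_delta
        attempts = 0
        while not ok and attempts < 1000:
            for g, spec in enumerate(config.groups):
                f = spec.fst
                freqs[g, j] = rng.beta(
                    ancestral[j] * (1 - f) / f, (1 - ancestral[j]) * (1 - f) / f
                )
            ok = freqs[:, j].max() - freqs[:, j].min() >= config.divergent_delta
            attempts += 1
        if not ok:
            high = rng.integers(n_groups)
            freqs[:, j] = 0.1
            freqs[high, j] = 0.9

    admixed_proportions = {
        adm.name: rng.dirichlet(np.asarray(adm.dirichlet_alpha, dtype=float),
                                size=adm.size)
        for adm in config.admixed_groups
    }
    return GroundTruth(
        variants=variants,
        group_names=config.group_names,
        frequencies=freqs,
        divergent_variant_ids={variants[j].id for j in divergent_idx},
        admixed_proportions=admixed_proportions,
        ancestral_frequencies=ancestral,
    )


def simulate_genotypes(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[GenotypeMatrix, GroupLabelSet]:
    """Draw diploid genotypes for every group in the config.

    Non-admixed samples are ``Binomial(2, p_gj)``. Each admixed sample's
    two allele copies independently pick a parental group by its ancestry
    proportions, i.e. ``Binomial(2, w . p_j)``.
    """
    if truth.group_names != config.group_names:
        raise ValueError("ground truth groups do not match config groups")
    rng = np.random.default_rng([config.seed, 1])
    blocks, samples, labels = [], [], {}
    for g, spec in enumerate(config.groups):
        blocks.append(rng.binomial(2, truth.frequencies[g], size=(spec.size, config.n_variants)))
        for i in range(spec.size):
            sid = f"{spec.name}_{i:05d}"
            samples.append(sid)
            labels[sid] = spec.name
    for adm in config.admixed_groups:
        W = truth.admixed_proportions[adm.name]  # (size, n_groups)
        Q = W @ truth.frequencies  # per-sample per-variant allele prob
        blocks.append(rng.binomial(2, Q))
        for i in range(adm.size):
            sid = f"{adm.name}_{i:05d}"
            samples.append(sid)
            labels[sid] = adm.name
    dosages = np.vstack(blocks).astype(float)
    matrix = GenotypeMatrix(samples=samples, variants=list(truth.variants),
                            dosages=dosages)
    vocabulary = tuple(config.group_names + [a.name for a in config.admixed_groups])
    return matrix, GroupLabelSet(labels=labels, vocabulary=vocabulary)


def synthetic_annotation(truth: GroundTruth) -> pd.DataFrame:
    """PharmGKB-style annotation for the simulated variants.

    Planted divergent variants are annotated as toxicity-associated with
    alternating dominant/recessive modes (effect allele = alternate);
    background variants carry weak-evidence placeholder annotations with
    unknown mode, so downstream risk tables only use the planted set.
    """
    rows = []
    k = 0
    for j, v in enumerate(truth.variants):
        divergent = v.id in truth.divergent_variant_ids
        if divergent:
            mode = "dominant" if k % 2 == 0 else "recessive"
            k += 1
            rows.append(
                {
                    "variant_id": v.id, "rsid": v.rsid, "gene": f"GENE{j:05d}",
                    "drugs": f"drug{j:05d}", "evidence_level": "2A",
                    "association_type": "toxicity", "mode_of_effect": mode,
                    "effect_allele": v.alt,
                }
            )
        else:
            rows.append(
                {
                    "variant_id": v.id, "rsid": v.rsid, "gene": f"GENE{j:05d}",
                    "drugs": f"drug{j:05d}", "evidence_level": "3",
                    "association_type": "other", "mode_of_effect": "unknown",
                    "effect_allele": v.alt,
                }
            )
    return pd.DataFrame(rows)


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Ratio-of-averages Hudson-style FST from two population frequencies.

    Uses per-variant numerator (p1 - p2)^2 and denominator
    p1(1 - p2) + p2(1 - p1), averaged before taking the ratio. On
    population (not sample) frequencies this estimates the shared
    divergence parameter F of the Balding-Nichols model.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
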