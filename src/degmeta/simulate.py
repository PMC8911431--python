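"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study designs the pipeline consumes: paired
log2 fold changes of homologous DEGs with a controlled Pearson
correlation, multi-study DEG tables where each seed gene has a family of
partners with plantable sign discordance, negative-binomial count
matrices for a 3-vs-3 RNA-seq design with planted DEGs, and qPCR
triplicates for an 8-vs-8 animal design with a multiplicative group
effect.  Everything is driven by one explicit integer seed; there is no
global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .deg_calling import ExpressionMatrix
from .records import (
    DegRecord,
    HomologMapEntry,
    HomologPair,
    QpcrMeasurement,
    ValidationError,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generators.

    Defaults follow the study conditions the pipeline targets: 151 homolog
    pairs at Pearson rho = -0.29, 42 seed genes, a 3-vs-3 count design and
    an 8-vs-8 qPCR design with triplicate technical replicates.
    sigma_log2 = 2.5 matches the spread of published hippocampal log2
    values; qpcr_effect = 9.3 is the observed tame/aggressive group-mean
    ratio of the strongest verified gene.
    """

    seed: int = 0
    n_pairs: int = 151
    rho: float = -0.29
    n_seed_genes: int = 42
    family_size_range: tuple[int, int] = (1, 10)
    frac_discordant: float = 0.5
    sigma_log2: float = 2.5
    n_genes: int = 1000
    frac_deg: float = 0.05
    effect_log2: float = 2.0
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    n_animals_per_group: int = 8
    n_qpcr_replicates: int = 3
    qpcr_effect: float = 9.3
    qpcr_sigma: float = 0.2

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise ValidationError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.sigma_log2 <= 0:
            raise ValidationError("sigma_log2 must be > 0")
        if not (0.0 <= self.frac_discordant <= 1.0):
            raise ValidationError("frac_discordant must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("family_size_range must satisfy 1 <= min <= max")
        for name in ("n_pairs", "n_seed_genes", "n_genes", "n_replicates",
                     "n_animals_per_group", "n_qpcr_replicates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


def simulate_paired_log2(config: SimConfig) -> list[HomologPair]:
    """Draw n_pairs (seed, partner) log2 pairs from a zero-mean bivariate
    normal with variance sigma_log2^2 and correlation rho."""
    rng = np.random.default_rng(config.seed)
    if abs(config.rho) == 1.0:  # singular covariance: exact linear relation
        x = rng.normal(0.0, config.sigma_log2, size=config.n_pairs)
        draws = np.column_stack([x, config.rho * x])
    else:
        cov = config.sigma_log2**2 * np.array(
            [[1.0, config.rho], [config.rho, 1.0]]
        )
        draws = rng.multivariate_normal(
            np.zeros(2), cov, size=config.n_pairs, method="cholesky"
        )
    return [
        HomologPair(
            seed_gene=f"SG{i:04d}",
            seed_log2=float(x),
            partner_gene=f"PG{i:04d}",
            partner_log2=float(y),
            study_id="sim_study",
            species="sim",
            tissue="sim",
        )
        for i, (x, y) in enumerate(draws)
    ]


def simulate_deg_tables(
    config: SimConfig,
) -> tuple[list[DegRecord], list[DegRecord], list[HomologMapEntry]]:
    """Seed DEG table, multi-study partner DEG table and the homolog map.

    Each of n_seed_genes seed genes gets a family of partner DEGs (family
    size uniform over family_size_range) spread across fictitious studies.
    The first round(frac_discordant * n_seed_genes) seed genes are planted
    "discordant": every partner's log2 sign is opposite to the seed's;
    the rest are fully concordant.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.family_size_range
    n_discordant = round(config.frac_discordant * config.n_seed_genes)

    seed_records: list[DegRecord] = []
    partner_records: list[DegRecord] = []
    map_entries: list[HomologMapEntry] = []
    for i in range(config.n_seed_genes):
        gene = f"SEED{i:04d}"
        sign = -1.0 if rng.random() < 0.5 else 1.0
        magnitude = abs(rng.normal(0.0, config.sigma_log2)) + 1e-6
        seed_log2 = sign * magnitude
        seed_records.append(
            DegRecord(
                study_id="seed_study",
                species="rat",
                tissue="hippocampus",
                contrast="tame_vs_aggressive",
                gene=gene,
                log2=seed_log2,
                p=1e-4,
                p_adj=0.01,
            )
        )
        discordant = i < n_discordant
        family_size = int(rng.integers(lo, hi + 1))
        for j in range(family_size):
            partner = f"{gene}_H{j:02d}"
            pmag = abs(rng.normal(0.0, config.sigma_log2)) + 1e-6
            plog2 = -seed_log2 / magnitude * pmag if discordant else (
                seed_log2 / magnitude * pmag
            )
            partner_records.append(
                DegRecord(
                    study_id=f"study{j:02d}",
                    species="sim",
                    tissue=f"tissue{j:02d}",
                    contrast="hypertensive_vs_normotensive",
                    gene=partner,
                    log2=plog2,
                    p=1e-3,
                    p_adj=0.05,
                )
            )
            map_entries.append(
                HomologMapEntry(
                    seed_gene=gene,
                    partner_gene=partner,
                    partner_species="sim",
                    family=gene,
                )
            )
    return seed_records, partner_records, map_entries


def simulate_counts(config: SimConfig) -> tuple[ExpressionMatrix, list[str]]:
    """Negative-binomial count matrix for two groups of n_replicates
    samples, with planted DEGs.

    The first round(frac_deg * n_genes) genes get group means differing by
    effect_log2 (alternating direction).  Counts are NB with mean mu and
    variance mu + nb_dispersion * mu^2.  Returns the matrix and the list
    of planted gene ids.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, reps = config.n_genes, config.n_replicates
    n_planted = round(config.frac_deg * n_genes)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(math.log(config.nb_mean), 1.0, size=n_genes)
    fold = np.ones(n_genes)
    fold[:n_planted] = 2.0 ** (
        config.effect_log2 * (-1.0) ** np.arange(n_planted)
    )
    mu = np.empty((n_genes, 2 * reps))
    mu[:, :reps] = (base * fold)[:, None]  # group A carries the effect
    mu[:, reps:] = base[:, None]
    # NB parametrization: size r = 1/dispersion, p = r / (r + mu)
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    values = rng.negative_binomial(r, p).astype(float)
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"A{i}" for i in range(reps)] + [f"B{i}" for i in range(reps)],
        group_labels=["A"] * reps + ["B"] * reps,
        values=values,
    )
    return matrix, genes[:n_planted]


def simulate_qpcr(config: SimConfig, gene: str = "SIMGENE") -> list[QpcrMeasurement]:
    """Per-animal qPCR triplicates for two groups with a multiplicative
    group effect.

    Treated animals ("tame") have expected relative expression
    qpcr_effect; controls ("aggressive") have 1.  Animal-level and
    replicate-level noise are lognormal with scale qpcr_sigma.
    """
    rng = np.random.default_rng(config.seed)
    out: list[QpcrMeasurement] = []
    for group, effect in (("tame", config.qpcr_effect), ("aggressive", 1.0)):
        for animal in range(config.n_animals_per_group):
            animal_level = effect * rng.lognormal(0.0, config.qpcr_sigma)
            reps = animal_level * rng.lognormal(
                0.0, config.qpcr_sigma, size=config.n_qpcr_replicates
            )
            out.append(
                QpcrMeasurement(
                    rat_id=f"{group}_{animal + 1}",
                    group=group,
                    gene=gene,
                    replicate_values=tuple(float(v) for v in reps),
                )
            )
    return out
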