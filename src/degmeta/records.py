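"""Shared record types for the cross-study DEG meta-analysis.

Each type is the in-memory row of one of the exchange tables the pipeline
reads or writes: per-study DEG tables, homolog maps, paired fold changes,
sign-concordance rows, 2x2 contingency summaries, and qPCR measurements.
All records are plain frozen dataclasses so that lists of them can be
round-tripped losslessly through TSV (see :mod:`degmeta.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class DegmetaError(Exception):
    """Base class for all package errors."""


class ValidationError(DegmetaError):
    """Malformed input: a record or configuration violates its invariants."""


class DegenerateInputError(DegmetaError):
    """Statistically degenerate input (e.g. zero pooled SE with unequal means)."""


@dataclass(frozen=True)
class DegRecord:
    """One gene's fold-change result in one study.

    ``log2`` is the log2-transformed fold change of the contrast's first
    level over its second (e.g. tame over aggressive); ``p``/``p_adj`` are
    the raw and multiplicity-adjusted significance.  Published tables often
    report bounds ("<10^-4") rather than values; the ``*_is_bound`` flags
    record that the stored number is an upper bound.
    """

    study_id: str
    species: str
    tissue: str
    contrast: str
    gene: str
    log2: float
    p: float = 1.0
    p_adj: float = 1.0
    p_is_bound: bool = False
    p_adj_is_bound: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("DegRecord.gene must be non-empty")
        if not math.isfinite(self.log2):
            raise ValidationError(f"DegRecord.log2 must be finite, got {self.log2!r}")
        for name in ("p", "p_adj"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"DegRecord.{name} must be in (0,1], got {v!r}")


@dataclass(frozen=True)
class HomologMapEntry:
    """Curated homology assertion: ``seed_gene`` (rat hippocampal DEG) is in
    the same gene family as ``partner_gene`` in ``partner_species``."""

    seed_gene: str
    partner_gene: str
    partner_species: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.seed_gene or not self.partner_gene:
            raise ValidationError("HomologMapEntry genes must be non-empty")


@dataclass(frozen=True)
class HomologPair:
    """A (seed DEG, homologous partner DEG) pair carrying both log2 values."""

    seed_gene: str
    seed_log2: float
    partner_gene: str
    partner_log2: float
    study_id: str
    species: str
    tissue: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.seed_log2) and math.isfinite(self.partner_log2)):
            raise ValidationError("HomologPair log2 values must be finite")


@dataclass(frozen=True)
class SignConcordanceRow:
    """Per seed gene: counts of partners with opposite (n_pc1) and matching
    (n_pc2) log2 sign, with the exact binomial p and its Bonferroni
    adjustment.  ``p`` and ``p_adj`` are ``None`` for ND rows (no partners)."""

    gene: str
    n_pc1: int
    n_pc2: int
    p: Optional[float]
    p_adj: Optional[float]
    n_excluded_zero: int = 0

    def __post_init__(self) -> None:
        if self.n_pc1 < 0 or self.n_pc2 < 0 or self.n_excluded_zero < 0:
            raise ValidationError("sign-concordance counts must be non-negative")


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 contingency table; rows are animal lineage (wild, domestic),
    columns are the human hypertension direction the expression state
    corresponds to (hypertensive-concordant, normotensive-concordant)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self):
        import numpy as np

        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class DirectionalCounts:
    """Counts of candidate SNP markers by predicted direction of effect.

    ``n_gt``/``n_lt``: markers increasing/decreasing TBP-promoter affinity;
    ``n_to_ht``/``n_from_ht``: markers predicted to provoke/prevent
    hypertension.  Consumed as given; this package only tests the counts.
    """

    n_gene: int
    n_snp: int
    n_res: int
    n_gt: int
    n_lt: int
    n_to_ht: Optional[int] = None
    n_from_ht: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_gt + self.n_lt != self.n_res:
            raise ValidationError("n_gt + n_lt must equal n_res")
        if self.n_to_ht is not None and self.n_from_ht is not None:
            if self.n_to_ht + self.n_from_ht != self.n_res:
                raise ValidationError("n_to_ht + n_from_ht must equal n_res")


@dataclass(frozen=True)
class DivergencePolarity:
    """Which lineage (domestic or wild) shows downregulation of a gene,
    derived from the sign of its log2(domestic vs wild) fold change."""

    gene: str
    lineage_down: str  # "domestic" | "wild"
    family: str = ""

    def __post_init__(self) -> None:
        if self.lineage_down not in ("domestic", "wild"):
            raise ValidationError(
                f"lineage_down must be 'domestic' or 'wild', got {self.lineage_down!r}"
            )


@dataclass(frozen=True)
class QpcrMeasurement:
    """Per-rat relative expression of one gene: technical replicates plus
    their mean (M0) and standard error (SEM)."""

    rat_id: str
    group: str
    gene: str
    replicate_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_values) < 1:
            raise ValidationError("at least one replicate value required")
        if any(v < 0 for v in self.replicate_values):
            raise ValidationError("replicate values must be non-negative")

    @property
    def m0(self) -> float:
        return sum(self.replicate_values) / len(self.replicate_values)

    @property
    def sem(self) -> float:
        vals = self.replicate_values
        k = len(vals)
        if k == 1:
            return 0.0
        m = self.m0
        var = sum((v - m) ** 2 for v in vals) / (k - 1)
        return math.sqrt(var / k)


@dataclass(frozen=True)
class GroupSummary:
    """Group-level summary of per-rat means for one gene."""

    gene: str
    group: str
    per_rat_means: tuple[float, ...]
    group_mean: float
    group_sd: float
    n_rats: int


@dataclass(frozen=True)
class CorrelationBattery:
    """Pearson r, Spearman R, Kendall tau-b and Goodman-Kruskal gamma with
    their p-values, computed on one set of paired log2 values."""

    r: float
    r_p: float
    spearman: float
    spearman_p: float
    tau: float
    tau_p: float
    gamma: float
    gamma_p: float
    n: int


@dataclass(frozen=True)
class PcaResult:
    """Eigendecomposition of the 2x2 correlation matrix of paired log2
    values, with bootstrap percentile intervals on the loadings.

    ``loadings`` is components x variables (rows are PC1, PC2) and is
    orthonormal; ``eigenvalues`` descend and sum to 2 (correlation mode).
    """

    loadings: tuple[tuple[float, float], tuple[float, float]]
    eigenvalues: tuple[float, float]
    bootstrap_low: tuple[tuple[float, float], tuple[float, float]]
    bootstrap_high: tuple[tuple[float, float], tuple[float, float]]
    n_boot: int
    seed: int
    r: float = field(default=float("nan"))
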