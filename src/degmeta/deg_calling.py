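"""Final differential-expression statistics on a gene x sample matrix.

The DE stage takes an expression matrix with a two-level group factor
(e.g. three tame vs three aggressive rats), normalizes counts to counts
per million, and per gene computes the log2 fold change of group means and
a two-sample z-test on the log2-transformed values ("Fisher Z-test":
unpooled standard errors, standard-normal reference).  P-values are then
adjusted across genes with the Benjamini-Hochberg step-up procedure, and
genes with placeholder names (hypothetical / predicted / uncharacterized /
non-coding symbols) are discarded before significance is thresholded.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import DegenerateInputError, DegRecord, ValidationError

#: Symbol patterns treated as hypothetical / predicted / uncharacterized /
#: non-protein-coding and excluded from the final DEG list.
DEFAULT_EXCLUSION_PATTERNS: tuple[str, ...] = (
    r"^LOC\d",
    r"^RGD\d",
    r"predicted",
    r"hypothetical",
    r"uncharacterized",
    r"tentative",
    r"-ps\d*$",
)


@dataclass
class ExpressionMatrix:
    """Non-negative expression values for genes x samples with a two-level
    group factor over the samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("values shape must be (n_genes, n_samples)")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValidationError("one group label per sample required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        levels = self.group_levels
        if len(levels) != 2:
            raise ValidationError(f"exactly two groups required, got {levels}")
        for lev in levels:
            if self.group_labels.count(lev) < 2:
                raise ValidationError(f"group {lev!r} needs >= 2 samples")

    @property
    def group_levels(self) -> tuple[str, ...]:
        """Group levels in order of first appearance (first level = group A)."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return tuple(seen)

    def group_columns(self, level: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group_labels) if g == level])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to counts per million (library-size normalization).

    Total-count scaling is composition-sensitive: a few strongly changed
    high-abundance genes shift every other gene's normalized value; see
    :func:`median_ratio_normalize` for the robust alternative.
    """
    totals = matrix.values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("cannot CPM-normalize a sample with zero total")
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        group_labels=list(matrix.group_labels),
        values=matrix.values / totals * 1e6,
    )


def median_ratio_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors (robust to composition bias).

    Each sample is divided by the median, over genes expressed in every
    sample, of its ratio to the per-gene geometric-mean reference.
    """
    v = matrix.values
    positive = np.all(v > 0, axis=1)
    if not positive.any():
        raise ValidationError("no gene expressed in every sample")
    ref = np.exp(np.mean(np.log(v[positive]), axis=1))
    factors = np.median(v[positive] / ref[:, None], axis=0)
    if np.any(factors <= 0):
        raise ValidationError("non-positive size factor")
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        group_labels=list(matrix.group_labels),
        values=v / factors,
    )


def log2_fold_change(
    matrix: ExpressionMatrix, gene: str, pseudocount: float = 0.5
) -> float:
    """log2((mean_A + pc) / (mean_B + pc)); group A is the first factor level."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    try:
        row = matrix.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not in matrix") from None
    a_level, b_level = matrix.group_levels
    a = matrix.values[row, matrix.group_columns(a_level)].mean()
    b = matrix.values[row, matrix.group_columns(b_level)].mean()
    return math.log2((a + pseudocount) / (b + pseudocount))


def fisher_z_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    pseudocount: float = 0.5,
    log_transform: bool = True,
    reference: str = "t",
) -> tuple[float, float]:
    """Two-sample z-test on (optionally log2-transformed) expression values.

    z = (mean(A) - mean(B)) / sqrt(SE_A^2 + SE_B^2) with unpooled standard
    errors.  The default reference distribution is Student t with
    Welch-Satterthwaite degrees of freedom, which keeps the type-I error
    near nominal at the small group sizes typical of RNA-seq designs; with
    ``reference="normal"`` the two-sided p is 2 (1 - Phi(|z|)), the naive
    large-sample form (anti-conservative for tiny groups).

    Identical constant groups give (0, 1).  Zero pooled SE with unequal
    means is degenerate and raises :class:`DegenerateInputError`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if log_transform:
        a = np.log2(a + pseudocount)
        b = np.log2(b + pseudocount)
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    se2 = va + vb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise DegenerateInputError(
            "zero pooled standard error with unequal group means"
        )
    z = diff / math.sqrt(se2)
    if reference == "normal":
        p = 2.0 * stats.norm.sf(abs(z))
    elif reference == "t":
        df = se2**2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        p = 2.0 * stats.t.sf(abs(z), df)
    else:
        raise ValidationError(f"unknown reference {reference!r}")
    return float(z), float(min(p, 1.0))


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def filter_gene_names(
    records: Sequence[DegRecord],
    patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
    biotypes: Optional[dict[str, str]] = None,
) -> list[DegRecord]:
    """Drop records whose symbol matches an exclusion pattern or whose
    annotated biotype (when provided) is not protein-coding."""
    compiled = [re.compile(pat, re.IGNORECASE) for pat in patterns]
    kept = []
    for rec in records:
        if any(c.search(rec.gene) for c in compiled):
            continue
        if biotypes is not None:
            bt = biotypes.get(rec.gene)
            if bt is not None and bt != "protein_coding":
                continue
        kept.append(rec)
    return kept


def call_degs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    normalize: Union[bool, str] = True,
    exclusion_patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
    study_id: str = "this_study",
    species: str = "rat",
    tissue: str = "hippocampus",
    contrast: str = "tame_vs_aggressive",
) -> list[DegRecord]:
    """Full DE stage: CPM-normalize, per-gene log2 fold change and z-test,
    BH adjustment across genes, name filtering, threshold on adjusted p.

    Genes with degenerate test input (zero pooled SE, unequal means) are
    excluded from both the p-value family and the returned calls.  Returns
    records sorted by gene symbol.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must lie in [0, 1]")
    if normalize in (True, "cpm"):
        mat = cpm_normalize(matrix)
    elif normalize == "median_ratio":
        mat = median_ratio_normalize(matrix)
    elif normalize in (False, None, "none"):
        mat = matrix
    else:
        raise ValidationError(f"unknown normalization {normalize!r}")
    a_level, b_level = mat.group_levels
    cols_a = mat.group_columns(a_level)
    cols_b = mat.group_columns(b_level)

    genes: list[str] = []
    lfcs: list[float] = []
    pvals: list[float] = []
    for i, gene in enumerate(mat.gene_ids):
        va = mat.values[i, cols_a]
        vb = mat.values[i, cols_b]
        try:
            _, p = fisher_z_test(va, vb, pseudocount=pseudocount)
        except DegenerateInputError:
            continue
        genes.append(gene)
        lfcs.append(
            math.log2((va.mean() + pseudocount) / (vb.mean() + pseudocount))
        )
        pvals.append(max(p, 1e-300))  # keep within (0,1] for the BH stage

    padj = benjamini_hochberg(pvals)
    records = [
        DegRecord(
            study_id=study_id,
            species=species,
            tissue=tissue,
            contrast=contrast,
            gene=g,
            log2=lfc,
            p=p,
            p_adj=q,
        )
        for g, lfc, p, q in zip(genes, lfcs, pvals, padj)
    ]
    records = filter_gene_names(records, exclusion_patterns)
    out = [rec for rec in records if rec.p_adj < alpha]
    return sorted(out, key=lambda r: r.gene)
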