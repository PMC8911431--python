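"""qPCR relative-expression summarization and group comparison.

Relative expression of a target gene is its efficiency-weighted quantity
E_t^(-Cq_t) divided by the geometric mean of the same quantity over the
reference genes; per-animal technical replicates are averaged to M0 +/-
SEM, and groups are compared with an exact Mann-Whitney U test (and,
in the pipeline, the same two-sample z-test used by the DE stage).
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import correlation_battery
from .records import (
    CorrelationBattery,
    GroupSummary,
    HomologPair,
    QpcrMeasurement,
    ValidationError,
)

Alternative = Literal["two_sided", "greater", "less"]


def relative_expression(
    target_cq: float,
    reference_cqs: Mapping[str, float],
    efficiencies: Mapping[str, float],
    target_gene: str = "target",
    calibrator: Optional[float] = None,
) -> float:
    """Efficiency-corrected relative expression against multi-reference
    geometric-mean normalization.

    quantity(g) = E_g ** (-Cq_g); the result is quantity(target) divided by
    the geometric mean of the reference quantities, then by ``calibrator``
    when given.  Efficiencies are amplification factors in (1, 2].
    """
    if not reference_cqs:
        raise ValidationError("at least one reference gene required")
    for gene in list(reference_cqs) + [target_gene]:
        e = efficiencies.get(gene)
        if e is None:
            raise ValidationError(f"missing efficiency for {gene!r}")
        if not (1.0 < e <= 2.0):
            raise ValidationError(f"efficiency for {gene!r} must be in (1, 2]")
    log_q_target = -target_cq * math.log(efficiencies[target_gene])
    log_q_refs = [
        -cq * math.log(efficiencies[g]) for g, cq in reference_cqs.items()
    ]
    value = math.exp(log_q_target - sum(log_q_refs) / len(log_q_refs))
    if calibrator is not None:
        if calibrator <= 0:
            raise ValidationError("calibrator must be positive")
        value /= calibrator
    return value


def summarize_group(
    measurements: Sequence[QpcrMeasurement], gene: str, group: str
) -> GroupSummary:
    """Group mean of per-rat replicate means (M0) for one gene, with the SD
    of the per-rat means as the dispersion summary."""
    means = [m.m0 for m in measurements if m.gene == gene and m.group == group]
    if not means:
        raise ValidationError(f"no measurements for gene {gene!r} group {group!r}")
    arr = np.asarray(means)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(
        gene=gene,
        group=group,
        per_rat_means=tuple(float(v) for v in means),
        group_mean=float(arr.mean()),
        group_sd=sd,
        n_rats=len(means),
    )


def _u_counts(n1: int, n2: int) -> list[int]:
    """Number of rank arrangements of groups (n1, n2) giving each value of
    U_A, by the classical recurrence f(i,j,u) = f(i,j-1,u) + f(i-1,j,u-j):
    the largest rank comes from A (beating all j B's) or from B."""
    umax = n1 * n2
    # counts[i][j][u]; roll over i to keep two layers
    prev = [[1] + [0] * umax for _ in range(n2 + 1)]  # i = 0
    for i in range(1, n1 + 1):
        cur = [[0] * (umax + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1  # j = 0: all A, U_A = 0
        for j in range(1, n2 + 1):
            row, left, up = cur[j], cur[j - 1], prev[j]
            for u in range(umax + 1):
                row[u] = left[u] + (up[u - j] if u >= j else 0)
        prev = cur
    return prev[n2]


def mann_whitney_exact(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: Alternative = "two_sided",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Mann-Whitney U test with the exact null distribution of U.

    Returns (U, p) where U = min(U_A, U_B).  For combined n up to
    ``exact_limit`` and tie-free data the null distribution is computed by
    the partition recurrence; with ties or larger samples the normal
    approximation with tie correction is used.  Two-sided p is twice the
    smaller tail, capped at 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u_a = r1 - n1 * (n1 + 1) / 2.0
    u_b = n1 * n2 - u_a
    u_min = min(u_a, u_b)

    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= exact_limit and not has_ties:
        counts = _u_counts(n1, n2)
        total = sum(counts)
        k = int(round(u_a))
        p_le = sum(counts[: k + 1]) / total
        p_ge = sum(counts[k:]) / total
        if alternative == "greater":  # group A tends larger -> large U_A
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_min), float(p)

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return float(u_min), 1.0
    mu = n1 * n2 / 2.0
    if alternative == "greater":
        z = (u_a - 0.5 - mu) / math.sqrt(sigma2)
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u_a + 0.5 - mu) / math.sqrt(sigma2)
        p = stats.norm.cdf(z)
    else:
        z = (abs(u_a - mu) - 0.5) / math.sqrt(sigma2)
        p = 2.0 * stats.norm.sf(z)
    return float(u_min), float(min(1.0, p))


def rnaseq_qpcr_correlation(
    rnaseq_log2: Mapping[str, float], qpcr_log2: Mapping[str, float]
) -> CorrelationBattery:
    """Correlation battery between platform log2 fold changes on the genes
    shared by the RNA-seq and qPCR result sets."""
    shared = sorted(set(rnaseq_log2) & set(qpcr_log2))
    if len(shared) < 3:
        raise ValidationError("need >= 3 genes shared by both platforms")
    pairs = [
        HomologPair(
            seed_gene=g,
            seed_log2=float(rnaseq_log2[g]),
            partner_gene=g,
            partner_log2=float(qpcr_log2[g]),
            study_id="platform_comparison",
            species="",
            tissue="",
        )
        for g in shared
    ]
    return correlation_battery(pairs)
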