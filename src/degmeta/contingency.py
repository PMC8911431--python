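"""Directional 2x2 contrasts between animal lineages and human
hypertension effects, plus exact binomial direction tests.

Each domestication DEG (domestic vs wild contrast) is polarized: its log2
sign says which lineage shows downregulation relative to the most recent
common ancestor.  A curated annotation then says whether down- or
upregulation of the human homolog is hypertension-provoking or
-preventing, yielding a 2x2 table of lineage x human direction that is
tested with an exact-rational Fisher test, Pearson's chi-square (1 df, no
continuity correction by default), and exact binomial tails.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from typing import Literal, Optional, Sequence

from scipy import stats

from .records import (
    Contingency2x2,
    DegenerateInputError,
    DegRecord,
    DirectionalCounts,
    DivergencePolarity,
    ValidationError,
)

log = logging.getLogger(__name__)

Alternative = Literal["ge", "le", "two_sided"]


def polarize_divergence(record: DegRecord) -> DivergencePolarity:
    """Turn a domestic-vs-wild log2 fold change into which lineage shows
    downregulation: log2 < 0 means the domestic lineage does."""
    if record.log2 == 0:
        raise ValidationError(f"gene {record.gene!r} has log2 = 0; polarity undefined")
    return DivergencePolarity(
        gene=record.gene,
        lineage_down="domestic" if record.log2 < 0 else "wild",
    )


def build_2x2(
    polarities: Sequence[DivergencePolarity],
    human_direction: dict[str, str],
) -> Contingency2x2:
    """Cross lineage (rows: wild, domestic) with the human hypertension
    direction of the expression state each lineage shows (columns:
    hypertensive-concordant, normotensive-concordant).

    ``human_direction`` maps a gene or its family tag to the effect of
    DOWNregulation of the human homolog: "normotensive" or "hypertensive".
    Each gene record contributes one count for the downregulated lineage
    (with the annotated direction) and one for the other lineage (with the
    opposite direction).  Records without an annotation are excluded with
    a warning.
    """
    cells = {("wild", "hypertensive"): 0, ("wild", "normotensive"): 0,
             ("domestic", "hypertensive"): 0, ("domestic", "normotensive"): 0}
    for pol in polarities:
        direction = human_direction.get(pol.gene) or human_direction.get(pol.family)
        if direction is None:
            log.warning("no human-direction annotation for %r; excluded", pol.gene)
            continue
        if direction not in ("hypertensive", "normotensive"):
            raise ValidationError(f"bad annotation {direction!r} for {pol.gene!r}")
        opposite = "hypertensive" if direction == "normotensive" else "normotensive"
        up_lineage = "wild" if pol.lineage_down == "domestic" else "domestic"
        cells[(pol.lineage_down, direction)] += 1
        cells[(up_lineage, opposite)] += 1
    return Contingency2x2(
        a=cells[("wild", "hypertensive")],
        b=cells[("wild", "normotensive")],
        c=cells[("domestic", "hypertensive")],
        d=cells[("domestic", "normotensive")],
    )


def _hypergeom_pmf_exact(k: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(A = k) for a 2x2 table with row sums r1, r2 and first column sum c1."""
    return Fraction(
        math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(r1 + r2, c1)
    )


def fisher_exact(table: Contingency2x2) -> tuple[float, float]:
    """Fisher's exact test with rational hypergeometric arithmetic.

    Returns (one-sided p, two-sided p).  One-sided: the smaller of the two
    tail probabilities P(A <= a) and P(A >= a) at fixed margins.  Two-sided:
    the point-probability rule (sum of all tables whose probability does
    not exceed the observed one, with 1e-7 relative slack), as in
    mainstream statistics suites.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.n < 1:
        raise ValidationError("empty table")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: _hypergeom_pmf_exact(k, r1, r2, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    left = sum(pmf[k] for k in range(lo, a + 1))
    right = sum(pmf[k] for k in range(a, hi + 1))
    one_sided = min(left, right)
    cutoff = p_obs * (1 + Fraction(1, 10**7))
    two_sided = sum(p for p in pmf.values() if p <= cutoff)
    return float(min(one_sided, 1)), float(min(two_sided, 1))


def chi2_2x2(table: Contingency2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, 1 df, optional Yates correction.

    chi2 = n (|ad - bc| - [n/2 if yates]) ^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateInputError("zero marginal; chi-square undefined")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    chi2 = n * delta**2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def binomial_direction_test(
    k: int, n: int, alternative: Alternative = "two_sided"
) -> float:
    """Exact Binomial(n, 1/2) tail test for a directional count split.

    ``ge``: P(X >= k); ``le``: P(X <= k); ``two_sided``: 2 min(tails),
    capped at 1.  Integer-exact tail summation.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValidationError("need 0 <= k <= n and n >= 1")
    denom = 2**n
    ge = Fraction(sum(math.comb(n, j) for j in range(k, n + 1)), denom)
    le = Fraction(sum(math.comb(n, j) for j in range(0, k + 1)), denom)
    if alternative == "ge":
        return float(ge)
    if alternative == "le":
        return float(le)
    if alternative == "two_sided":
        return float(min(1, 2 * min(ge, le)))
    raise ValidationError(f"unknown alternative {alternative!r}")


def directional_acceptance_probability(counts: DirectionalCounts) -> float:
    """Probability of accepting H0: "affinity-increasing markers are not the
    minority", computed as 1 - P(X <= n_gt | n_res, 1/2).

    An interpretation of the genome-wide-norm comparison: high values mean
    the observed N> vs N< split is consistent with the genome-wide
    dominance of affinity-decreasing SNPs.
    """
    le = binomial_direction_test(counts.n_gt, counts.n_res, "le")
    return 1.0 - le


def equivalence_test(counts: DirectionalCounts) -> Optional[float]:
    """One-sided exact binomial test of H0: provoking and preventing
    markers are equivalent, using the smaller of the two direction counts.

    Returns P(X <= min(n_to_ht, n_from_ht) | n_res, 1/2), or None when the
    direction counts are not reported.
    """
    if counts.n_to_ht is None or counts.n_from_ht is None:
        return None
    k = min(counts.n_to_ht, counts.n_from_ht)
    return binomial_direction_test(k, counts.n_res, "le")
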