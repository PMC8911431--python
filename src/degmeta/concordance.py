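"""Analytical core: correlation battery, 2-D bootstrap PCA, and the
per-seed-gene sign-concordance exact binomial test.

The scientific question: do the log2 fold changes of stress-reactivity
DEGs (tame vs aggressive rat hippocampus) run opposite to the fold
changes of their homologs in hypertensive vs normotensive subjects?  On
standardized paired log2 values the answer lives in the 2x2 correlation
matrix [[1, r], [r, 1]], whose principal axes are the half-difference
(1,-1)/sqrt(2) and half-sum (1,1)/sqrt(2) of the two variables: with
r < 0 the difference axis carries the larger eigenvalue 1 - r.  Per seed
gene, the number of partners with opposite (n_pc1) versus matching
(n_pc2) log2 sign is tested against Binomial(n, 1/2) with the one-sided
tail on the larger count, Bonferroni-corrected across seed genes.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    CorrelationBattery,
    DegenerateInputError,
    DegRecord,
    HomologPair,
    PcaResult,
    SignConcordanceRow,
    ValidationError,
)

__all__ = [
    "correlation_battery",
    "goodman_kruskal_gamma",
    "pca_2d_bootstrap",
    "binomial_sign_test",
    "binomial_sign_test_exact",
    "bonferroni",
    "sign_concordance_table",
]


def goodman_kruskal_gamma(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Goodman-Kruskal gamma = (C - D) / (C + D) over all unordered pairs,
    with ties in either variable dropped from both counts.

    The p-value uses the standard asymptotic statistic
    z = gamma * sqrt((C + D) / (n (1 - gamma^2))) against a two-sided
    normal reference.  Vectorized O(n^2) pair comparison.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < 3:
        raise ValidationError("gamma needs n >= 3")
    dx = np.sign(xa[:, None] - xa[None, :])
    dy = np.sign(ya[:, None] - ya[None, :])
    prod = dx * dy
    iu = np.triu_indices(n, k=1)
    c = int(np.sum(prod[iu] > 0))
    d = int(np.sum(prod[iu] < 0))
    if c + d == 0:
        raise DegenerateInputError("all pairs tied; gamma undefined")
    gamma = (c - d) / (c + d)
    if abs(gamma) >= 1.0:
        return gamma, 0.0
    z = gamma * math.sqrt((c + d) / (n * (1.0 - gamma**2)))
    return gamma, float(2.0 * stats.norm.sf(abs(z)))


def correlation_battery(pairs: Sequence[HomologPair]) -> CorrelationBattery:
    """Pearson r, Spearman R, Kendall tau-b and Goodman-Kruskal gamma (with
    p-values) over the (seed_log2, partner_log2) columns of ``pairs``."""
    if len(pairs) < 3:
        raise ValidationError("correlation battery needs >= 3 pairs")
    x = np.array([p.seed_log2 for p in pairs])
    y = np.array([p.partner_log2 for p in pairs])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input; correlations undefined")
    r, r_p = stats.pearsonr(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    tau, tau_p = stats.kendalltau(x, y)  # tau-b; exact p for small tie-free n
    gamma, gamma_p = goodman_kruskal_gamma(x, y)
    return CorrelationBattery(
        r=float(r),
        r_p=float(r_p),
        spearman=float(rho),
        spearman_p=float(rho_p),
        tau=float(tau),
        tau_p=float(tau_p),
        gamma=gamma,
        gamma_p=gamma_p,
        n=len(pairs),
    )


def _eigen_2x2(r: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigendecomposition of [[1, r], [r, 1]].

    Returns (eigenvalues descending, loadings rows=components).  The
    eigenvalues are 1+r (sum axis) and 1-r (difference axis); ties (r = 0)
    put the difference axis first by convention.  First nonzero loading of
    each component is made positive.
    """
    s = 1.0 / math.sqrt(2.0)
    diff = np.array([s, -s])
    summ = np.array([s, s])
    if r > 0:
        vals = np.array([1.0 + r, 1.0 - r])
        vecs = np.vstack([summ, diff])
    else:
        vals = np.array([1.0 - r, 1.0 + r])
        vecs = np.vstack([diff, summ])
    return vals, vecs


def pca_2d_bootstrap(
    pairs: Sequence[HomologPair],
    n_boot: int = 999,
    seed: int = 0,
) -> PcaResult:
    """Correlation-mode PCA of the paired log2 values with bootstrap
    percentile intervals on the loadings.

    The point estimate is the closed-form eigendecomposition of the 2x2
    sample correlation matrix.  Each bootstrap replicate resamples pairs
    with replacement, recomputes the decomposition, aligns eigenvector
    signs to the point estimate by dot product, and the 2.5/97.5
    percentiles of the aligned loadings form the intervals.
    """
    if len(pairs) < 3:
        raise ValidationError("PCA needs >= 3 pairs")
    x = np.array([p.seed_log2 for p in pairs])
    y = np.array([p.partner_log2 for p in pairs])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        import warnings

        warnings.warn("|r| = 1: correlation matrix is rank-deficient")
    vals, vecs = _eigen_2x2(r)

    rng = np.random.default_rng(seed)
    n = len(pairs)
    boot = np.empty((n_boot, 2, 2))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            boot[b] = vecs  # degenerate resample: fall back to point estimate
            continue
        rb = float(np.corrcoef(xb, yb)[0, 1])
        _, vb = _eigen_2x2(rb)
        for comp in range(2):
            if float(vb[comp] @ vecs[comp]) < 0:
                vb[comp] = -vb[comp]
        boot[b] = vb
    low = np.percentile(boot, 2.5, axis=0)
    high = np.percentile(boot, 97.5, axis=0)

    to_t = lambda m: tuple(tuple(float(v) for v in row) for row in np.atleast_2d(m))
    return PcaResult(
        loadings=to_t(vecs),
        eigenvalues=(float(vals[0]), float(vals[1])),
        bootstrap_low=to_t(low),
        bootstrap_high=to_t(high),
        n_boot=n_boot,
        seed=seed,
        r=r,
    )


def binomial_sign_test_exact(n_pc1: int, n_pc2: int) -> Fraction:
    """Exact rational tail P(X >= max(n_pc1, n_pc2)) for X ~ Bin(n, 1/2)."""
    if n_pc1 < 0 or n_pc2 < 0:
        raise ValidationError("counts must be non-negative")
    n = n_pc1 + n_pc2
    if n < 1:
        raise ValidationError("both counts zero: test undefined (ND)")
    k = max(n_pc1, n_pc2)
    num = sum(math.comb(n, j) for j in range(k, n + 1))
    return Fraction(num, 2**n)


def binomial_sign_test(n_pc1: int, n_pc2: int) -> float:
    """One-sided exact binomial sign test on the larger count.

    p = P(X >= max(n_pc1, n_pc2)) with X ~ Binomial(n_pc1 + n_pc2, 1/2),
    computed by exact integer tail summation; symmetric in its arguments.
    """
    return float(binomial_sign_test_exact(n_pc1, n_pc2))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, p * m)."""
    if not (0.0 < p <= 1.0):
        raise ValidationError("p must lie in (0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return min(1.0, p * m)


def sign_concordance_table(
    seed: Sequence[DegRecord],
    pairs: Sequence[HomologPair],
    m: Optional[int] = None,
) -> list[SignConcordanceRow]:
    """Per seed gene, count partners with opposite (n_pc1) vs matching
    (n_pc2) log2 sign and attach the exact binomial p with Bonferroni
    adjustment.

    Partners with log2 exactly 0 have no sign; they are excluded from both
    counts and reported in ``n_excluded_zero``.  Seed genes without
    partners get an ND row (p and p_adj are ``None``).  The Bonferroni
    multiplier defaults to the number of seed genes in the table, ND rows
    included.  Rows are returned in seed-list order.
    """
    seed_sign: dict[str, int] = {}
    for rec in seed:
        if rec.log2 == 0:
            raise ValidationError(f"seed gene {rec.gene!r} has log2 = 0; sign undefined")
        seed_sign[rec.gene] = 1 if rec.log2 > 0 else -1

    counts: dict[str, list[int]] = {g: [0, 0, 0] for g in seed_sign}
    for pair in pairs:
        if pair.seed_gene not in seed_sign:
            raise ValidationError(
                f"pair references unknown seed gene {pair.seed_gene!r}"
            )
        tallies = counts[pair.seed_gene]
        if pair.partner_log2 == 0:
            tallies[2] += 1
        elif (pair.partner_log2 > 0) == (seed_sign[pair.seed_gene] > 0):
            tallies[1] += 1  # matching sign -> n_pc2
        else:
            tallies[0] += 1  # opposite sign -> n_pc1

    multiplier = m if m is not None else len(seed_sign)
    rows = []
    for rec in seed:
        n1, n2, nz = counts[rec.gene]
        if n1 + n2 == 0:
            p = p_adj = None
        else:
            p = binomial_sign_test(n1, n2)
            p_adj = bonferroni(p, multiplier)
        rows.append(
            SignConcordanceRow(
                gene=rec.gene, n_pc1=n1, n_pc2=n2, p=p, p_adj=p_adj,
                n_excluded_zero=nz,
            )
        )
    return rows
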