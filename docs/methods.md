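# Methods

`degmeta` implements a cross-study meta-analysis that asks whether genes
whose expression tracks stress reactivity in the rat hippocampus (tame vs
aggressive outbred lines) change in the *opposite* direction in
hypertensive vs normotensive subjects, and whether the same directional
pattern separates domestic animals from their wild congeners.  The unit
of analysis is a published per-study DEG record — gene symbol, log2 fold
change, significance — not raw reads; everything upstream of the DEG
tables (alignment, counting, dispersion modeling) is out of scope.

## Homolog pairing

Family-level homology (rat *Hbb-b1* vs human *HBA1*, say) cannot be
recovered from symbols, so a curated homolog map is a first-class input.
A pair is emitted for every map entry whose seed and partner both occur
as DEGs, once per partner study-tissue record, plus exact
normalized-symbol matches as a fallback (on by default).  Symbol
normalization is deliberately minimal — strip and upper-case — because
anything cleverer silently invents homology.  Output is sorted and
deduplicated on (seed, partner, study, tissue), so shuffled inputs give
identical results.

## Correlation battery and principal components

On the paired log2 values the package reports Pearson r, Spearman R,
Kendall tau-b (all via scipy, which supplies the usual t-, permutation-
and normal-approximation p-values) and Goodman–Kruskal gamma, computed
in-house as (C − D)/(C + D) over all unordered pairs with ties dropped,
with the asymptotic significance z = gamma·sqrt((C + D)/(n(1 − gamma²))).
Tau-b is used because it is the default of mainstream statistics suites;
gamma's O(n²) pair enumeration is vectorized and is checked in the tests
against an independently written loop oracle.

Correlation-mode PCA of two standardized variables is fully determined
by the sample correlation r: the 2×2 correlation matrix [[1, r], [r, 1]]
has eigenvalues 1 − r and 1 + r with eigenvectors (1, −1)/√2 and
(1, 1)/√2.  With r < 0 the *half-difference* of the two fold changes is
the leading component and the *half-sum* the second — the structure the
sign-concordance counts are named after.  The closed form is used
directly (and verified against `numpy.linalg.eigh` to 1e-10); ties at
r = 0 put the difference axis first by convention, and each component's
first nonzero loading is made positive.  Bootstrap intervals resample
pairs with replacement (default 999 replicates, seeded), sign-align each
replicate's eigenvectors to the point estimate by dot product, and take
2.5/97.5 loading percentiles.

## Sign concordance

Per seed gene, partners are counted by log2 sign: opposite to the seed
(n_pc1) or matching (n_pc2).  Partners with log2 exactly 0 have no sign;
they are excluded from both counts and reported separately (the
continuous generators never produce them, but real tables can).  The
test is the exact one-sided binomial tail on the larger count,
p = P(X ≥ max(n_pc1, n_pc2)) for X ~ Binomial(n_pc1 + n_pc2, ½),
computed in integer/rational arithmetic (no normal approximation at any
n), Bonferroni-multiplied by the number of seed genes in the table — ND
rows included, 42 for the packaged tables — and capped at 1.  The
max-tail rule is the one that reproduces the published two-decimal
p-values from their printed counts for every testable row but one
(printed 0.83 for a (7, 5) split whose max-tail value is 0.387; left as
a documented discrepancy, not modeled).  Seed genes with no partners
yield ND rows with no p-value rather than a placeholder number.

## Directional 2×2 contrasts

A domestic-vs-wild DEG's log2 sign says which lineage shows
downregulation.  A curated annotation gives, per gene, the human
hypertension direction of downregulation of its homolog
("normotensive" = hypertension-preventing).  Crossing lineage with
direction (each record contributes its down-lineage cell and the
opposite cell for the other lineage) yields a 2×2 table tested three
ways: Fisher's exact test in rational hypergeometric arithmetic
(one-sided = smaller tail; two-sided = point-probability rule with 1e-7
relative slack, matching mainstream suites), Pearson's chi-square with
1 df and no continuity correction by default (the Yates-corrected value
is available but is not the published statistic), and exact
Binomial(n, ½) row tails.  The candidate-SNP direction counts are
consumed as given; the "equivalence" test on provoking vs preventing
markers is the exact lower tail at the smaller count, and the
neutral-drift acceptance probability is reported as
1 − P(X ≤ N> | n, ½), clearly an interpretation since no formula is
published for it.

## qPCR summarization

Relative expression is the efficiency-weighted quantity E_t^(−Cq_t)
over the geometric mean of the reference-gene quantities (the
multi-reference recommendation gives no formula; the geometric mean is
the standard choice), optionally divided by a calibrator sample —
a common Cq shift then cancels exactly.  Per animal, technical
replicates give M0 ± SEM; per group, the mean of per-animal M0 values.
The packaged per-animal table stores printed M0 summaries (raw
replicates are unpublished), and its one ND cell is treated as missing,
shrinking that animal's group to n = 7.  The published group dispersions
(e.g. ±1.71) are not reproducible from the per-animal means by SD, SEM
or pooled-replicate formulas; the package reports the SD of per-animal
means and flags the difference.  Groups are compared with a Mann–Whitney
U test whose null distribution is exact — computed by the classical
count recurrence f(i, j, u) = f(i, j−1, u) + f(i−1, j, u−j) — for
tie-free samples up to a combined n of 25, with a tie-corrected normal
approximation beyond; two-sided p is twice the smaller tail, capped
at 1.

## DE stage

The DE stage operates on a gene × sample matrix with two groups.
Samples are scaled to counts per million by default; DESeq-style
median-of-ratios size factors are available (`normalize="median_ratio"`)
because total-count scaling is composition-biased — in a simulation
where a tenth of genes change 16-fold, CPM produced dozens of spurious
calls that median-of-ratios removed entirely.  Per gene the statistic is
z = (mean log2(A + pc) − mean log2(B + pc)) / sqrt(SE_A² + SE_B²) with
unpooled SEs and pseudocount 0.5 (configurable).  The reference
distribution is Student t with Welch–Satterthwaite degrees of freedom:
with three samples per group the naive standard-normal reference is
anti-conservative (measured type-I error 0.12 at nominal 0.05 over 5000
null simulations, versus 0.036 for the t reference), and calibration was
judged more important than the large-sample form, which remains
available as `reference="normal"`.  P-values are Benjamini–Hochberg
adjusted across genes (statsmodels), and placeholder symbols
(LOC*/RGD* prefixes, "predicted", "hypothetical", "uncharacterized",
"tentative", "-ps" suffixes, or a non-protein-coding biotype when
annotated) are discarded before thresholding.  Genes with zero pooled SE
and unequal means are degenerate for this statistic and are excluded
from both the p-value family and the calls.

## Synthetic data

The generators produce inputs with the statistical structure the
analysis assumes, at the study's own design sizes: 151 homolog pairs at
Pearson rho = −0.29 from a zero-mean bivariate normal (|rho| = 1 handled
as an exact linear relation); 42 seed genes with 1–10 family partners
and a plantable fraction of fully sign-discordant families; 3-vs-3
negative-binomial counts (variance mu + phi·mu²) with planted log2
effects; and 8-vs-8 qPCR animals with lognormal animal- and
replicate-level noise around a multiplicative group effect.  All
generators take an explicit integer seed and share no global state.

Free parameters were fixed once: sigma_log2 = 2.5 (the spread of the 42
published hippocampal log2 values), nb_mean = 100 and dispersion 0.1
(typical bulk RNA-seq), qpcr_effect = 9.3 (the observed tame/aggressive
group-mean ratio of the strongest verified gene), frac_discordant = 0.5.
The bivariate normal is a modeling assumption — only the observed
correlations are published, not the joint distribution — and the
generators emulate summary-level structure only: no read-level data, no
between-study heterogeneity, no dependence between partners of one seed
gene.  Passing tests therefore demonstrate that the statistical
machinery is correct on data satisfying its assumptions, not that real
cross-study tables satisfy them.

## Calibration and frozen regression values

Measured during the build and frozen in the tests (not re-tuned since):
mean sample Pearson r over 1000 simulated 151-pair replicates at
rho = −0.29 is within ±0.01 of the target; the DE-stage type-I error at
3 vs 3 on normal data is within ±0.02 of nominal 0.05 over 2000
simulations; planted-DEG recovery at |log2| = 4, dispersion 0.05,
3 vs 3 with BH at 0.05 measured 0.80 over 30 seeds (0.85 on the frozen
test seeds; floor asserted at 0.75).  Under the anti-conservative normal
reference the same recovery is ~1.0 — the calibrated test pays for its
honesty with power at n = 3.

## Problem sizes

Test-suite simulations use 100–500 genes, ≤ 2000 replicates and ≤ 1000
bootstrap or simulation repetitions; the acceptance script uses the
same sizes.  These are the package's own choices for a desk-scale,
deterministic analysis: every published worked example it reproduces is
exact at these sizes, and the stochastic calibration checks have
standard errors comfortably inside their asserted bands.

## Known limitations

Published DEG tables enter as fixed inputs; no effect-size shrinkage,
heterogeneity modeling or publication-bias correction is attempted —
the meta-analysis is a sign-level synthesis by design.  The Bonferroni
multiplier counts ND rows, which is conservative.  The homolog map
covers the two gene families with published partner tables; the full
cross-study pair set is exercised synthetically.  The exact Fisher and
binomial routines use exact integer arithmetic and are practical to a
few hundred observations, far beyond any table this analysis meets.
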