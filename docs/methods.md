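# Methods

## Count model and the exact test

Read counts for gene g in sample s are modelled as negative binomial with
mean μ_gs and dispersion φ, Var = μ + φμ² (φ = 0 is Poisson).  A single φ is
shared across genes, which is the workable choice at 2–3 replicates per
group; per-gene method-of-moments estimates are available
(`estimate_common_dispersion(..., per_gene=True)`) but are noisy at these
replicate numbers and are not used by default.

Library sizes differ between samples, so before testing, counts are scaled
to the geometric mean library size of the samples involved and rounded
half-even ("pseudo-counts").  This equalization is an approximation: the
scaled values are treated as NB counts at a common library size even though
scaling changes the noise properties slightly.  The payoff is that with
equal per-sample means under the null, the group sums A and B are NB with a
shared success probability, and the conditional distribution of A given
T = A + B is free of the unknown mean:

    P(A = k | T) ∝ C(k + r_a − 1, k) · C(T − k + r_b − 1, T − k),
    r_a = n_a/φ,  r_b = n_b/φ,

a negative-hypergeometric form enumerated exactly over k = 0..T.  The
two-sided p-value is the minimum-likelihood rule — the sum of P(k | T) over
all splits with P(k | T) ≤ P(A | T) — which handles the asymmetry of skewed
conditional distributions; a doubled-tail rule is available via
`two_sided_rule="doubling"`.  Ties in split probability (exactly symmetric
layouts) are compared with a 1e-10 log-space tolerance so floating-point
jitter cannot drop the mirror split.  When every split qualifies (the
observed split is modal) the p-value is exactly 1.  Probabilities are
accumulated in log space; totals larger than 2^20 switch to a chunked
two-pass log-sum-exp so memory stays bounded.

The common dispersion maximizes the summed conditional log-likelihood of the
within-group splits given each group's total (the classic conditional
approach for small-replicate count data), optimized by bounded Brent on
φ ∈ [0, 10] with the φ → 0 Poisson/multinomial limit evaluated analytically
at the boundary; an estimate that does not beat the boundary is snapped to
0.  Simulation recovery: Poisson data yield φ̂ ≤ 0.02 and φ = 0.2 data yield
φ̂ ∈ [0.15, 0.25] at 500 genes, 3 vs 3.

Multiple testing uses Benjamini–Hochberg step-up adjustment
(statsmodels' `fdr_bh`).  `de_compare` reports log2 fold changes of group
mean CPM with pseudocount 0.5 (so zero-count groups stay finite) and flags
significance as FDR < α together with |log2FC| above a floor — defaults
α = 0.001 with |log2FC| ≥ 1 for time-course DE lists; the inheritance
contrasts use α = 0.01 with no fold-change floor.

## Inheritance classification

"H ≈ P" is operationalized as "H vs P not significant at FDR α"; "H above /
below P" as significant with the corresponding fold-change sign.  The
decision table (evaluated in order) is: nothing significant → conserved;
H differs from both parents in the same direction → over-/underdominant;
H differs from both in opposite directions *and* the parents differ →
additive; H matches exactly one parent and differs from the other →
dominant toward the matching parent; everything else → ambiguous (notably
the pattern "parents differ but H matches both", which no category fits).
The table is total and single-valued over all 2³ × 3² flag/direction
combinations.

Two deliberate design points.  First, additive calls require the parental
contrast to be significant even in the default "literal" rule, because
"P1 < H < P2" presupposes distinguishable parents.  Second, the literal rule
does *not* require parental significance for dominant calls — the category
definitions don't mention it — but that makes "P1-dominant" possible with
indistinguishable parents, so a "strict" rule that routes such genes to
ambiguous is provided (`rule="strict"`).

F1 samples are pooled into one hybrid group by default (`f1="pooled"`);
`f1="per_f1"` classifies each F1 genotype separately, in which case the
per-time-point summary averages class counts across genotypes (the family
average).  Chromosome summaries sort each chromosome's genes by start
position and cut them into 12 contiguous bins of near-equal gene count
(sizes differ by ≤ 1, the larger bins first); equal-width binning by
physical span is available by flag since "equal bins" is ambiguous between
the two readings.

Before classification, genes are expression-filtered: CPM > 1 in at least
50% of samples (the permissive variant 0.5 / 30% is reachable through
parameters), with a separate count-level filter (< 5 reads in ≥ 80% of
libraries) intended ahead of co-expression work.  Both thresholds are read
strictly (< and >).  Library sizes are fixed at first read as column sums
and are *not* recomputed after filtering, so filtering never changes CPM
values; a flag recomputes them when that is wanted.

## Association

Traits are genotype-level means, so expression is summarized as the mean
log2(CPM + 1) per genotype (optionally one time point) before a simple
linear regression of trait on expression.  The per-gene score is
R² × −log10(p) with p from the two-sided t test on n − 2 df, floored at
1e-300 to keep the score finite; zero-variance inputs yield a degenerate
record with score 0 instead of failing the batch.  (R² is already
nonnegative, so taking its absolute value is a no-op.)  The genome-wide
threshold is Bonferroni in score units, −log10(α/n genes), with α = 0.05;
a gene passes when score ≥ threshold.

A module eigengene is the first principal component of the module's
gene-wise z-scored expression across samples, computed by SVD, oriented so
the mean correlation with member genes is nonnegative (tie broken by the
first member gene) and scaled to unit standard deviation — a module of
identical profiles therefore returns exactly the shared z-scored profile
with variance_explained = 1.  Constant member genes are dropped; an
all-constant module is an error.  Module–trait correlation is Pearson on
genotype-mean eigengene values.  Module *construction* (network building,
tree cutting) is out of scope: module assignments are an input.

## The synthetic family

`simulate_family` emulates the targeted study design: 2 parents + 7 F1
genotypes, time points 0/6/24/96 h, 3 replicates, NB counts with φ = 0.05,
library sizes log-normal with mean 6,384,059 reads and sdlog 0.18 (spanning
roughly the 4.3–9.2 million range such experiments report), gene positions
uniform over 19 chromosomes of 18 Mb with gene lengths 0.3–5 kb, baseline
expression log-normal with median 200 CPM and sdlog ≈ 0.7 on the log2-CPM
scale.  Non-conserved genes split the parents ±1 log2 unit around baseline
(parental |log2FC| = 2); dominant genes set μ_H to one parent's mean,
additive genes to the arithmetic mid-parent, transgressive genes 1 log2
unit beyond the parental range.  Class counts follow the requested
proportions exactly (largest-remainder allocation, then a seeded
interleaving across the genome), so recovery tests have exact denominators.
Default proportions are 55% conserved, 15% per dominant class, 5% each for
additive and the two transgressive classes — dominance-heavy, as hybrid
expression studies typically find.

The causal module comprises conserved genes sharing a genotype-level
activity factor (N(0,1) per genotype, loading 0.5 on the log2 scale);
`simulate_traits` computes the module eigengene from the realized counts,
averages it per genotype and sets trait = effect × eigengene + N(0, σ),
defaults effect 1.0 and σ 0.25.  One root seed spawns named substreams
(classes, means, positions, library sizes, counts, module, traits), so runs
are byte-reproducible and components can be regenerated independently.

What the generator does *not* emulate: batch effects, GC/length bias,
sample-to-sample dispersion heterogeneity, correlated time-course dynamics
(time points are i.i.d. redraws unless `time_varying_classes` reshuffles the
planted classes), allelic mapping bias, or outlier libraries.  Passing
recovery tests therefore demonstrates correctness of the statistics under
the stated model, not robustness to those real-data artifacts.

## Problem sizes and measured behaviour

The verification suite works at deliberately compact sizes: exhaustive
exact-test checks for all totals ≤ 40 across layouts {1v1, 2v2, 2v3} and
φ ∈ {0, 0.1, 0.5} against a brute-force oracle that builds group pmfs by
numerical convolution (agreement ~3e-14, asserted at 1e-10); a 2000-gene
3v3 null at φ = 0.1 (p < 0.05 fraction observed ≈ 0.049, asserted within
[0.03, 0.07]; BH discoveries ≤ 3); a 1200-gene equal-proportion family for
class recovery (accuracy ≈ 96%, conserved recall ≈ 98–99%, false-conserved
0%, asserted at ≥ 80% / ≥ 95% / ≤ 5%); and a 500-gene, 9-genotype
association design with a 30-gene causal module (top gene in module; null
effect passes the threshold in ≤ 10% of 100 runs).
`scripts/acceptance.py` recomputes all of these from a single seed.

## Limitations

* The library-size equalization (geometric-mean pseudo-counts, half-even
  rounding) is a simple stand-in for quantile-based equalization; p-values
  on strongly unequal libraries are approximate at low counts.
* A common dispersion underestimates uncertainty for genes that are more
  variable than average; the exact test is also mildly conservative on
  discrete totals (null rejection ≈ 4.9% at nominal 5%).
* Classification accuracy is bounded by test power: additive genes whose
  mid-parent level sits within noise of one parent are the dominant error
  mode at 3 replicates.
* Association uses marginal per-gene regressions; it makes no claim of
  conditional independence or causal direction.
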