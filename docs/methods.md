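# Methods

## Setting and model

The pipeline analyses a small clinical cohort (n = 16 in the packaged
table) with a genes × samples matrix of library-size-normalized expression
(CPM). All inference is per-gene and univariate; no count model is fitted
because the inputs are already normalized. Three facts shape every design
choice:

1. onset age + disease duration ≈ age at sampling, so duration and age are
   strongly rank-correlated (ρ ≈ 0.81 in the packaged cohort) and any gene
   tracking age will masquerade as a duration gene;
2. at n = 16 only rank statistics and small-sample-aware approximations are
   trustworthy;
3. every threshold (CPM 1, 50 % detection, p 0.05, |log₂FC| 0.5, |ρ| 0.5,
   duration 20 y, onset 12 y) is configuration, not code.

## Preprocessing

Genes are kept when CPM exceeds the detection threshold (strict `>` by
default; `>=` selectable since published gene counts can hinge on the
boundary operator) in at least ⌈f·n⌉ samples, f = 0.5. The pseudocount is
min(nonzero CPM)/1000, computed on the filtered matrix (the processing
order filters first; a flag computes it on the full matrix). Values become
log₂(CPM + c). The log base is irrelevant to every rank-based statistic
downstream and uniformly rescales t statistics; base 2 keeps fold changes
in conventional units.

## Group comparison

The clinical comparison applies a two-sided Mann–Whitney U test with
midranks, the tie-corrected variance
σ² = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))], a 0.5 continuity correction
toward the null mean n₁n₂/2, and the standard-normal tail. This exact
variant was fixed because it reproduces all six printed p-values of the
reference clinical tables from the packaged cohort to their printed
precision, whereas e.g. Welch's t gives ≈ 0.002 for the age comparison.
An exact enumeration of the permutation distribution of U over all
C(n, n₁) assignments is available (`method="exact"`); on tie-free 8 vs 8
data the normal approximation stays within ≈ 0.011 of it. When all values
coincide, p = 1 by convention.

Descriptive statistics use the n−1 standard deviation. Gender is reported
as counts only; seizure burden is dichotomized at 2 seizures/month (≤ 2
low, > 2 high).

## Differential expression

log₂FC is the difference of group means of log₂(CPM + c) — the log of a
ratio of geometric means, not of arithmetic means. The default per-gene
test is Welch's unequal-variance t on log₂ values; the rank-sum variant is
available. Volcano labels use strict inequalities (p < 0.05 and
|log₂FC| > 0.5). Raw p-values drive the labels, matching the screening
character of the analysis; Benjamini–Hochberg values can be added but are
not applied by default. When both groups have zero variance, p = 1 if the
means agree (no evidence) and 0 otherwise (infinite t). On spike-free
simulated data the fraction of genes with p < 0.05 is ≈ 0.05 (checked
within three binomial standard errors on ~2000 genes).

## Correlation screening

Spearman's ρ is the Pearson correlation of midranks; two-sided p from
t = ρ√((n−2)/(1−ρ²)) with n−2 df. At n = 16 this approximation stays
within 0.003 of a 10⁵-permutation p-value for |ρ| ≤ 0.9. A gene is flagged
when |ρ| > 0.5 and p < 0.05 jointly. At n = 16 the joint rule is dominated
by the |ρ| > 0.5 clause and its intrinsic null rate is ≈ 4.9 % (exact
permutation null of |ρ| > 0.5) — a screening, not a discovery, threshold.
Zero-variance vectors yield an undefined-ρ marker with p = 1 and are never
flagged. Traits enter in raw years; expression may be CPM or log scale
(identical ranks — asserted by test).

Genes on a user-supplied age-associated list are marked and removed from
the reported view only; the full record set is always retained.

## Partial correlation

Expression of each gene and the trait are each regressed by OLS on an
intercept, age at sampling, gender and etiology (indicator columns, most
frequent level as reference — "Unk" dominates etiology in the packaged
cohort), and the residual vectors are Spearman-correlated. Rank-deficient
designs fall back to minimum-norm least squares with a warning. The
p-value keeps n−2 df by default, because the procedure is plain Spearman
applied to residuals; a covariate-adjusted df variant (n−2−q) is behind a
flag and is uniformly more conservative.

Two numerical caveats are handled explicitly. First, a variable that is an
exact linear function of the covariates leaves only ~10⁻¹⁵ floating-point
noise as residual; such residual vectors are flattened to zero (undefined
ρ, unflagged) rather than ranked. Second, with 16 samples and up to seven
design columns — including singleton etiology indicators that pin their
sample's residual to exactly zero — residual rank correlations are
noticeably inflated relative to the nominal null (the adjusted screen's
null flag rate runs near 11 % rather than 5 %). The partial screen is
therefore a confound-removal device, not a calibrated test: in the default
simulation it cuts the flagged rate of purely age-driven genes from 90 %
to 15 % while spiked duration genes remain recovered. Partial correlation
is *not* invariant to monotone transforms of expression (residualization
precedes ranking); this is asserted by a test.

## Band enrichment

For a list of n genes from an annotated universe of N with K on a band,
p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n) (hypergeometric upper tail), BH
adjusted across all bands with K ≥ 1. Genes map to exactly one band.
List genes outside the universe and unannotated universe genes are dropped
with warnings. The tail probability is verified against direct pmf
summation and a resampling null in the tests.

## Synthetic data

The generator emulates the structure the analysis assumes, not raw-count
realism: per gene, log₂ expression = baseline + β·driver + ε with
ε ~ N(0, noise_sd), driver ∈ {duration, onset age, age} per class,
β = ±effect for spiked classes and 0 for nulls; the matrix is exported as
2^log₂ (strictly positive CPM-like values), so the pseudocount path is
exercised. Defaults: 2000 genes, 20 per spiked class, effect 0.05 log₂
units/year, noise 0.5 log₂ units, baselines N(5, 2) — placing spiked genes
near |ρ| ≈ 0.85 at n = 16, strong enough for stable recovery yet leaving
the joint threshold non-trivial. Random cohorts draw age ~ U[16, 62],
onset ~ U[1, age−3], duration = age − onset (reproducing the natural
age–duration entanglement), gender Bernoulli(1/2), etiology from the
packaged table's empirical frequencies, seizure frequency log-uniform on
[0.25, 60]. Everything is deterministic given a seed.

What the generator does *not* emulate: library-size/batch effects,
count-level (negative binomial) noise, cell-type composition shifts,
correlated gene modules, and medication effects. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed signal model, not performance on real blood transcriptomes.

## Problem sizes in tests

The test-suite simulations use the generator defaults (2000 genes, the
16-sample packaged cohort); oracle comparisons use 100 datasets for the
rank-sum check, 10⁵ permutations per Spearman check, and 10⁴ resampling
draws for enrichment — sizes at which the Monte-Carlo standard errors are
well below the tolerances being asserted.

## Known limitations

* The Mann–Whitney continuity-corrected normal approximation is anti-
  conservative for very small groups (< 5 per group); use the exact mode.
* The partial screen's inflated null rate at n = 16 with many covariate
  levels (above) means its flag counts are not comparable to the plain
  screen's.
* The age/duration disentanglement relies on linear covariate effects in
  the residualization; nonlinear age effects would leak through.
* The packaged clinical fixture records one patient's gender as female
  based on the cohort's published group counts and an etiology only
  coherent for a female patient; all published summary statistics
  reproduce under this reading.
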