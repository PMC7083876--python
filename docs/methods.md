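# Methods

This note documents the models implemented in `demosat`, the defaults and
why they were chosen, the numerical details that affect results, and the
limits of what the synthetic tests demonstrate.

## Coalescent model

Each locus is an independent realisation of the single-population Kingman
coalescent with piecewise-constant diploid effective size `Ne(t)` on a
backwards generation axis (time 0 = present).  With `k` ancestral lineages
the waiting time to the next coalescence is exponential with rate
`k(k-1)/(4*Ne(t))`; waiting times are carried across epoch boundaries using
the memoryless property (equivalent to the usual time-rescaling argument),
which the test suite verifies against the closed-form piecewise-exponential
distribution of pairwise coalescence times.  Two demographic shapes are
used throughout:

* **bottleneck** — three epochs `(0, Ne_cur)`, `(t_bot_end, Ne_bot)`,
  `(t_bot_start, Ne_hist)`; the bottleneck occupies
  `[t_bot_end, t_bot_start]` generations before present;
* **non-bottleneck** — two epochs `(0, Ne_cur)`, `(t_hist, Ne_hist)`.

The continuous-time approximation (rather than discrete Wright–Fisher
generations) matches standard coalescent simulators and is accurate for the
sample and population sizes used here; agreement with an independent
coalescent implementation (msprime) is asserted in the tests at Ne = 100,
n = 20, to within Monte-Carlo error.

## Mutation model

Microsatellite mutations occur along branches as a Poisson process with
rate `mu` per locus per generation.  Every mutation shifts the allele by a
positive integer number of repeat units with equiprobable sign.  The
magnitude law is a two-component mixture: single-step with probability
`1 - p_multistep`, otherwise `1 + G` with `G` geometric.  Two presets
cover the models used in the analysis:

* **GSM** — the geometric parameter equals `p_multistep` (= `GSMpar`), so
  the overall law is `P(|S| = s) = (1 - p) p^(s-1)` and `GSMpar` is exactly
  the proportion of multistep mutations.
* **TPM80** — 80% single-step mutations; the multistep magnitude's
  geometric parameter is set so that the variance of the multistep size
  equals `variance_target` (default 30, the customary default of the
  classical bottleneck-testing software; configurable).

Allele sizes are unbounded (no range constraint); the M-ratio remains
computable because it only uses the observed size range.  The ancestral
(root) allele is fixed at 50 repeat units — an arbitrary origin, since all
statistics computed by the package are invariant to translation of allele
sizes (asserted by property tests).  Simulated gene copies are paired
sequentially into diploids; under random mating any pairing is
exchangeable, and the statistics used do not depend on it.

The Ohta–Kimura equilibrium identity `E[He] = 1 - 1/sqrt(1 + 8*Ne*mu)`
(single-step model) is used as a closed-form oracle in the tests.

## Summary statistics

All statistics drop missing gene copies locus-wise and renormalise
frequencies.  Expected heterozygosity is the unbiased estimator
`n/(n-1) * (1 - sum p_i^2)` over `n` gene copies; `Fis = 1 - Ho/He`
(0 where `He = 0`) — the estimator behind the published tables is not
stated, so this direct definition was chosen and is documented here.
Rarefied allelic richness uses the exact hypergeometric expectation
`A_r = sum_i [1 - C(N-N_i, g)/C(N, g)]`.  The "proportion of low-frequency
alleles" counts alleles at strictly < 5% frequency (the 1/20 cut is
evaluated in integer arithmetic to avoid ties being decided by floating
point).  Pairwise F_st is Weir & Cockerham's theta, summed over alleles
and loci as a ratio of variance components, with percentile bootstrap over
loci for confidence intervals.

The ABC summary vector is (mean allele count per locus, mean proportion of
<5% alleles, mean M-ratio).  The first component is deliberately the raw
allele count, not a rarefied value: simulated reference datasets are
generated at the same sample size as the target, so rarefaction would be a
no-op.  When an observed population is larger than the reference-table
sample size, a seeded random subsample of that size is taken before
computing the target (the choice mirrors simulating at the smallest
population's size).

## Heterozygosity-excess test

For each polymorphic locus with `n` copies and `k` alleles, the package
simulates equilibrium (constant-size) coalescent loci under the chosen
mutation model, conditioned on exactly `k` alleles, and compares observed
He with the conditional distribution (`DH = He_obs - mean`).  Conditioning
is by rejection after the scaled mutation rate theta is tuned with ~14
steps of stochastic bisection so the mean simulated allele count matches
`k` (the conditioning scheme of the original program is not fully
published; this is the standard reconstruction).  The attempt cap is
200 × `n_iter` replicates, and failure to condition raises an error naming
the locus.  Results for repeated `(n, k)` combinations are cached within a
test run.

Dataset-level significance:

* **sign test** — exact Poisson-binomial tail over the per-locus null
  excess probabilities `P(He > conditional mean)` estimated from the same
  conditional simulations (dynamic-programming convolution);
* **standardized differences** — `T2 = sum(DH_i/sd_i)/sqrt(L)` against a
  standard normal, one-tailed towards excess;
* **Wilcoxon signed-rank** on `DH`, one-tailed.

A calibration caveat worth knowing: the conditional He distribution is
left-skewed, so its mean lies below its median and even at equilibrium
more than half of loci fall above the conditional mean.  The sign test
accounts for this by using the estimated per-locus null excess
probabilities rather than 1/2, and the standardized-differences test is
mean-centred by construction; both hold their nominal type-I error in the
test suite.  The Wilcoxon variant — which classically assumes `DH`
symmetric about zero under the null — is anticonservative on equilibrium
data and should be read as the original software's convention rather than
an exact test.  On strongly bottlenecked data all three agree and the
power question is moot.

Monomorphic loci are excluded from all three tests; a dataset with fewer
than ten polymorphic loci triggers a warning.

## Rejection ABC

Priors (all configurable): `Ne_cur`, `Ne_hist` ~ lognormal(logmean 10.5,
logsd 1); `Ne_bot` ~ U[1, 600]; `t_bot_start` ~ U[10, 40]; `t_bot_end` ~
U[1, 20] (bottleneck draws resampled until `t_bot_start > t_bot_end`);
`t_hist` ~ U[10, 40]; `mu` ~ U[1e-5, 1e-4]; `GSMpar` ~ U[0, 0.3].  Note
that lognormal(10.5, 1) has median ≈ 36,300 — much wider than the verbal
description "about 90% between 3,000 and 15,000" that sometimes accompanies
this prior.  The literal distribution is the default; a `PriorSet.verbal()`
preset (median 6,708, logsd 0.489) matches the verbal description instead.
Both are shipped because the two cannot be reconciled.

Reference tables join parameter draws to summary vectors, one row per
simulated dataset (181 diploids × 39 loci by default).  Rejection retains
the `tolerance` fraction of rows with smallest Euclidean distance after
scaling each statistic by its median absolute deviation over the full
table (the conventional choice; a zero MAD falls back to the SD with a
warning).  Model posterior probabilities are acceptance fractions.
Default scale is reduced (1e4–1e5 rows per model with tolerances chosen to
retain a few hundred rows); the published-scale run (1e7 rows, tolerance
5e-4, 5,000 accepted) is a matter of passing larger arguments.

Cross-validation is leave-one-out: a held-out row is the pseudo-observed
dataset and its own row is excluded from the table before rejection.
Model-selection CV draws holdouts balanced across models and reports
per-model correct-classification rates (ties broken at random).
Parameter-estimation CV uses the posterior median as point estimate and
reports `E_pred = sum_i (est_i - true_i)^2 / (n * Var(true))`, i.e. the
variance-normalised mean squared error, so an uninformative estimator
scores ~1.  The printed formula this reproduces omits the `1/n`, but the
stated interpretation ("below one means informative") requires it.  Two
sensitivities worth noting: `E_pred(Ne_hist)` is dominated by the heavy
right tail of the lognormal prior (a handful of very large true values
control both numerator and denominator), so it is noisy across holdout
draws, and it increases substantially as the rejection tolerance is
relaxed; comparisons of this number across studies are only meaningful at
matched tolerance.

Posterior predictive checks resample accepted rows whole (preserving
parameter correlations), re-simulate summary statistics, and report
per-statistic tail probabilities (two-sided).  The goodness-of-fit
statistic is the median accepted distance; its null distribution comes
from pseudo-observed table rows, and the p-value is
`(1 + #{null >= obs}) / (1 + n_null)` so it is always in (0, 1].

## Expected allele loss

For a bottleneck (`Ne_hist` down to `Ne_bot` for `duration` generations,
ending `t_bot_end = 10` generations ago, post-bottleneck size back at
`Ne_hist`) and a
matched constant-size model at `Ne_hist`, the package simulates `n_sims`
datasets per arm with `mu` and `GSMpar` drawn from the ABC priors, and
reports `loss = 1 - mean_k(bottleneck)/mean_k(constant)` — a ratio of
means, with a delta-method Monte-Carlo standard error.  Expected
heterozygosity loss is computed alongside and is always smaller: rare
alleles are lost preferentially but contribute little heterozygosity.
The three-scenario analysis (`Ne_hist` 1,000 / 10,000 / 50,000, `Ne_bot`
200, duration 10) and the full grid (`Ne_bot` 25–600 by 25, duration 1–20)
use the same machinery.  The constant-size arm of the grid does not depend
on the cell, so it is simulated once per grid at four times the per-cell
replication and shared; scenario timing fixes `t_bot_end = 10` to match
the grid (the effect of the end time within 1–20 generations is negligible
at these mutation rates).

## Synthetic multi-population data

The generator emulates the statistical structure of a multi-population
microsatellite survey without a multi-population coalescent: a large
equilibrium ancestral pool is simulated per locus (per-locus mutation
rates loguniform on [4e-5, 4e-4] at `Ne_hist = 10,000`, chosen so that
per-population observed heterozygosity lands in the published 0.69–0.72
range and allele counts span roughly 2–26); each bottlenecked population is
founded by a multinomial draw of `2*Ne_bot` copies, drifts as a
Wright–Fisher frequency process for the bottleneck duration, and is then
sampled at its final frequencies.  An admixed population draws each gene
copy from a source population according to mixing proportions.  The
"fur-seal-like" preset has four bottlenecked populations (Ne_bot 150–200,
10 generations) and one 50:50 admixed population.

What this emulation does **not** reproduce: shared drift before the split
(differentiation arises only from the bottleneck-era drift), migration,
mutation during the bottleneck, linkage, null alleles, allele dropout and
genotyping error.  Passing end-to-end tests on these data therefore
demonstrates internal consistency of the pipeline — bottleneck signatures
are detected where planted and absent where not — not robustness to the
messiness of real genotype data.

## Scales, seeds and reproducibility

Every stochastic operation takes an explicit seed (or numpy Generator) and
is bit-for-bit reproducible; the pipeline derives one sub-seed per stage
from the global seed by hashing.  The test suite and the acceptance script
run reduced simulation counts chosen to keep a full run in the tens of
minutes on one core (e.g. 2,500–5,000 paired simulations per loss scenario
instead of 100,000; 1e4–1e5 reference-table rows instead of 1e7); the
corresponding Monte-Carlo standard errors are reported alongside results
so the residual simulation noise is visible.

## Known limitations

* Single-population models only: the ABC cannot express migration or
  admixture, which is why admixed populations must be interpreted with
  caution.
* Plain rejection ABC only (no regression adjustment or SMC), matching the
  original analysis.
* The heterozygosity-excess Wilcoxon variant is anticonservative under the
  null (see above).
* The equilibrium-conditioning scheme reconstructs undocumented behaviour
  of the classical software; per-locus equilibrium means agree
  qualitatively but published per-dataset p-values should only be expected
  to match in their significance pattern, not digit-for-digit.
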