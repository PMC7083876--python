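# demosat

Demographic inference for diploid microsatellite data: did a population go
through a recent bottleneck, how severe was it, and how much allelic
diversity did it cost?

`demosat` re-creates, as a tested and reusable Python package, the analysis
toolchain used to reconstruct the recent demographic history of heavily
exploited wildlife populations (the motivating case is a circumpolar
pinniped hunted close to extinction in the 18th–19th centuries and genotyped
at 39 microsatellite loci):

* a **single-population coalescent simulator** for unlinked microsatellites
  under piecewise-constant demography (bottleneck or constant size) with a
  generalized stepwise mutation model (GSM): mutation counts per branch are
  Poisson(μ·t) and step sizes follow P(|S| = s) = (1 − p)·p^(s−1), so the
  parameter p (`GSMpar`) is the proportion of multistep mutations;
* **diversity statistics**: observed and unbiased expected heterozygosity,
  F_is, rarefied allelic richness A_r, the Garza–Williamson M-ratio, private
  alleles, the proportion of low-frequency (<5%) alleles, and pairwise
  Weir–Cockerham F_st with bootstrap confidence intervals;
* the **Cornuet–Luikart heterozygosity-excess bottleneck test** under the
  two-phase mutation model with 80% single-step mutations (TPM80), with
  sign, standardized-differences and Wilcoxon signed-rank tests;
* **rejection ABC** over a three-epoch bottleneck model and a matched
  non-bottleneck model — priors N_e, N_e_hist ~ lognorm(10.5, 1),
  N_e_bot ~ U[1, 600], t_bot_start ~ U[10, 40], t_bot_end ~ U[1, 20],
  μ ~ U[10⁻⁵, 10⁻⁴], GSMpar ~ U[0, 0.3] — with summary statistics
  (mean allele count, proportion of <5% alleles, mean M-ratio),
  leave-one-out cross-validation of model selection and parameter
  estimation (prediction error E_pred = Σᵢ(θ̄ᵢ − θᵢ)²/(n·Var(θ))),
  posterior predictive checks and a distance-based goodness-of-fit test;
* **expected allele loss**: paired coalescent simulation of bottleneck vs
  constant-size scenarios, reporting 1 − k̄_bot/k̄_const over a grid of
  bottleneck sizes and durations;
* a **synthetic multi-population generator** (shared ancestral pool,
  per-population drift, optional admixed population) so the whole pipeline
  is testable without any external data.

Simulation kernels are numba-compiled; a full ABC reference table of 10⁵
simulated datasets (181 diploids × 39 loci each) builds in minutes on one
core.

## Worked example

```python
import demosat as ds

# a population that crashed from Ne 10,000 to 200 ten generations ago
dem = ds.bottleneck_model(ne_cur=10000, ne_bot=200, ne_hist=10000,
                          t_bot_end=10, t_bot_start=20)
mut = ds.MutationModel.gsm(mu=1e-4, gsm_par=0.2)
data = ds.simulate_dataset(181, 39, dem, mut, seed=101)

res = ds.het_excess_test(data, n_iter=250, seed=31)
print(f"prop_het_exc = {res.prop_het_exc:.2f}")
print(f"Wilcoxon p   = {res.p_wilcoxon:.2e}")

loss = ds.expected_allele_loss(ne_hist=10000, ne_bot=200, duration=10,
                               seed=11, n_sims=1500)
print(f"allele loss  = {100 * loss.loss:.1f}%")
```

Output:

```
prop_het_exc = 0.85
Wilcoxon p   = 4.08e-06
allele loss  = 14.7%
```

A strong recent bottleneck leaves most loci with more heterozygosity than
an equilibrium population with the same allele counts would have
(`prop_het_exc` ≈ 0.85, Wilcoxon p ≪ 0.05), yet costs the population only
about 14% of its alleles — rare alleles are lost first, and they contribute
little to heterozygosity.

The same machinery is available from the shell:

```bash
demosat simulate --preset fur_seal --seed 1 --out out/
demosat hetexcess --input out/dataset.gen --model tpm80 --seed 2
demosat abc simulate --n-sims 20000 --seed 3 --out table.csv
demosat abc cv-models --table table.csv --n-pseudo 200 --seed 4
demosat loss scenarios --n-sims 5000 --seed 5
demosat run-all --preset fur_seal --seed 6 --out run/
```

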