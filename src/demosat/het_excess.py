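"""Cornuet-Luikart heterozygosity-excess bottleneck test.

A recent bottleneck preferentially removes rare alleles, so for a while the
observed gene diversity of a locus exceeds the equilibrium diversity
expected for its (reduced) allele count.  For each polymorphic locus we
simulate equilibrium coalescent samples under the chosen mutation model
(TPM with 80% single-step mutations by default), condition on the observed
allele count k, and compare the observed unbiased expected heterozygosity
with the conditional equilibrium distribution.  Dataset-level significance
is assessed with a sign test (exact Poisson-binomial tail over per-locus
null excess probabilities), the standardized-differences test
(T2 = sum(DH_i/sd_i)/sqrt(L) against a standard normal) and a one-tailed
Wilcoxon signed-rank test on the DH values.

Conditioning on k uses rejection sampling after the scaled mutation rate
theta is tuned by stochastic bisection so that the mean simulated allele
count matches k; replicates are then filtered to exactly k alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from ._util import as_rng, kernel_seed
from .dataset import GenotypeDataset
from .simulator import MutationModel

__all__ = ["EquilibriumHet", "HetExcessResult",
           "equilibrium_het_distribution", "het_excess_test",
           "poisson_binomial_tail"]

# mu is arbitrary for equilibrium simulation (only theta = 4*Ne*mu matters);
# Ne is derived from the tuned theta at this rate.
_TUNING_MU = 1e-3


@dataclass
class EquilibriumHet:
    """Conditional equilibrium He distribution for one (n, k) combination."""

    mean: float
    sd: float
    he_values: np.ndarray
    prob_excess_under_null: float
    degenerate: bool = False


def _tune_theta(n_copies: int, k: int, mut: MutationModel, n_reps: int = 150,
                n_iters: int = 14, lo: float = 0.02, hi: float = 800.0) -> float:
    """Bisection on log(theta) so the mean simulated allele count is ~k."""
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(n_iters):
        mid = 0.5 * (llo + lhi)
        theta = np.exp(mid)
        ne = theta / (4.0 * _TUNING_MU)
        mk = _kernels.mean_allele_count(n_copies, ne, _TUNING_MU,
                                        mut.p_multistep, mut.multistep_q, n_reps)
        if mk < k:
            llo = mid
        else:
            lhi = mid
    return float(np.exp(0.5 * (llo + lhi)))


def equilibrium_het_distribution(n_copies: int, k_alleles: int,
                                 mut: MutationModel | None = None,
                                 n_iter: int = 1000, seed=None,
                                 attempt_cap_factor: int = 200) -> EquilibriumHet:
    """Equilibrium He distribution conditioned on exactly k alleles.

    Returns the mean, SD, per-iteration He values and the probability that a
    null (equilibrium) locus exceeds the conditional mean — the per-locus
    null excess probability used by the sign test.
    """
    if not (1 <= k_alleles <= n_copies):
        raise ValueError("need 1 <= k_alleles <= n_copies")
    if mut is None:
        mut = MutationModel.tpm80()
    if k_alleles == 1:
        return EquilibriumHet(0.0, 0.0, np.zeros(n_iter), 0.0, degenerate=True)
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    theta = _tune_theta(n_copies, k_alleles, mut)
    ne = theta / (4.0 * _TUNING_MU)
    he, n_acc = _kernels.equilibrium_het_conditional(
        n_copies, k_alleles, ne, _TUNING_MU, mut.p_multistep, mut.multistep_q,
        n_iter, attempt_cap_factor * n_iter)
    if n_acc < n_iter:
        raise RuntimeError(
            f"failed to accumulate {n_iter} equilibrium replicates with k={k_alleles} "
            f"(n={n_copies}); got {n_acc}")
    mean = float(he.mean())
    sd = float(he.std(ddof=1))
    prob_excess = float(np.mean(he > mean))
    return EquilibriumHet(mean, sd, he, prob_excess)


def poisson_binomial_tail(probs, x: int) -> float:
    """P(X >= x) for X a sum of independent Bernoulli(probs), exact DP."""
    probs = np.asarray(probs, dtype=float)
    pmf = np.zeros(probs.size + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return float(pmf[x:].sum())


@dataclass
class HetExcessResult:
    """Per-locus DH diagnostics and dataset-level bottleneck test p-values."""

    per_locus: pd.DataFrame
    prop_het_exc: float
    n_loci_excess: int
    n_loci_used: int
    p_sign: float
    p_std_diff: float
    p_wilcoxon: float

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.per_locus.to_csv(fh)


def het_excess_test(d: GenotypeDataset, mut: MutationModel | None = None,
                    n_iter: int = 1000, seed=None) -> HetExcessResult:
    """Heterozygosity-excess bottleneck test on a (single-population) dataset.

    Monomorphic loci are excluded.  DH = He_obs - He_eq_mean per locus; the
    three tests are one-tailed towards heterozygosity excess.
    """
    if mut is None:
        mut = MutationModel.tpm80()
    rng = as_rng(seed)
    cache: dict = {}
    rows = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        n = copies.size
        if n < 2:
            continue
        _, counts = np.unique(copies, return_counts=True)
        k = counts.size
        he_obs = (n / (n - 1)) * (1 - np.sum((counts / n) ** 2))
        if k == 1:
            rows.append((d.locus_names[l], n, k, he_obs, 0.0, 0.0,
                         np.nan, np.nan, False, np.nan))
            continue
        key = (n, k)
        if key not in cache:
            try:
                cache[key] = equilibrium_het_distribution(n, k, mut, n_iter, rng)
            except RuntimeError as err:
                raise RuntimeError(f"locus {d.locus_names[l]}: {err}") from err
        eq = cache[key]
        dh = he_obs - eq.mean
        dh_std = dh / eq.sd if eq.sd > 0 else np.nan
        rows.append((d.locus_names[l], n, k, he_obs, eq.mean, eq.sd, dh, dh_std,
                     dh > 0, eq.prob_excess_under_null))
    per_locus = pd.DataFrame(rows, columns=[
        "locus", "n_copies", "k", "He_obs", "He_eq_mean", "He_eq_sd",
        "DH", "DH_std", "excess", "p_null_excess"]).set_index("locus")
    poly = per_locus[per_locus["k"] > 1]
    n_used = poly.shape[0]
    if n_used == 0:
        raise ValueError("all loci are monomorphic; heterozygosity-excess test undefined")
    if n_used < 10:
        warnings.warn(f"only {n_used} polymorphic loci; test has little power")
    n_excess = int(poly["excess"].sum())
    prop = n_excess / n_used
    p_sign = poisson_binomial_tail(poly["p_null_excess"].to_numpy(), n_excess)
    dh_std = poly["DH_std"].dropna().to_numpy()
    t2 = dh_std.sum() / np.sqrt(dh_std.size)
    p_std = float(stats.norm.sf(t2))
    p_wil = float(stats.wilcoxon(poly["DH"].to_numpy(), alternative="greater").pvalue)
    return HetExcessResult(per_locus=per_locus, prop_het_exc=prop,
                           n_loci_excess=n_excess, n_loci_used=n_used,
                           p_sign=p_sign, p_std_diff=p_std, p_wilcoxon=p_wil)
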