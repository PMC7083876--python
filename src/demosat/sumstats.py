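"""Per-locus and dataset-level diversity statistics and differentiation.

Covers observed/expected heterozygosity, Fis, the Garza-Williamson M-ratio,
rarefied allelic richness, low-frequency allele proportion, private alleles,
Weir-Cockerham pairwise Fst with bootstrap confidence intervals, the
three-statistic summary vector used by the rejection-ABC machinery, and a
generic resampling operation over random individual subsets.

Missing gene copies are excluded locus-wise and allele frequencies are
renormalised over the copies present.  All statistics are invariant to
translation of allele sizes and to the ordering of individuals and loci.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._util import as_rng
from .dataset import MISSING, GenotypeDataset

__all__ = [
    "DiversityTable", "SummaryVector", "FstResult",
    "per_locus_diversity", "rarefied_allelic_richness", "m_ratio",
    "prop_low_freq_alleles", "private_alleles", "pairwise_fst",
    "abc_summary_vector", "subsample_statistic", "abc_target_from_population",
]

SUMMARY_STAT_NAMES = ("mean_allelic_richness", "prop_low_freq_alleles", "mean_m_ratio")


@dataclass(frozen=True)
class SummaryVector:
    """The three across-locus means used as ABC summary statistics."""

    mean_allelic_richness: float
    prop_low_freq_alleles: float
    mean_m_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_allelic_richness,
                         self.prop_low_freq_alleles,
                         self.mean_m_ratio], dtype=np.float64)


@dataclass
class DiversityTable:
    """Per-locus diversity rows plus across-locus means and SDs.

    Loci with no data are flagged (``usable`` False) and excluded from the
    means.  ``Fis = 1 - Ho/He`` per locus (0 where He = 0).
    """

    per_locus: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.per_locus.to_csv(fh)


def _locus_counts(d: GenotypeDataset, locus: int, pop=None) -> Counter:
    return Counter(d.gene_copies(locus, pop).tolist())


def per_locus_diversity(d: GenotypeDataset) -> DiversityTable:
    """Ho, unbiased He, Fis, M-ratio and allele count per locus."""
    rows = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        n = copies.size
        if n == 0:
            rows.append((d.locus_names[l], 0, 0, np.nan, np.nan, np.nan, np.nan, False))
            continue
        counts = np.array(sorted(Counter(copies.tolist()).values()), dtype=float)
        k = counts.size
        freqs = counts / n
        he = (n / (n - 1)) * (1 - np.sum(freqs**2)) if n > 1 else 0.0
        genos = d.alleles[:, l, :]
        complete = ~np.any(genos == MISSING, axis=1)
        n_geno = int(complete.sum())
        if n_geno > 0:
            ho = float(np.mean(genos[complete, 0] != genos[complete, 1]))
        else:
            ho = np.nan
        fis = 0.0 if he == 0 else 1.0 - ho / he
        mr = _m_ratio_from_copies(copies)
        rows.append((d.locus_names[l], n, k, ho, he, fis, mr, True))
    table = pd.DataFrame(rows, columns=["locus", "n_gene_copies", "k_alleles", "Ho",
                                        "He_unbiased", "Fis", "M_ratio", "usable"])
    table = table.set_index("locus")
    usable = table[table["usable"]]
    num = usable[["k_alleles", "Ho", "He_unbiased", "Fis", "M_ratio"]]
    return DiversityTable(per_locus=table, means=num.mean(), sds=num.std(ddof=1))


def _m_ratio_from_copies(copies: np.ndarray) -> float:
    k = np.unique(copies).size
    r = int(copies.max() - copies.min())
    return k / (r + 1)


def m_ratio(d: GenotypeDataset, repeat_unit_bp: np.ndarray | None = None):
    """Garza-Williamson M = k / (range + 1) per locus, and the mean.

    Allele sizes are interpreted as integer repeat counts.  If
    ``repeat_unit_bp`` is given, stored sizes are treated as base pairs and
    divided by the per-locus motif length (must divide exactly).
    """
    vals = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        if copies.size == 0:
            vals.append(np.nan)
            continue
        if repeat_unit_bp is not None:
            unit = int(repeat_unit_bp[l])
            if np.any(copies % unit != 0):
                raise ValueError(
                    f"locus {d.locus_names[l]}: allele sizes not divisible by motif length {unit}")
            copies = copies // unit
        vals.append(_m_ratio_from_copies(copies))
    arr = np.array(vals)
    return arr, float(np.nanmean(arr))


def rarefied_allelic_richness(d: GenotypeDataset, g: int = 20):
    """Expected allele count in a random subsample of g gene copies, per locus.

    A_r = sum_i [1 - C(N - N_i, g) / C(N, g)] over alleles i, where N is the
    number of copies at the locus and N_i the count of allele i.  This is the
    exact expectation of the allele count over all g-subsets.
    """
    if g < 1:
        raise ValueError("g must be at least 1")
    vals = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        n = copies.size
        if n < g:
            raise ValueError(
                f"locus {d.locus_names[l]} has only {n} gene copies (< g={g})")
        counts = np.array(list(Counter(copies.tolist()).values()), dtype=np.int64)
        vals.append(float(np.sum(1.0 - _hyper_zero_prob(n, counts, g))))
    arr = np.array(vals)
    return arr, float(arr.mean())


def _hyper_zero_prob(n: int, counts: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a g-subset) = C(n-c, g)/C(n, g), log-space safe."""
    out = np.zeros(counts.size)
    ok = n - counts >= g
    c = counts[ok]
    log_p = (gammaln(n - c + 1) - gammaln(g + 1) - gammaln(n - c - g + 1)
             - (gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)))
    out[ok] = np.exp(log_p)
    return out


def prop_low_freq_alleles(d: GenotypeDataset, threshold: float = 0.05):
    """Per-locus fraction of alleles at strictly < threshold frequency; mean.

    The default 5% cut uses exact integer arithmetic (20*count < n_copies).
    """
    vals = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        n = copies.size
        if n == 0:
            vals.append(np.nan)
            continue
        counts = np.array(list(Counter(copies.tolist()).values()))
        if threshold == 0.05:
            low = int(np.sum(20 * counts < n))
        else:
            low = int(np.sum(counts < threshold * n))
        vals.append(low / counts.size)
    arr = np.array(vals)
    return arr, float(np.nanmean(arr))


def private_alleles(d: GenotypeDataset) -> pd.Series:
    """Number of alleles observed in exactly one population, per population."""
    pops = d.populations()
    if len(pops) < 2:
        raise ValueError("private alleles require at least two populations")
    counts = {p: 0 for p in pops}
    for l in range(d.n_loci):
        present = {p: set(np.unique(d.gene_copies(l, p)).tolist()) for p in pops}
        all_alleles = set().union(*present.values())
        for a in all_alleles:
            holders = [p for p in pops if a in present[p]]
            if len(holders) == 1:
                counts[holders[0]] += 1
    return pd.Series(counts, name="private_alleles")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta

def _wc_components(d: GenotypeDataset, pop_a, pop_b) -> np.ndarray:
    """Per-locus (a, a+b+c) variance-component sums for one population pair."""
    out = np.zeros((d.n_loci, 2))
    for l in range(d.n_loci):
        stats = []
        for pop in (pop_a, pop_b):
            genos = d.alleles[d.pop_labels == pop, l, :]
            complete = ~np.any(genos == MISSING, axis=1)
            genos = genos[complete]
            stats.append(genos)
        n1, n2 = (g.shape[0] for g in stats)
        if n1 < 2 or n2 < 2:
            out[l] = (np.nan, np.nan)
            continue
        alleles = np.unique(np.concatenate([g.reshape(-1) for g in stats]))
        n_bar = (n1 + n2) / 2.0
        nc = 2 * n_bar - (n1**2 + n2**2) / (2 * n_bar)
        a_sum = 0.0
        abc_sum = 0.0
        for al in alleles:
            p1 = np.mean(stats[0] == al)
            p2 = np.mean(stats[1] == al)
            h1 = np.mean(np.sum(stats[0] == al, axis=1) == 1)
            h2 = np.mean(np.sum(stats[1] == al, axis=1) == 1)
            p_bar = (n1 * p1 + n2 * p2) / (2 * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
            h_bar = (n1 * h1 + n2 * h2) / (2 * n_bar)
            pq = p_bar * (1 - p_bar)
            a = (n_bar / nc) * (s2 - (pq - s2 / 2 - h_bar / 4) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (pq - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2
            a_sum += a
            abc_sum += a + b + c
        out[l] = (a_sum, abc_sum)
    return out


@dataclass
class FstResult:
    fst: pd.DataFrame
    ci_low: pd.DataFrame | None
    ci_high: pd.DataFrame | None
    n_bootstrap: int


def pairwise_fst(d: GenotypeDataset, n_bootstrap: int = 0, seed=None,
                 ci: float = 0.95) -> FstResult:
    """Multilocus Weir-Cockerham theta for every population pair.

    The multilocus estimator is the ratio of summed variance components
    across loci; optional percentile bootstrap over loci gives CIs.
    Populations with fewer than two genotyped individuals are excluded with
    a warning.
    """
    pops = [p for p in d.populations()]
    kept = []
    for p in pops:
        if int(np.sum(d.pop_labels == p)) >= 2:
            kept.append(p)
        else:
            warnings.warn(f"population {p!r} has <2 individuals; excluded from Fst")
    if len(kept) < 2:
        raise ValueError("pairwise Fst requires at least two usable populations")
    rng = as_rng(seed) if (n_bootstrap and seed is not None) else (
        np.random.default_rng(0) if n_bootstrap else None)
    fst = pd.DataFrame(0.0, index=kept, columns=kept)
    lo = pd.DataFrame(0.0, index=kept, columns=kept) if n_bootstrap else None
    hi = pd.DataFrame(0.0, index=kept, columns=kept) if n_bootstrap else None
    alpha = (1 - ci) / 2
    for i, pa in enumerate(kept):
        for pb in kept[i + 1:]:
            comp = _wc_components(d, pa, pb)
            comp = comp[~np.isnan(comp[:, 0])]
            theta = comp[:, 0].sum() / comp[:, 1].sum()
            fst.loc[pa, pb] = fst.loc[pb, pa] = theta
            if n_bootstrap:
                idx = rng.integers(0, comp.shape[0], size=(n_bootstrap, comp.shape[0]))
                sums = comp[idx].sum(axis=1)
                reps = sums[:, 0] / sums[:, 1]
                lo.loc[pa, pb] = lo.loc[pb, pa] = float(np.quantile(reps, alpha))
                hi.loc[pa, pb] = hi.loc[pb, pa] = float(np.quantile(reps, 1 - alpha))
    return FstResult(fst=fst, ci_low=lo, ci_high=hi, n_bootstrap=n_bootstrap)


# ---------------------------------------------------------------------------
# ABC summary vector and subsampling

def abc_summary_vector(d: GenotypeDataset) -> SummaryVector:
    """(mean allele count, prop <5% alleles, mean M-ratio) across loci.

    The first component is the raw mean observed allele count: simulated
    reference datasets are generated at the same sample size as the target,
    so no rarefaction is applied here.
    """
    if len(d.populations()) > 1:
        raise ValueError("abc_summary_vector expects a single-population dataset; "
                         "subset with for_population() first")
    ks = []
    for l in range(d.n_loci):
        copies = d.gene_copies(l)
        if copies.size == 0:
            continue
        ks.append(np.unique(copies).size)
    _, plf = prop_low_freq_alleles(d)
    _, mr = m_ratio(d)
    return SummaryVector(float(np.mean(ks)), plf, mr)


def abc_target_from_population(d: GenotypeDataset, pop, n_ind: int, seed) -> SummaryVector:
    """Summary vector of a population, randomly subsampled to n_ind if larger."""
    sub = d.for_population(pop)
    if sub.n_individuals > n_ind:
        rng = as_rng(seed)
        idx = rng.choice(sub.n_individuals, size=n_ind, replace=False)
        sub = sub.subset(np.sort(idx))
    return abc_summary_vector(sub)


def subsample_statistic(d: GenotypeDataset, statistic, n_ind: int = 10,
                        n_rep: int = 1000, seed=None) -> np.ndarray:
    """Distribution of a statistic over random subsets of individuals.

    ``statistic`` is any callable mapping a GenotypeDataset to a float.
    """
    if n_ind > d.n_individuals:
        raise ValueError(f"cannot subsample {n_ind} of {d.n_individuals} individuals")
    rng = as_rng(seed)
    out = np.empty(n_rep)
    for r in range(n_rep):
        idx = np.sort(rng.choice(d.n_individuals, size=n_ind, replace=False))
        out[r] = float(statistic(d.subset(idx)))
    return out
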