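"""Low-level numba kernels: coalescent genealogies, stepwise mutation, locus summaries.

All kernels draw from numba's internal NumPy-compatible global random stream.
Callers seed it once through :func:`seed_rng` at the start of a stochastic
operation; the kernels themselves never reseed, so a single seeded stream
covers an arbitrary sequence of kernel calls and results are reproducible
bit-for-bit for a given seed.

Demographies are passed as two parallel arrays ``epoch_starts`` /
``epoch_sizes`` (generations before present, diploid Ne), first start 0,
strictly increasing.  The coalescent is the continuous-time Kingman process
with pair rate ``1/(2*Ne)`` per generation; exponential waiting times are
carried across epoch boundaries by the memoryless property (time rescaling).
"""

import numpy as np
from numba import njit

# Arbitrary ancestral allele size in repeat units.  Every statistic computed
# downstream is invariant to translation of allele sizes.
ROOT_ALLELE = 50


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _geometric(q):
    # P(G=g) = (1-q) * q**(g-1), g >= 1  (success probability 1-q)
    u = np.random.random()
    while u <= 0.0:
        u = np.random.random()
    return 1 + int(np.log(u) / np.log(q))


@njit(cache=True)
def _sim_tree(n, epoch_starts, epoch_sizes, parent, node_time, active):
    """Fill parent pointers / node times for a coalescent tree on n tips.

    Nodes 0..n-1 are tips at time 0; internal nodes are appended in
    coalescence order, so every parent has a larger index than its children
    and the root is node 2n-2.
    """
    for i in range(n):
        active[i] = i
        node_time[i] = 0.0
        parent[i] = -1
    t = 0.0
    k = n
    j = 0
    n_ep = epoch_starts.shape[0]
    nxt = n
    while k > 1:
        while True:
            rate = k * (k - 1.0) / (4.0 * epoch_sizes[j])
            w = np.random.exponential(1.0 / rate)
            if j + 1 < n_ep and t + w > epoch_starts[j + 1]:
                t = epoch_starts[j + 1]
                j += 1
            else:
                t = t + w
                break
        a = np.random.randint(k)
        na = active[a]
        active[a] = active[k - 1]
        b = np.random.randint(k - 1)
        nb = active[b]
        parent[na] = nxt
        parent[nb] = nxt
        node_time[nxt] = t
        parent[nxt] = -1
        active[b] = nxt
        nxt += 1
        k -= 1


@njit(cache=True)
def _mutation_delta(branch_len, mu, p_multi, q):
    """Net allele-size change along one branch under the generalized stepwise model.

    Mutation count is Poisson(mu * branch_len).  Each mutation moves the
    allele by +/-S with equal sign probability; S = 1 with probability
    1 - p_multi, otherwise S = 1 + G with G geometric (success 1-q), i.e.
    multistep magnitudes of at least two repeat units.
    """
    m = np.random.poisson(mu * branch_len)
    d = 0
    for _ in range(m):
        s = 1
        if p_multi > 0.0 and np.random.random() < p_multi:
            s = 1 + _geometric(q)
        if np.random.random() < 0.5:
            d += s
        else:
            d -= s
    return d


@njit(cache=True)
def _mutate_tree(n, parent, node_time, mu, p_multi, q, root_allele, out):
    """Propagate allele sizes from the root to the n tips (written to out)."""
    total = 2 * n - 1
    vals = np.empty(total, np.int64)
    vals[total - 1] = root_allele
    for v in range(total - 2, -1, -1):
        bl = node_time[parent[v]] - node_time[v]
        vals[v] = vals[parent[v]] + _mutation_delta(bl, mu, p_multi, q)
    for i in range(n):
        out[i] = vals[i]


@njit(cache=True)
def _locus_summary(alleles, n):
    """(k, n_lowfreq, M_ratio, He_unbiased) for one locus of n gene copies.

    n_lowfreq counts alleles at strictly <5% frequency; the comparison
    20*count < n is exact in integer arithmetic.
    """
    srt = np.sort(alleles)
    k = 1
    nlow = 0
    run = 1
    sumsq = 0.0
    for i in range(1, n):
        if srt[i] != srt[i - 1]:
            if 20 * run < n:
                nlow += 1
            sumsq += run * run
            k += 1
            run = 1
        else:
            run += 1
    if 20 * run < n:
        nlow += 1
    sumsq += run * run
    he = 0.0
    if n > 1:
        he = (n / (n - 1.0)) * (1.0 - sumsq / (float(n) * n))
    m = k / (srt[n - 1] - srt[0] + 1.0)
    return k, nlow, m, he


@njit(cache=True)
def sim_dataset_summary(n_copies, n_loci, epoch_starts, epoch_sizes, mu, p_multi, q):
    """Simulate one dataset; return means across loci of (k, prop<5%, M, He)."""
    parent = np.empty(2 * n_copies - 1, np.int64)
    node_time = np.empty(2 * n_copies - 1, np.float64)
    active = np.empty(n_copies, np.int64)
    alleles = np.empty(n_copies, np.int64)
    ks = 0.0
    lows = 0.0
    ms = 0.0
    hes = 0.0
    for _ in range(n_loci):
        _sim_tree(n_copies, epoch_starts, epoch_sizes, parent, node_time, active)
        _mutate_tree(n_copies, parent, node_time, mu, p_multi, q, ROOT_ALLELE, alleles)
        k, nlow, m, he = _locus_summary(alleles, n_copies)
        ks += k
        lows += nlow / k
        ms += m
        hes += he
    return ks / n_loci, lows / n_loci, ms / n_loci, hes / n_loci


@njit(cache=True)
def sim_summary_batch(n_copies, n_loci, epoch_starts, epoch_sizes, n_epochs,
                      mus, p_multis, qs, out):
    """Batch of datasets with per-dataset demography and mutation parameters.

    epoch_starts/epoch_sizes: (n_datasets, max_epochs); n_epochs gives the
    number of valid epochs per row.  out: (n_datasets, 4) receiving mean k,
    mean prop<5%, mean M-ratio, mean He.
    """
    for i in range(mus.shape[0]):
        ne = n_epochs[i]
        a, b, c, d = sim_dataset_summary(
            n_copies, n_loci, epoch_starts[i, :ne], epoch_sizes[i, :ne],
            mus[i], p_multis[i], qs[i])
        out[i, 0] = a
        out[i, 1] = b
        out[i, 2] = c
        out[i, 3] = d


@njit(cache=True)
def sim_alleles(n_copies, n_loci, epoch_starts, epoch_sizes, mu_per_locus,
                p_multi, q, root_allele):
    """Full allele matrix (n_copies x n_loci) for one dataset, per-locus mu."""
    out = np.empty((n_copies, n_loci), np.int64)
    if n_copies == 1:
        for l in range(n_loci):
            out[0, l] = root_allele
        return out
    parent = np.empty(2 * n_copies - 1, np.int64)
    node_time = np.empty(2 * n_copies - 1, np.float64)
    active = np.empty(n_copies, np.int64)
    alleles = np.empty(n_copies, np.int64)
    for l in range(n_loci):
        _sim_tree(n_copies, epoch_starts, epoch_sizes, parent, node_time, active)
        _mutate_tree(n_copies, parent, node_time, mu_per_locus[l], p_multi, q,
                     root_allele, alleles)
        for i in range(n_copies):
            out[i, l] = alleles[i]
    return out


@njit(cache=True)
def sim_tree_arrays(n, epoch_starts, epoch_sizes):
    """One genealogy as (parent, node_time) arrays of length 2n-1 (root last)."""
    parent = np.full(2 * n - 1, -1, np.int64)
    node_time = np.zeros(2 * n - 1, np.float64)
    if n > 1:
        active = np.empty(n, np.int64)
        _sim_tree(n, epoch_starts, epoch_sizes, parent, node_time, active)
    return parent, node_time


@njit(cache=True)
def mutate_tips(n, parent, node_time, mu, p_multi, q, root_allele):
    """Tip allele sizes for an existing genealogy."""
    out = np.empty(n, np.int64)
    if n == 1:
        out[0] = root_allele
        return out
    _mutate_tree(n, parent, node_time, mu, p_multi, q, root_allele, out)
    return out


@njit(cache=True)
def sim_tmrca_batch(n, epoch_starts, epoch_sizes, n_reps):
    """Times to the most recent common ancestor over independent genealogies."""
    out = np.empty(n_reps, np.float64)
    parent = np.empty(2 * n - 1, np.int64)
    node_time = np.empty(2 * n - 1, np.float64)
    active = np.empty(n, np.int64)
    for r in range(n_reps):
        _sim_tree(n, epoch_starts, epoch_sizes, parent, node_time, active)
        out[r] = node_time[2 * n - 2]
    return out


@njit(cache=True)
def equilibrium_het_conditional(n_copies, k_target, ne, mu, p_multi, q,
                                n_iter, max_attempts):
    """He values of equilibrium coalescent loci conditioned on exactly k alleles.

    Simulates constant-size loci and keeps the unbiased expected
    heterozygosity of replicates whose allele count equals k_target.
    Returns (he array of length n_iter, number actually accumulated).
    """
    he = np.zeros(n_iter, np.float64)
    starts = np.zeros(1, np.float64)
    sizes = np.full(1, ne, np.float64)
    parent = np.empty(2 * n_copies - 1, np.int64)
    node_time = np.empty(2 * n_copies - 1, np.float64)
    active = np.empty(n_copies, np.int64)
    alleles = np.empty(n_copies, np.int64)
    count = 0
    attempts = 0
    while count < n_iter and attempts < max_attempts:
        _sim_tree(n_copies, starts, sizes, parent, node_time, active)
        _mutate_tree(n_copies, parent, node_time, mu, p_multi, q, ROOT_ALLELE,
                     alleles)
        k, _nl, _m, h = _locus_summary(alleles, n_copies)
        if k == k_target:
            he[count] = h
            count += 1
        attempts += 1
    return he, count


@njit(cache=True)
def mean_allele_count(n_copies, ne, mu, p_multi, q, n_reps):
    """Monte-Carlo mean allele count of an equilibrium locus (used to tune theta)."""
    starts = np.zeros(1, np.float64)
    sizes = np.full(1, ne, np.float64)
    parent = np.empty(2 * n_copies - 1, np.int64)
    node_time = np.empty(2 * n_copies - 1, np.float64)
    active = np.empty(n_copies, np.int64)
    alleles = np.empty(n_copies, np.int64)
    tot = 0.0
    for _ in range(n_reps):
        _sim_tree(n_copies, starts, sizes, parent, node_time, active)
        _mutate_tree(n_copies, parent, node_time, mu, p_multi, q, ROOT_ALLELE,
                     alleles)
        k, _nl, _m, _h = _locus_summary(alleles, n_copies)
        tot += k
    return tot / n_reps
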