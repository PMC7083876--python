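"""Multi-population synthetic microsatellite datasets for end-to-end testing.

Populations are carved from a shared ancestral gene pool: each locus is
first simulated as a large equilibrium coalescent sample under the
generalized stepwise model (per-locus mutation rates vary, producing the
wide spread of allele counts seen in real microsatellite panels).  A
bottlenecked population is founded by a multinomial draw of ``2*ne_bot``
gene copies from the ancestral frequencies, drifts through the bottleneck
as a Wright-Fisher frequency process for the given number of generations,
and is then sampled at its final frequencies (post-bottleneck growth is
fast enough that additional drift is negligible).  Non-bottlenecked
populations sample the ancestral pool directly, and an admixed population
draws each gene copy from a source population chosen by the mixing
proportions.

This is an emulation of inter-population differentiation by independent
drift from a shared pool — not a joint multi-population coalescent (the
in-scope coalescent is strictly single-population).  It reproduces the
statistical structure the analysis pipeline assumes: bottleneck signatures
within populations, modest Fst between them, and an admixed population
lying between its sources.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from ._kernels import ROOT_ALLELE
from ._util import as_rng, kernel_seed
from .dataset import GenotypeDataset, write_csv, write_genepop

__all__ = ["PopulationSpec", "SyntheticConfig", "fur_seal_preset",
           "constant_preset", "generate_multipop_dataset", "fixture_suite"]


@dataclass(frozen=True)
class PopulationSpec:
    """One synthetic population.

    Either a drift history (``ne_bot`` + ``bottleneck_generations``; use
    ``ne_bot=None`` for no bottleneck) or an ``admixture`` mapping of source
    population names to mixing proportions (must sum to 1).
    """

    name: str
    n_individuals: int
    ne_bot: float | None = None
    bottleneck_generations: int = 10
    admixture: dict | None = None

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.admixture is not None:
            total = sum(self.admixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"admixture proportions for {self.name!r} sum to {total}, not 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a multi-population synthetic dataset."""

    populations: tuple
    n_loci: int = 39
    ne_hist: float = 10000.0
    mu_range: tuple = (4e-5, 4e-4)   # per-locus loguniform mutation rates
    gsm_par: float = 0.2
    ancestral_pool_copies: int = 1000

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for p in self.populations:
            if p.admixture:
                for src in p.admixture:
                    if src not in names or src == p.name:
                        raise ValueError(f"bad admixture source {src!r} for {p.name!r}")


def fur_seal_preset(scale: float = 1.0) -> SyntheticConfig:
    """Five populations shaped like a heavily sealed pinniped: four relicts
    with recent bottlenecks (Ne ~150-200 for ~10 generations) and one
    population admixed between two of them.  ``scale`` shrinks sample sizes
    for fast tests."""
    def n(x):
        return max(8, int(round(x * scale)))
    pops = (
        PopulationSpec("south_shetlands", n(197), ne_bot=200.0),
        PopulationSpec("south_georgia", n(1042), ne_bot=200.0),
        PopulationSpec("bouvetoya", n(396), ne_bot=175.0),
        PopulationSpec("kerguelen", n(181), ne_bot=150.0),
        PopulationSpec("marion_crozet", n(184),
                       admixture={"bouvetoya": 0.5, "kerguelen": 0.5}),
    )
    return SyntheticConfig(populations=pops)


def constant_preset(scale: float = 1.0, n_pops: int = 3) -> SyntheticConfig:
    """Populations drawn from the shared pool with no bottleneck (negative
    control: no heterozygosity excess, no bottleneck-model support)."""
    pops = tuple(PopulationSpec(f"const_{i + 1}", max(8, int(round(181 * scale))),
                                ne_bot=None)
                 for i in range(n_pops))
    return SyntheticConfig(populations=pops)


def _drift_frequencies(freqs: np.ndarray, n_copies: int, generations: int,
                       rng) -> np.ndarray:
    """Wright-Fisher multinomial drift of allele frequencies at one locus."""
    counts = rng.multinomial(n_copies, freqs)
    for _ in range(generations):
        counts = rng.multinomial(n_copies, counts / n_copies)
    return counts / n_copies


def generate_multipop_dataset(cfg: SyntheticConfig, seed) -> GenotypeDataset:
    """Generate the multi-population dataset described by ``cfg``."""
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    log_lo, log_hi = np.log(cfg.mu_range[0]), np.log(cfg.mu_range[1])
    mu_per_locus = np.exp(rng.uniform(log_lo, log_hi, cfg.n_loci))
    pool = _kernels.sim_alleles(
        cfg.ancestral_pool_copies, cfg.n_loci, np.zeros(1),
        np.full(1, cfg.ne_hist), mu_per_locus, cfg.gsm_par, cfg.gsm_par,
        ROOT_ALLELE)

    # per-locus ancestral allele lists and frequencies
    anc_alleles = []
    anc_freqs = []
    for l in range(cfg.n_loci):
        vals, counts = np.unique(pool[:, l], return_counts=True)
        anc_alleles.append(vals)
        anc_freqs.append(counts / counts.sum())

    # final allele frequencies per (population, locus)
    pop_freqs: dict = {}
    for spec in cfg.populations:
        if spec.admixture is not None:
            continue
        freqs_l = []
        for l in range(cfg.n_loci):
            if spec.ne_bot is None:
                freqs_l.append(anc_freqs[l])
            else:
                freqs_l.append(_drift_frequencies(
                    anc_freqs[l], int(round(2 * spec.ne_bot)),
                    spec.bottleneck_generations, rng))
        pop_freqs[spec.name] = freqs_l

    blocks = []
    labels = []
    for spec in cfg.populations:
        n_copies = 2 * spec.n_individuals
        mat = np.empty((n_copies, cfg.n_loci), dtype=np.int64)
        for l in range(cfg.n_loci):
            if spec.admixture is None:
                mat[:, l] = rng.choice(anc_alleles[l], size=n_copies,
                                       p=pop_freqs[spec.name][l])
            else:
                sources = list(spec.admixture)
                probs = np.array([spec.admixture[s] for s in sources])
                which = rng.choice(len(sources), size=n_copies, p=probs)
                for s_i, s in enumerate(sources):
                    m = which == s_i
                    mat[m, l] = rng.choice(anc_alleles[l], size=int(m.sum()),
                                           p=pop_freqs[s][l])
        block = np.empty((spec.n_individuals, cfg.n_loci, 2), dtype=np.int64)
        block[:, :, 0] = mat[0::2]
        block[:, :, 1] = mat[1::2]
        blocks.append(block)
        labels.extend([spec.name] * spec.n_individuals)
    return GenotypeDataset(
        alleles=np.concatenate(blocks, axis=0),
        pop_labels=np.array(labels, dtype=object),
        locus_names=[f"L{l + 1:02d}" for l in range(cfg.n_loci)],
    )


# ---------------------------------------------------------------------------
# Fixture suite

# Tiny hand-checkable dataset: 2 populations x 3 individuals x 3 loci.
# Expected statistics in the manifest are derived by hand from these genotypes.
_TINY_ALLELES = np.array([
    # pop a
    [[10, 12], [20, 20], [30, 31]],
    [[10, 10], [20, 21], [30, 31]],
    [[12, 12], [20, 20], [31, 31]],
    # pop b
    [[12, 14], [20, 20], [30, 30]],
    [[14, 14], [20, 22], [30, 30]],
    [[12, 14], [20, 20], [30, 30]],
], dtype=np.int64)


def tiny_dataset() -> GenotypeDataset:
    return GenotypeDataset(
        alleles=_TINY_ALLELES.copy(),
        pop_labels=np.array(["a"] * 3 + ["b"] * 3, dtype=object),
        locus_names=["loc1", "loc2", "loc3"],
    )


# Hand computation for population "a" (6 gene copies per locus):
#  loc1 copies {10,12,10,10,12,12}: k=2, freqs 1/2,1/2 -> He = 6/5*(1-1/2)=0.6,
#       Ho = 1/3, M = 2/(2+1) = 2/3
#  loc2 copies {20,20,20,21,20,20}: k=2, freqs 5/6,1/6 -> He = 6/5*(1-26/36)=1/3,
#       Ho = 1/3, M = 2/2 = 1
#  loc3 copies {30,31,30,31,31,31}: k=2, freqs 1/3,2/3 -> He = 6/5*(1-5/9)=8/15,
#       Ho = 2/3, M = 1
_TINY_MANIFEST = {
    "pop_a": {
        "k": [2, 2, 2],
        "Ho": [1 / 3, 1 / 3, 2 / 3],
        "He_unbiased": [0.6, 1 / 3, 8 / 15],
        "M_ratio": [2 / 3, 1.0, 1.0],
    },
    # a: 10 (loc1), 21 (loc2), 31 (loc3); b: 14 (loc1), 22 (loc2)
    "private_alleles": {"a": 3, "b": 2},
}


def fixture_suite(out_dir, seed: int = 20_200_320) -> dict:
    """Write a deterministic directory of small plain-text fixtures.

    Contents: the tiny hand-checkable dataset (CSV + GENEPOP), a reduced
    five-population preset dataset, a bottlenecked/constant single-population
    pair, and ``manifest.json`` recording the generation seed and the
    hand-computed expectations for the tiny set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tiny = tiny_dataset()
    write_csv(tiny, out / "tiny.csv")
    write_genepop(tiny, out / "tiny.gen", title="tiny fixture")

    rng = as_rng(seed)
    multi = generate_multipop_dataset(fur_seal_preset(scale=0.3), rng)
    write_genepop(multi, out / "multipop.gen", title="five-population preset")
    write_csv(multi, out / "multipop.csv")

    from .simulator import MutationModel, bottleneck_model, constant_model, simulate_dataset
    mut = MutationModel.gsm(1e-4, 0.2)
    bot = simulate_dataset(60, 39, bottleneck_model(10000, 200, 10000, 10, 20),
                           mut, rng, population="bottlenecked")
    con = simulate_dataset(60, 39, constant_model(10000, 10000, 25), mut, rng,
                           population="constant")
    write_genepop(bot, out / "bottlenecked.gen", title="bottleneck pair: bottlenecked")
    write_genepop(con, out / "constant.gen", title="bottleneck pair: constant")

    manifest = {"seed": seed, "tiny": _TINY_MANIFEST,
                "files": ["tiny.csv", "tiny.gen", "multipop.gen", "multipop.csv",
                          "bottlenecked.gen", "constant.gen"]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
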