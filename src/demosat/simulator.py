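"""Single-population neutral coalescent simulation of unlinked microsatellite loci.

The demographic model is piecewise-constant diploid effective size on a
backwards generation axis (time 0 = present).  Mutation follows a
generalized stepwise model (GSM): mutation counts per branch are Poisson
with rate ``mu`` per locus per generation; each mutation shifts the allele
by a positive integer number of repeat units with equiprobable sign.  Under
the GSM the step magnitude law is geometric, ``P(|S| = s) = (1-p) p**(s-1)``
with ``p`` the proportion of multistep mutations; the two-phase model (TPM)
instead mixes single steps with a separately tuned multistep magnitude
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import ROOT_ALLELE
from ._util import as_rng, kernel_seed
from .dataset import GenotypeDataset

__all__ = [
    "DemographicModel",
    "MutationModel",
    "Genealogy",
    "bottleneck_model",
    "constant_model",
    "simulate_genealogy",
    "mutate_genealogy",
    "simulate_dataset",
    "ROOT_ALLELE",
]


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant diploid Ne; epochs tile [0, inf) backwards in time.

    ``epochs`` is an ordered tuple of ``(start_time, diploid_Ne)`` with
    strictly increasing start times, the first at 0.
    """

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.epochs) == 0:
            raise ValueError("demography needs at least one epoch")
        starts = [t for t, _ in self.epochs]
        sizes = [n for _, n in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n <= 0 for n in sizes):
            raise ValueError("all effective sizes must be positive")
        object.__setattr__(self, "epochs", tuple((float(t), float(n)) for t, n in self.epochs))

    @property
    def start_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs], dtype=np.float64)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs], dtype=np.float64)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


def bottleneck_model(ne_cur: float, ne_bot: float, ne_hist: float,
                     t_bot_end: float, t_bot_start: float) -> DemographicModel:
    """Three-epoch demography: present size, bottleneck, historical size.

    The bottleneck runs (backwards in time) from ``t_bot_end`` to
    ``t_bot_start`` generations before present, so ``t_bot_start`` must
    exceed ``t_bot_end``.
    """
    if t_bot_end <= 0:
        raise ValueError("t_bot_end must be positive")
    if t_bot_start <= t_bot_end:
        raise ValueError(
            f"t_bot_start ({t_bot_start}) must exceed t_bot_end ({t_bot_end})")
    return DemographicModel(((0.0, ne_cur), (t_bot_end, ne_bot), (t_bot_start, ne_hist)))


def constant_model(ne_cur: float, ne_hist: float, t_hist: float) -> DemographicModel:
    """Two-epoch demography without a bottleneck (size change at t_hist)."""
    if t_hist <= 0:
        raise ValueError("t_hist must be positive")
    return DemographicModel(((0.0, ne_cur), (t_hist, ne_hist)))


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite stepwise mutation law.

    Parameters
    ----------
    mu:
        Mutations per locus per generation.
    p_multistep:
        Probability that a mutation changes allele size by more than one
        repeat unit.
    multistep_q:
        Geometric parameter of the multistep magnitude: conditional on a
        multistep event, ``|S| = 1 + G`` with ``P(G=g) = (1-q) q**(g-1)``.
        For the GSM preset ``q = p_multistep``, which makes the overall step
        law ``P(|S|=s) = (1-p) p**(s-1)``.
    """

    mu: float
    p_multistep: float = 0.0
    multistep_q: float = 0.0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mutation rate must be non-negative")
        if not (0 <= self.p_multistep < 1):
            raise ValueError("p_multistep must be in [0, 1)")
        if self.p_multistep > 0 and not (0 < self.multistep_q < 1):
            raise ValueError("multistep_q must be in (0, 1) when multistep mutations occur")

    @classmethod
    def smm(cls, mu: float) -> "MutationModel":
        """Strict single-step model (every mutation is +/- one repeat)."""
        return cls(mu=mu, p_multistep=0.0, multistep_q=0.0)

    @classmethod
    def gsm(cls, mu: float, gsm_par: float) -> "MutationModel":
        """Generalized stepwise model; gsm_par is the multistep proportion."""
        if gsm_par == 0.0:
            return cls.smm(mu)
        return cls(mu=mu, p_multistep=gsm_par, multistep_q=gsm_par)

    @classmethod
    def tpm(cls, mu: float = 5e-4, p_multistep: float = 0.2,
            variance_target: float = 30.0) -> "MutationModel":
        """Two-phase model: multistep magnitude tuned to a target variance.

        The geometric parameter q solves Var(1+G) = q/(1-q)^2 = variance_target.
        """
        v = float(variance_target)
        if v <= 0:
            raise ValueError("variance_target must be positive")
        q = (2 * v + 1 - math.sqrt(4 * v + 1)) / (2 * v)
        return cls(mu=mu, p_multistep=p_multistep, multistep_q=q)

    @classmethod
    def tpm80(cls, mu: float = 5e-4) -> "MutationModel":
        """TPM with 80% single-step mutations and multistep variance 30."""
        return cls.tpm(mu=mu, p_multistep=0.2, variance_target=30.0)


@dataclass(frozen=True)
class Genealogy:
    """Binary ultrametric coalescent tree stored as parent pointers.

    Nodes 0..n-1 are tips at time 0; internal nodes are in coalescence
    order, the root is node ``2n-2`` (parent -1).
    """

    parent: np.ndarray
    node_times: np.ndarray
    n_tips: int

    def __post_init__(self):
        if self.parent.shape[0] != 2 * self.n_tips - 1:
            raise ValueError("parent array must have 2n-1 entries")

    @property
    def tmrca(self) -> float:
        return float(self.node_times[-1])

    @property
    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        nonroot = np.arange(self.parent.shape[0] - 1)
        if self.n_tips == 1:
            return np.zeros(0)
        return self.node_times[self.parent[nonroot]] - self.node_times[nonroot]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())


def simulate_genealogy(n_lineages: int, demography: DemographicModel, seed) -> Genealogy:
    """Draw one coalescent genealogy on ``n_lineages`` tips.

    Waiting times are exponential with rate ``k(k-1)/(4 Ne(t))`` and carried
    across epoch boundaries by time rescaling.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be at least 1")
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    parent, times = _kernels.sim_tree_arrays(
        n_lineages, demography.start_times, demography.sizes)
    return Genealogy(parent=parent, node_times=times, n_tips=n_lineages)


def mutate_genealogy(genealogy: Genealogy, mut: MutationModel, seed,
                     root_allele: int = ROOT_ALLELE) -> np.ndarray:
    """Drop stepwise mutations on a genealogy; return tip allele sizes."""
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    return _kernels.mutate_tips(
        genealogy.n_tips, genealogy.parent, genealogy.node_times,
        mut.mu, mut.p_multistep, mut.multistep_q, root_allele)


def simulate_dataset(n_individuals: int, n_loci: int,
                     demography: DemographicModel, mut: MutationModel, seed,
                     population: str = "sim", locus_prefix: str = "L") -> GenotypeDataset:
    """Simulate a complete single-population diploid dataset.

    One independent genealogy is drawn per locus over ``2 * n_individuals``
    gene copies, which are paired sequentially into diploids (pairing is
    arbitrary under random mating and invisible to all statistics used).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be at least 1")
    if n_loci < 1:
        raise ValueError("n_loci must be at least 1")
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    n_copies = 2 * n_individuals
    mu_per_locus = np.full(n_loci, mut.mu, dtype=np.float64)
    copies = _kernels.sim_alleles(
        n_copies, n_loci, demography.start_times, demography.sizes,
        mu_per_locus, mut.p_multistep, mut.multistep_q, ROOT_ALLELE)
    alleles = np.empty((n_individuals, n_loci, 2), dtype=np.int64)
    alleles[:, :, 0] = copies[0::2, :]
    alleles[:, :, 1] = copies[1::2, :]
    return GenotypeDataset(
        alleles=alleles,
        pop_labels=np.array([population] * n_individuals, dtype=object),
        locus_names=[f"{locus_prefix}{i + 1:02d}" for i in range(n_loci)],
    )


def simulate_tmrca(n_lineages: int, demography: DemographicModel, n_reps: int,
                   seed) -> np.ndarray:
    """TMRCA sample over independent genealogies (convenience for calibration)."""
    if n_lineages < 2:
        raise ValueError("TMRCA requires at least two lineages")
    rng = as_rng(seed)
    _kernels.seed_rng(kernel_seed(rng))
    return _kernels.sim_tmrca_batch(
        n_lineages, demography.start_times, demography.sizes, n_reps)
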