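"""Diploid microsatellite genotype container and plain-text I/O.

The universal currency of all statistics is :class:`GenotypeDataset`: an
``(n_individuals, n_loci, 2)`` integer array of allele sizes in repeat
units, with ``-1`` marking missing gene copies, plus per-individual
population labels.  Supported on-disk formats are GENEPOP (3-digit allele
codes), a tidy CSV (one row per individual x locus) and a STRUCTURE-style
two-rows-per-individual text export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeDataset", "MISSING", "read_genepop", "write_genepop",
           "read_csv", "write_csv", "write_structure"]


@dataclass
class GenotypeDataset:
    """Diploid allele-size matrix with population labels.

    alleles : (n_individuals, n_loci, 2) int array, -1 = missing copy.
    pop_labels : per-individual population identifier (object array).
    locus_names : list of locus names, length n_loci.
    repeat_unit_bp : optional per-locus motif length for base-pair conversion.
    individual_ids : optional explicit individual identifiers.
    """

    alleles: np.ndarray
    pop_labels: np.ndarray
    locus_names: list
    repeat_unit_bp: np.ndarray | None = None
    individual_ids: list | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        if self.pop_labels.shape[0] != self.alleles.shape[0]:
            raise ValueError("every individual needs a population label")
        if len(self.locus_names) != self.alleles.shape[1]:
            raise ValueError("locus_names length must match n_loci")
        if self.alleles.shape[1] < 1:
            raise ValueError("at least one locus required")
        if self.individual_ids is None:
            self.individual_ids = [f"ind_{i + 1:04d}" for i in range(self.n_individuals)]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.alleles == MISSING

    def populations(self) -> list:
        """Unique population labels in order of first appearance."""
        seen: dict = {}
        for p in self.pop_labels:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, indices) -> "GenotypeDataset":
        indices = np.asarray(indices)
        return GenotypeDataset(
            alleles=self.alleles[indices].copy(),
            pop_labels=self.pop_labels[indices].copy(),
            locus_names=list(self.locus_names),
            repeat_unit_bp=None if self.repeat_unit_bp is None else self.repeat_unit_bp.copy(),
            individual_ids=[self.individual_ids[i] for i in indices],
        )

    def for_population(self, pop) -> "GenotypeDataset":
        idx = np.where(self.pop_labels == pop)[0]
        if idx.size == 0:
            raise ValueError(f"unknown population: {pop!r}")
        return self.subset(idx)

    def gene_copies(self, locus: int, pop=None) -> np.ndarray:
        """Non-missing gene copies at one locus (optionally one population)."""
        sub = self.alleles[:, locus, :]
        if pop is not None:
            sub = sub[self.pop_labels == pop]
        flat = sub.reshape(-1)
        return flat[flat != MISSING]

    def translated(self, offset: int) -> "GenotypeDataset":
        """Shift all non-missing allele sizes by a constant (test helper)."""
        shifted = self.alleles.copy()
        shifted[shifted != MISSING] += offset
        return GenotypeDataset(shifted, self.pop_labels.copy(), list(self.locus_names),
                               individual_ids=list(self.individual_ids))


# ---------------------------------------------------------------------------
# GENEPOP

def _genepop_code(a: int) -> str:
    if a == MISSING:
        return "000"
    if not (1 <= a <= 999):
        raise ValueError(f"allele size {a} cannot be encoded as a 3-digit GENEPOP code")
    return f"{a:03d}"


def write_genepop(d: GenotypeDataset, path, title: str = "demosat export") -> None:
    """Write GENEPOP with 3-digit allele codes and one 'Pop' block per population."""
    lines = [title]
    lines.extend(str(l) for l in d.locus_names)
    for pop in d.populations():
        lines.append("Pop")
        idx = np.where(d.pop_labels == pop)[0]
        for i in idx:
            genos = " ".join(
                _genepop_code(int(d.alleles[i, l, 0])) + _genepop_code(int(d.alleles[i, l, 1]))
                for l in range(d.n_loci))
            lines.append(f"{d.individual_ids[i]} ,  {genos}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeDataset:
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh]
    raw = [l for l in raw if l.strip()]
    if len(raw) < 3:
        raise ValueError("not a GENEPOP file: too short")
    locus_names: list = []
    i = 1
    while i < len(raw) and raw[i].strip().lower() != "pop":
        # locus names may be one per line or comma separated
        locus_names.extend(s.strip() for s in raw[i].split(",") if s.strip())
        i += 1
    if i == len(raw):
        raise ValueError("not a GENEPOP file: no 'Pop' marker found")
    rows = []
    labels = []
    ids = []
    pop_counter = 0
    pop_name = None
    while i < len(raw):
        if raw[i].strip().lower() == "pop":
            pop_counter += 1
            pop_name = f"pop_{pop_counter}"
            i += 1
            continue
        line = raw[i]
        if "," not in line:
            raise ValueError(f"malformed GENEPOP individual line: {line!r}")
        ind_id, genos = line.split(",", 1)
        codes = genos.split()
        if len(codes) != len(locus_names):
            raise ValueError(
                f"individual {ind_id.strip()!r} has {len(codes)} genotypes, "
                f"expected {len(locus_names)}")
        pair_list = []
        for code in codes:
            if len(code) not in (4, 6):
                raise ValueError(f"bad genotype code {code!r}")
            half = len(code) // 2
            a1, a2 = int(code[:half]), int(code[half:])
            pair_list.append((a1 if a1 else MISSING, a2 if a2 else MISSING))
        rows.append(pair_list)
        labels.append(pop_name)
        ids.append(ind_id.strip())
        i += 1
    alleles = np.array(rows, dtype=np.int64)
    return GenotypeDataset(alleles=alleles, pop_labels=np.array(labels, dtype=object),
                           locus_names=locus_names, individual_ids=ids)


# ---------------------------------------------------------------------------
# Tidy CSV

def write_csv(d: GenotypeDataset, path) -> None:
    """Long-format CSV: individual, population, locus, allele1, allele2."""
    recs = []
    for i in range(d.n_individuals):
        for l in range(d.n_loci):
            a1, a2 = d.alleles[i, l]
            recs.append((d.individual_ids[i], d.pop_labels[i], d.locus_names[l],
                         "" if a1 == MISSING else int(a1),
                         "" if a2 == MISSING else int(a2)))
    pd.DataFrame(recs, columns=["individual", "population", "locus",
                                "allele1", "allele2"]).to_csv(path, index=False)


def read_csv(path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    ind_order = list(dict.fromkeys(df["individual"]))
    locus_order = list(dict.fromkeys(df["locus"]))
    ind_idx = {v: i for i, v in enumerate(ind_order)}
    loc_idx = {v: i for i, v in enumerate(locus_order)}
    alleles = np.full((len(ind_order), len(locus_order), 2), MISSING, dtype=np.int64)
    labels = np.empty(len(ind_order), dtype=object)
    for row in df.itertuples(index=False):
        i = ind_idx[row.individual]
        l = loc_idx[row.locus]
        labels[i] = row.population
        for c, val in enumerate((row.allele1, row.allele2)):
            if pd.notna(val) and str(val).strip() != "":
                alleles[i, l, c] = int(float(val))
    return GenotypeDataset(alleles=alleles, pop_labels=labels,
                           locus_names=locus_order, individual_ids=ind_order)


# ---------------------------------------------------------------------------
# STRUCTURE export (two rows per individual, -9 = missing)

def write_structure(d: GenotypeDataset, path) -> None:
    pops = {p: i + 1 for i, p in enumerate(d.populations())}
    with open(path, "w") as fh:
        fh.write("\t".join(str(l) for l in d.locus_names) + "\n")
        for i in range(d.n_individuals):
            for copy in (0, 1):
                vals = [str(int(a)) if a != MISSING else "-9" for a in d.alleles[i, :, copy]]
                fh.write("\t".join([d.individual_ids[i], str(pops[d.pop_labels[i]])] + vals) + "\n")
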