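"""Filtering rules and level-specific working datasets.

From the full loci x individuals table this module applies, in order, the
hypervariability filter (loci whose variability exceeds the across-locus
mean by ``var_k`` interquartile ranges are treated as collapsed
multi-copy regions and removed) and the missingness filters (individuals
holding fewer than ``theta_ind`` of the loci, then loci present in fewer
than ``theta_loc`` of the remaining individuals; both strictly "fewer
than").  Three working datasets are built per taxon subset:

* Individual — every individual that survives filtering;
* Population — the single best individual per population;
* Taxon — one composite individual per taxon, seeded from the best
  individual and filled in from members of the same population.

It also reformats a dataset for sequence-based analyses (one random
allele per unit per locus, concatenated with a partition map), for
SNP-based analyses (biallelic reduction, extra states to missing), and
resamples loci for bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import iqr

from . import _seq
from .matrix import LocusMatrix

__all__ = [
    "FilterThresholds", "Dataset", "SequenceDataset", "SNPMatrix",
    "locus_variability", "filter_hypervariable", "filter_missingness",
    "select_best_unit", "build_dataset", "to_sequence_dataset",
    "to_snp_dataset", "bootstrap_loci",
]

LEVELS = ("individual", "population", "taxon")


@dataclass
class FilterThresholds:
    var_k: float = 3.0        # IQR multiplier of the hypervariability rule
    theta_ind: float = 0.10   # minimum per-individual locus fraction
    theta_loc: float = 0.70   # minimum per-locus individual fraction

    def __post_init__(self) -> None:
        if self.var_k < 0:
            raise ValueError("var_k must be >= 0")
        for f, name in [(self.theta_ind, "theta_ind"),
                        (self.theta_loc, "theta_loc")]:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class Dataset:
    level: str
    units: list[str]
    loci: list[str]                       # ordered; may repeat after bootstrap
    lengths: dict[str, int]
    cells: dict[tuple[str, str], tuple[str, ...]]  # (locus, unit) -> alleles
    grouping: pd.DataFrame
    thresholds: FilterThresholds
    provenance: dict = field(default_factory=dict)

    @property
    def partition(self) -> list[tuple[str, int, int]]:
        """Concatenated coordinates per locus, 1-based inclusive."""
        out, pos = [], 1
        for locus in self.loci:
            n = self.lengths[locus]
            out.append((locus, pos, pos + n - 1))
            pos += n
        return out

    @property
    def total_length(self) -> int:
        return sum(self.lengths[l] for l in self.loci)

    def alleles(self, locus: str, unit: str) -> tuple[str, ...]:
        return self.cells.get((locus, unit), ())


@dataclass
class SequenceDataset:
    units: list[str]
    sequences: dict[str, str]             # unit -> concatenated supermatrix row
    partition: list[tuple[str, int, int]]

    @property
    def total_length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclass
class SNPMatrix:
    units: list[str]
    data: np.ndarray                      # (units, sites): 0, 1 or NaN
    site_map: list[tuple[str, int]]       # site -> (locus, 0-based column)

    @property
    def n_sites(self) -> int:
        return int(self.data.shape[1])


# -- per-locus variability --------------------------------------------------

def locus_variability(alignment: list[str]) -> float:
    """Proportion of alignment columns with >= 2 distinct non-missing
    states.  Length-invariant, so the interquartile-range outlier rule is
    comparable across loci of different lengths."""
    if not alignment:
        raise ValueError("empty alignment")
    arr = _seq.encode_many(alignment)
    if arr.shape[1] == 0:
        raise ValueError("zero-length alignment")
    var = 0
    for col in arr.T:
        states = np.unique(col[col < 4])
        if len(states) >= 2:
            var += 1
    return var / arr.shape[1]


def _variabilities(matrix: LocusMatrix) -> dict[str, float]:
    return {l: locus_variability(matrix.alignment(l)) if matrix.alignment(l)
            else 0.0 for l in matrix.loci}


def filter_hypervariable(matrix: LocusMatrix, var_k: float = 3.0) -> LocusMatrix:
    """Drop loci with variability > mean + var_k * IQR across loci."""
    if not matrix.lengths:
        raise ValueError("matrix has no loci")
    v = _variabilities(matrix)
    vals = np.array([v[l] for l in matrix.loci])
    cutoff = vals.mean() + var_k * iqr(vals)
    keep = [l for l in matrix.loci if v[l] <= cutoff]
    return matrix.subset(loci=keep)


def filter_missingness(matrix: LocusMatrix, theta_ind: float = 0.10,
                       theta_loc: float = 0.70) -> LocusMatrix:
    """Single pass, in order: drop individuals holding < theta_ind of the
    current loci, then loci present in < theta_loc of the remaining
    individuals.  Boundaries are strict: exactly-at-threshold units stay."""
    if not matrix.lengths or not matrix.individuals:
        raise ValueError("matrix has no loci or no individuals")
    loci = matrix.loci
    inds = [i for i in matrix.individuals
            if matrix.presence_fraction(i, loci) >= theta_ind]
    keep_loci = [l for l in loci if matrix.locus_presence(l, inds) >= theta_loc]
    if not inds or not keep_loci:
        raise ValueError(
            f"missingness filter removed everything "
            f"({len(inds)}/{len(matrix.individuals)} individuals, "
            f"{len(keep_loci)}/{len(loci)} loci remain)")
    return matrix.subset(loci=keep_loci, individuals=inds)


def select_best_unit(matrix: LocusMatrix, members: list[str],
                     read_counts: dict[str, int] | None = None) -> str:
    """The member with the most retained loci; ties break by most total
    reads, then by the lexicographically smallest id."""
    if not members:
        raise ValueError("no members to choose from")
    loci = matrix.loci

    def key(m):
        n_loci = sum(matrix.present(l, m) for l in loci)
        reads = (read_counts or {}).get(m, 0)
        return (-n_loci, -reads, m)

    return sorted(members, key=key)[0]


# -- dataset construction ---------------------------------------------------

def build_dataset(matrix: LocusMatrix, level: str, grouping: pd.DataFrame,
                  thresholds: FilterThresholds | None = None,
                  read_counts: dict[str, int] | None = None) -> Dataset:
    """Build the Individual / Population / Taxon working dataset.

    The grouping frame must cover every individual in the matrix with
    columns individual, population, taxon.  Filters are applied to the
    selected subset: hypervariability first, then missingness, so the
    emitted dataset satisfies the per-locus presence guarantee."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    thresholds = thresholds or FilterThresholds()
    g = grouping.set_index("individual")
    unknown = [i for i in matrix.individuals if i not in g.index]
    if unknown:
        raise KeyError(f"individuals missing from grouping: {unknown[:5]}")

    pre = filter_hypervariable(matrix, thresholds.var_k)

    if level == "individual":
        unit_matrix = pre
    elif level == "population":
        keep = []
        for pop, members in _members_by(pre, g, "population").items():
            keep.append(select_best_unit(pre, members, read_counts))
        unit_matrix = pre.subset(individuals=sorted(keep))
    else:  # taxon: composite individual with same-population fill-in
        lengths = dict(pre.lengths)
        cells: dict[tuple[str, str], tuple[str, ...]] = {}
        units = []
        by_taxon = _members_by(pre, g, "taxon")
        for taxon in sorted(by_taxon):
            best = select_best_unit(pre, by_taxon[taxon], read_counts)
            pop = g.loc[best, "population"]
            pop_mates = [i for i in by_taxon[taxon]
                         if g.loc[i, "population"] == pop and i != best]
            pop_mates = sorted(
                pop_mates,
                key=lambda m: (-sum(pre.present(l, m) for l in pre.loci), m))
            units.append(taxon)
            for locus in pre.loci:
                source = None
                if pre.present(locus, best):
                    source = best
                else:
                    for mate in pop_mates:
                        if pre.present(locus, mate):
                            source = mate
                            break
                if source is not None:
                    cells[(locus, taxon)] = pre.alleles(locus, source)
        unit_matrix = LocusMatrix(lengths=lengths, individuals=units,
                                  cells=cells, provenance=dict(pre.provenance))

    refiltered = filter_hypervariable(unit_matrix, thresholds.var_k)
    refiltered = filter_missingness(refiltered, thresholds.theta_ind,
                                    thresholds.theta_loc)
    return Dataset(
        level=level,
        units=list(refiltered.individuals),
        loci=refiltered.loci,
        lengths=dict(refiltered.lengths),
        cells=dict(refiltered.cells),
        grouping=grouping,
        thresholds=thresholds,
        provenance={"n_input_loci": len(matrix.lengths)},
    )


def _members_by(matrix: LocusMatrix, g: pd.DataFrame, column: str
                ) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for ind in matrix.individuals:
        out.setdefault(g.loc[ind, column], []).append(ind)
    return out


# -- reformatting -----------------------------------------------------------

def to_sequence_dataset(dataset: Dataset, rng: np.random.Generator
                        ) -> SequenceDataset:
    """One allele per unit per locus chosen uniformly at random, missing
    loci filled with N, concatenated in partition order."""
    seqs = {}
    for unit in dataset.units:
        parts = []
        for locus in dataset.loci:
            alleles = dataset.alleles(locus, unit)
            if alleles:
                parts.append(alleles[int(rng.integers(len(alleles)))])
            else:
                parts.append("N" * dataset.lengths[locus])
        seqs[unit] = "".join(parts)
    return SequenceDataset(units=list(dataset.units), sequences=seqs,
                           partition=dataset.partition)


def to_snp_dataset(dataset: Dataset, rng: np.random.Generator) -> SNPMatrix:
    """Biallelic 0/1 site matrix from a haploidised view of the dataset.

    One allele per unit per locus is drawn at random; monomorphic columns
    are dropped; at columns with more than two states, two are retained at
    random and the others become missing.  Code 0 is the state of the
    first retained unit that carries a retained state."""
    units = list(dataset.units)
    haploid = {}
    for unit in units:
        rows = []
        for locus in dataset.loci:
            alleles = dataset.alleles(locus, unit)
            if alleles:
                rows.append(_seq.encode(alleles[int(rng.integers(len(alleles)))]))
            else:
                rows.append(np.full(dataset.lengths[locus], _seq.N_CODE,
                                    dtype=np.uint8))
        haploid[unit] = rows

    cols, site_map = [], []
    for li, locus in enumerate(dataset.loci):
        block = np.stack([haploid[u][li] for u in units])  # units x L
        for col_idx in range(block.shape[1]):
            col = block[:, col_idx].astype(float)
            col[col >= 4] = np.nan
            states = np.unique(col[~np.isnan(col)])
            if len(states) < 2:
                continue
            if len(states) > 2:
                keep = rng.choice(states, size=2, replace=False)
            else:
                keep = states
            col[~np.isin(col, keep)] = np.nan
            ref = next(col[i] for i in range(len(units))
                       if not np.isnan(col[i]))
            coded = np.where(np.isnan(col), np.nan, (col != ref).astype(float))
            cols.append(coded)
            site_map.append((locus, col_idx))
    data = np.column_stack(cols) if cols else np.empty((len(units), 0))
    return SNPMatrix(units=units, data=data, site_map=site_map)


def bootstrap_loci(dataset: Dataset, B: int, rng: np.random.Generator
                   ) -> list[Dataset]:
    """B pseudo-datasets resampling loci (not sites) with replacement."""
    if B < 0:
        raise ValueError("B must be >= 0")
    reps = []
    loci = list(dataset.loci)
    for b in range(B):
        take = [loci[int(i)] for i in rng.integers(len(loci), size=len(loci))]
        reps.append(Dataset(
            level=dataset.level, units=list(dataset.units), loci=take,
            lengths=dict(dataset.lengths), cells=dataset.cells,
            grouping=dataset.grouping, thresholds=dataset.thresholds,
            provenance={**dataset.provenance, "bootstrap_replicate": b},
        ))
    return reps
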