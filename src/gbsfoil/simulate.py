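"""Synthetic GBS read sets with known ground truth.

Generates a genotyping-by-sequencing experiment for a clade with a known
ultrametric species tree: per-locus haplotypes evolve by a Jukes-Cantor
process down the tree, diploid individuals within populations add
within-population polymorphism, and optional introgression events replace
the genealogy of a fraction of loci by re-attaching the recipient lineage
to the donor lineage at the admixture time.  Locus dropout, paralogous
locus merging, sequencing coverage and per-base error emulate the
artifacts the downstream pipeline must tolerate.

Every draw comes from one seeded :class:`numpy.random.Generator`, so the
whole experiment is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _seq
from .matrix import LocusMatrix
from .simtree import LineageTree

__all__ = [
    "IntrogressionEvent", "SimulationConfig", "LocusTruth", "SyntheticTruth",
    "SimulationResult", "evolve_locus", "apply_introgression",
    "generate_reads", "corrupt", "simulate", "simulate_matrix",
    "DEFAULT_SPECIES_TREE", "study_like_config",
]

#: 13-taxon ultrametric default mirroring the study design: a calcifuge
#: clade, a calcicole clade, a Greek-endemic clade, three isolated lineages
#: and an outgroup, root depth 1 time unit (outgroup split at 1.0).
DEFAULT_SPECIES_TREE = (
    "((((((laricifolia_laricifolia:0.08,laricifolia_ophiolitica:0.08):0.12,"
    "garckeana:0.2):0.1,baldaccii:0.3):0.15,((dirphya:0.2,(parnonia:0.1,"
    "wettsteinii:0.1):0.1):0.15,capillacea_albanian:0.35):0.1):0.25,"
    "((langii:0.2,capillacea:0.2):0.3,(doerfleri:0.3,sedoides:0.3):0.2):0.2)"
    ":0.3,rupestris:1.0);"
)


@dataclass
class IntrogressionEvent:
    """Gene flow from ``donor`` into ``recipient`` affecting a fraction
    ``gamma`` of loci, with the recipient lineage attached to the donor at
    ``t_admix`` (time before present, same units as tree branch lengths).

    ``recipient`` may be a taxon (tip label) or a population id
    ``"taxon_pN"``; in the latter case only that population carries the
    introgressed haplotypes.
    """

    donor: str
    recipient: str
    gamma: float
    t_admix: float

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.t_admix < 0:
            raise ValueError("t_admix must be >= 0")


@dataclass
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    pops_per_taxon: int = 2
    inds_per_pop: int = 5
    n_loci: int = 500
    locus_length: int = 30
    mu: float = 0.02
    pop_theta: float = 0.0005
    events: list[IntrogressionEvent] = field(default_factory=list)
    dropout: float = 0.2
    paralog_rate: float = 0.05
    coverage: float = 10.0
    base_error: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pops_per_taxon < 1 or self.inds_per_pop < 1:
            raise ValueError("pops_per_taxon and inds_per_pop must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_length < 10:
            raise ValueError("locus_length must be >= 10")
        if self.mu < 0 or self.pop_theta < 0:
            raise ValueError("rates must be >= 0")
        for p, name in [(self.dropout, "dropout"),
                        (self.paralog_rate, "paralog_rate")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.base_error < 1.0:
            raise ValueError("base_error must be in [0, 1)")


@dataclass
class LocusTruth:
    locus_id: str
    label: str  # clean | introgressed | paralog
    donor: str | None = None
    recipient: str | None = None
    merged_from: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    loci: list[LocusTruth]
    alleles: dict[tuple[str, str], tuple[str, ...]]  # (individual, locus) -> alleles
    grouping: pd.DataFrame  # individual, population, taxon
    locus_length: int

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def labels(self) -> dict[str, str]:
        return {t.locus_id: t.label for t in self.loci}


@dataclass
class SimulationResult:
    readsets: dict[str, "np.ndarray"]  # individual -> (n_reads, L) uint8
    stacks: dict[str, dict[str, np.ndarray]]  # individual -> locus -> reads
    truth: SyntheticTruth
    config: SimulationConfig


def evolve_locus(tree: LineageTree, mu: float, length: int,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Jukes-Cantor evolution of one locus down a rooted tree.

    Each site substitutes on a branch of length ``b`` with probability
    ``1 - exp(-mu * b)``; the new base is uniform over the other three.
    Returns the tip haplotypes (coded uint8 arrays).
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    out: dict[str, np.ndarray] = {}

    def walk(node, seq: np.ndarray) -> None:
        for child in node.children:
            p = 1.0 - np.exp(-mu * child.length)
            child_seq = seq.copy()
            hits = rng.random(length) < p
            k = int(hits.sum())
            if k:
                child_seq[hits] = (child_seq[hits] + 1
                                   + rng.integers(0, 3, size=k, dtype=np.uint8)) % 4
            if child.is_tip:
                out[child.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.root, root_seq)
    if not out:
        raise ValueError("tree has no tips")
    return out


def apply_introgression(loci: dict[str, dict[str, np.ndarray]],
                        tree: LineageTree, event: IntrogressionEvent,
                        mu: float, rng: np.random.Generator,
                        *, population_recipient: bool = False,
                        ) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, LocusTruth]]:
    """Independently hit each locus with probability ``gamma`` and
    re-simulate hit loci on the grafted genealogy.

    Returns the updated per-locus haplotype maps and the truth labels for
    the affected loci.  With ``population_recipient`` the recipient tip is
    kept and an extra tip named after the recipient population is added.
    """
    recipient_taxon = event.recipient.split("_p")[0] if population_recipient \
        else event.recipient
    grafted = tree.grafted(event.donor, recipient_taxon, event.t_admix,
                           keep_recipient=population_recipient,
                           graft_label=event.recipient if population_recipient else None)
    length = len(next(iter(next(iter(loci.values())).values())))
    labels: dict[str, LocusTruth] = {}
    out = dict(loci)
    for locus_id in sorted(loci):
        if rng.random() < event.gamma:
            out[locus_id] = evolve_locus(grafted, mu, length, rng)
            labels[locus_id] = LocusTruth(locus_id, "introgressed",
                                          donor=event.donor,
                                          recipient=event.recipient)
    return out, labels


def generate_reads(alleles: np.ndarray, coverage: float, base_error: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Poisson(coverage) reads per allele with uniform per-base errors.

    ``alleles`` is an (n_alleles, L) coded array; the result stacks all
    reads for the read stack of one (individual, locus).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    depths = rng.poisson(coverage, size=alleles.shape[0])
    if depths.sum() == 0:
        return np.empty((0, alleles.shape[1]), dtype=np.uint8)
    reads = np.repeat(alleles, depths, axis=0).copy()
    if base_error > 0:
        flips = rng.random(reads.shape) < base_error
        k = int(flips.sum())
        if k:
            reads[flips] = (reads[flips] + 1
                            + rng.integers(0, 3, size=k, dtype=np.uint8)) % 4
    return reads


def corrupt(stacks: dict[str, dict[str, np.ndarray]], dropout: float,
            paralog_rate: float, rng: np.random.Generator,
            locus_ids: list[str] | None = None,
            ) -> tuple[dict[str, dict[str, np.ndarray]], list[tuple[str, str]]]:
    """Delete read stacks per (individual, locus) with probability
    ``dropout`` and merge a fraction ``paralog_rate`` of loci pairwise
    (reads relabelled to the first locus id of each pair), emulating
    multi-copy regions collapsing into one hypervariable composite locus.

    Returns the corrupted stacks and the list of (kept, absorbed) merges.
    """
    if locus_ids is None:
        locus_ids = sorted({l for s in stacks.values() for l in s})
    out: dict[str, dict[str, np.ndarray]] = {}
    for ind in sorted(stacks):
        out[ind] = {}
        for locus in sorted(stacks[ind]):
            if rng.random() >= dropout:
                out[ind][locus] = stacks[ind][locus]
    n_pairs = int(np.floor(paralog_rate * len(locus_ids) / 2))
    merges: list[tuple[str, str]] = []
    if n_pairs:
        chosen = rng.choice(len(locus_ids), size=2 * n_pairs, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            keep, absorb = sorted([locus_ids[a], locus_ids[b]])
            merges.append((keep, absorb))
            for ind in out:
                if absorb in out[ind]:
                    moved = out[ind].pop(absorb)
                    if keep in out[ind]:
                        out[ind][keep] = np.vstack([out[ind][keep], moved])
                    else:
                        out[ind][keep] = moved
    return out, merges


# ---------------------------------------------------------------------------

def _grouping_frame(taxa: list[str], pops_per_taxon: int,
                    inds_per_pop: int) -> pd.DataFrame:
    rows = []
    for taxon in sorted(taxa):
        for p in range(1, pops_per_taxon + 1):
            pop = f"{taxon}_p{p}"
            for i in range(1, inds_per_pop + 1):
                rows.append({"individual": f"{pop}_i{i}",
                             "population": pop, "taxon": taxon})
    return pd.DataFrame(rows)


def _simulate_alleles(config: SimulationConfig, rng: np.random.Generator
                      ) -> tuple[SyntheticTruth, pd.DataFrame]:
    """Core stages shared by the read-level and matrix-level entry points:
    locus genealogies (with introgression), taxon haplotypes, and diploid
    individual alleles with within-population polymorphism."""
    tree = LineageTree.from_newick(config.species_tree)
    taxa = tree.tip_labels
    grouping = _grouping_frame(taxa, config.pops_per_taxon, config.inds_per_pop)

    width = max(4, len(str(config.n_loci - 1)))
    locus_ids = [f"L{i:0{width}d}" for i in range(config.n_loci)]
    loci = {lid: evolve_locus(tree, config.mu, config.locus_length, rng)
            for lid in locus_ids}
    truth_records = {lid: LocusTruth(lid, "clean") for lid in locus_ids}

    pop_level = {e.recipient for e in config.events
                 if e.recipient not in tree.tips}
    for event in config.events:
        is_pop = event.recipient in pop_level
        if is_pop and event.recipient.split("_p")[0] not in tree.tips:
            raise KeyError(f"recipient {event.recipient!r} matches no taxon")
        loci, labels = apply_introgression(loci, tree, event, config.mu, rng,
                                           population_recipient=is_pop)
        truth_records.update(labels)

    L = config.locus_length
    alleles: dict[tuple[str, str], tuple[str, ...]] = {}
    for row in grouping.itertuples(index=False):
        for lid in locus_ids:
            haps = loci[lid]
            base = haps[row.population] if row.population in haps \
                else haps[row.taxon]
            pair = []
            for _ in range(2):
                al = base.copy()
                k = min(int(rng.poisson(config.pop_theta * L)), L)
                if k:
                    sites = rng.choice(L, size=k, replace=False)
                    al[sites] = (al[sites] + 1
                                 + rng.integers(0, 3, size=k, dtype=np.uint8)) % 4
                pair.append(_seq.decode(al))
            alleles[(row.individual, lid)] = tuple(pair)

    truth = SyntheticTruth(loci=[truth_records[lid] for lid in locus_ids],
                           alleles=alleles, grouping=grouping,
                           locus_length=L)
    return truth, grouping


def _apply_merges_to_truth(truth: SyntheticTruth,
                           merges: list[tuple[str, str]]) -> None:
    by_id = {t.locus_id: t for t in truth.loci}
    for keep, absorb in merges:
        by_id[keep].label = "paralog"
        by_id[keep].merged_from = (keep, absorb)
        by_id[absorb].label = "paralog"
        by_id[absorb].merged_from = (keep, absorb)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Full read-level simulation: alleles -> read stacks -> dropout and
    paralog merging -> flattened per-individual read sets."""
    rng = np.random.default_rng(config.seed)
    truth, grouping = _simulate_alleles(config, rng)
    locus_ids = [t.locus_id for t in truth.loci]

    stacks: dict[str, dict[str, np.ndarray]] = {}
    for ind in sorted(grouping["individual"]):
        stacks[ind] = {}
        for lid in locus_ids:
            pair = np.stack([_seq.encode(a) for a in truth.alleles[(ind, lid)]])
            reads = generate_reads(pair, config.coverage, config.base_error, rng)
            if len(reads):
                stacks[ind][lid] = reads
    stacks, merges = corrupt(stacks, config.dropout, config.paralog_rate,
                             rng, locus_ids=locus_ids)
    _apply_merges_to_truth(truth, merges)

    readsets = {}
    for ind in sorted(stacks):
        if stacks[ind]:
            readsets[ind] = np.vstack([stacks[ind][l] for l in sorted(stacks[ind])])
        else:
            readsets[ind] = np.empty((0, config.locus_length), dtype=np.uint8)
    return SimulationResult(readsets=readsets, stacks=stacks, truth=truth,
                            config=config)


def simulate_matrix(config: SimulationConfig) -> tuple[LocusMatrix, SyntheticTruth]:
    """Allele-level shortcut: the exact locus x individual allele table the
    assembly stage would recover from error-free data, with dropout and
    paralog merging applied directly.  Used to exercise filtering and the
    introgression scan at scales where read-level assembly is not the
    point."""
    rng = np.random.default_rng(config.seed)
    truth, grouping = _simulate_alleles(config, rng)
    locus_ids = [t.locus_id for t in truth.loci]
    individuals = sorted(grouping["individual"])

    cells: dict[tuple[str, str], tuple[str, ...]] = {}
    for ind in individuals:
        for lid in locus_ids:
            if rng.random() >= config.dropout:
                cells[(lid, ind)] = truth.alleles[(ind, lid)]

    n_pairs = int(np.floor(config.paralog_rate * len(locus_ids) / 2))
    merges: list[tuple[str, str]] = []
    if n_pairs:
        chosen = rng.choice(len(locus_ids), size=2 * n_pairs, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            keep, absorb = sorted([locus_ids[a], locus_ids[b]])
            merges.append((keep, absorb))
            for ind in individuals:
                got = cells.pop((absorb, ind), None)
                if got is not None:
                    cells[(keep, ind)] = tuple(cells.get((keep, ind), ())) + got
    _apply_merges_to_truth(truth, merges)

    kept = [l for l in locus_ids if l not in {m[1] for m in merges}]
    matrix = LocusMatrix(
        lengths={l: config.locus_length for l in kept},
        individuals=individuals,
        cells=cells,
        provenance={"source": "simulate_matrix", "seed": config.seed},
    )
    return matrix, truth


def study_like_config(**overrides) -> SimulationConfig:
    """The desk-scale default system: 13 taxa, 2 populations per taxon,
    5 individuals per population, 500 short loci."""
    return SimulationConfig(**overrides)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["events"] = [asdict(e) for e in config.events]
    return d
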