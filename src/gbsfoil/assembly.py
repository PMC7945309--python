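"""Two-step de novo locus construction.

Step one clusters the unique reads of a small set of representative
individuals into reference loci (single-linkage at an identity threshold,
majority consensus).  Step two assigns every individual's reads to those
reference loci by best-hit identity search with a winner margin, then
calls per-individual alleles with a majority error-correction step.

Reads are equal-length, restriction-site anchored fragments, so identity
is positional (no gaps); similarity search is plain vectorised identity
rather than a seeded aligner, which at GBS fragment lengths is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import _seq
from .matrix import LocusMatrix

__all__ = [
    "ReadSet", "ReferenceLocus", "ReferenceLoci", "IndividualGenotype",
    "build_reference_loci", "assign_to_loci", "compile_locus_matrix",
    "pick_representatives",
]


@dataclass
class ReadSet:
    individual: str
    reads: np.ndarray  # (n_reads, L) uint8 codes

    @classmethod
    def from_sequences(cls, individual: str, sequences) -> "ReadSet":
        return cls(individual, _seq.encode_many(sequences))

    @property
    def n_reads(self) -> int:
        return int(self.reads.shape[0])

    def unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique read sequences and their multiplicities."""
        if self.n_reads == 0:
            return self.reads, np.zeros(0, dtype=np.int64)
        return np.unique(self.reads, axis=0, return_counts=True)

    @property
    def n_unique(self) -> int:
        return int(self.unique()[0].shape[0])


@dataclass
class ReferenceLocus:
    locus_id: str
    consensus: str
    members: tuple[str, ...]
    depth: int


@dataclass
class ReferenceLoci:
    loci: list[ReferenceLocus]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def consensus_matrix(self) -> np.ndarray:
        return _seq.encode_many([l.consensus for l in self.loci])


@dataclass
class IndividualGenotype:
    individual: str
    calls: dict[str, tuple[str, ...]]  # locus -> alleles
    n_unassigned: int = 0


# -- identity machinery -----------------------------------------------------

def _onehot(codes: np.ndarray) -> np.ndarray:
    """(n, L) codes -> (n, 4L) float32 one-hot; N/gap match nothing."""
    oh = codes[:, :, None] == np.arange(4, dtype=np.uint8)[None, None, :]
    return oh.reshape(codes.shape[0], -1).astype(np.float32)


def _identity_block(a: np.ndarray, b: np.ndarray, block: int = 1024):
    """Yield (row_range, identity_rows) for the pairwise identity of coded
    arrays a (n, L) and b (m, L)."""
    L = a.shape[1]
    bh = _onehot(b)
    for start in range(0, a.shape[0], block):
        ah = _onehot(a[start:start + block])
        yield start, (ah @ bh.T) / L


def _check_lengths(arrays: list[np.ndarray]) -> int:
    lens = {a.shape[1] for a in arrays if a.size}
    if len(lens) > 1:
        raise ValueError(
            f"mixed read lengths {sorted(lens)}; apply a pad/trim policy first")
    return lens.pop() if lens else 0


def _consensus(reads: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted per-column majority; ties go to the smallest base (A<C<G<T)."""
    counts = np.zeros((4, reads.shape[1]))
    for b in range(4):
        counts[b] = ((reads == b) * weights[:, None]).sum(axis=0)
    return counts.argmax(axis=0).astype(np.uint8)


# -- step one: reference loci -----------------------------------------------

def build_reference_loci(representatives: list[ReadSet], tau_id: float = 0.90,
                         min_depth: int = 3, rng=None) -> ReferenceLoci:
    """Single-linkage cluster the representatives' unique reads at
    >= ``tau_id`` identity; discard clusters of summed depth < ``min_depth``;
    consensus by per-column majority.  Clusters whose consensi are
    themselves >= ``tau_id`` identical are merged until stable."""
    if not 0.0 < tau_id <= 1.0:
        raise ValueError("tau_id must be in (0, 1]")
    if not representatives:
        raise ValueError("need at least one representative read set")
    uniq_parts, count_parts = [], []
    for rs in representatives:
        u, c = rs.unique()
        if u.size:
            uniq_parts.append(u)
            count_parts.append(c)
    if not uniq_parts:
        raise ValueError("representatives contain no reads")
    _check_lengths(uniq_parts)
    pooled = np.vstack(uniq_parts)
    counts = np.concatenate(count_parts)
    # re-deduplicate across individuals
    pooled, inverse = np.unique(pooled, axis=0, return_inverse=True)
    counts = np.bincount(inverse, weights=counts).astype(np.int64)

    labels = _single_linkage(pooled, tau_id)

    clusters: list[tuple[np.ndarray, np.ndarray]] = []
    for lab in range(labels.max() + 1):
        idx = np.nonzero(labels == lab)[0]
        if counts[idx].sum() >= min_depth:
            clusters.append((pooled[idx], counts[idx]))

    clusters = _merge_close_consensi(clusters, tau_id)

    records = []
    for reads, w in clusters:
        cons = _seq.decode(_consensus(reads, w))
        members = tuple(sorted(_seq.decode(r) for r in reads))
        records.append((int(w.sum()), cons, members))
    records.sort(key=lambda r: (-r[0], r[1]))
    width = max(4, len(str(len(records))))
    loci = [ReferenceLocus(f"R{i:0{width}d}", cons, members, depth)
            for i, (depth, cons, members) in enumerate(records)]
    return ReferenceLoci(loci, params={"tau_id": tau_id, "min_depth": min_depth})


def _single_linkage(reads: np.ndarray, tau_id: float) -> np.ndarray:
    n = reads.shape[0]
    rows, cols = [], []
    for start, ident in _identity_block(reads, reads):
        r, c = np.nonzero(ident >= tau_id - 1e-12)
        rows.append(r + start)
        cols.append(c)
    adj = coo_matrix((np.ones(sum(len(r) for r in rows)),
                      (np.concatenate(rows), np.concatenate(cols))),
                     shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


def _merge_close_consensi(clusters, tau_id):
    while len(clusters) > 1:
        cons = np.stack([_consensus(r, w) for r, w in clusters])
        L = cons.shape[1]
        ident = (_onehot(cons) @ _onehot(cons).T) / L
        np.fill_diagonal(ident, 0.0)
        if not (ident >= tau_id - 1e-12).any():
            break
        adj = coo_matrix(ident >= tau_id - 1e-12)
        _, labels = connected_components(adj, directed=False)
        merged = []
        for lab in range(labels.max() + 1):
            idx = np.nonzero(labels == lab)[0]
            merged.append((np.vstack([clusters[i][0] for i in idx]),
                           np.concatenate([clusters[i][1] for i in idx])))
        if len(merged) == len(clusters):
            break
        clusters = merged
    return clusters


# -- step two: read assignment and allele calling ---------------------------

def assign_to_loci(readset: ReadSet, reference: ReferenceLoci,
                   tau_assign: float = 0.90, margin: float = 0.02,
                   min_depth: int = 3, a_max: int = 4,
                   correct_radius: int = 2) -> IndividualGenotype:
    """Best-hit assignment of one individual's reads to the reference loci,
    followed by allele calling.

    A unique read goes to the locus of maximal identity if that identity is
    >= ``tau_assign`` and beats the runner-up by >= ``margin``.  Within a
    locus, exact sequences with depth >= ``min_depth`` seed the alleles;
    shallower sequences within ``correct_radius`` mismatches of a seed are
    corrected onto it (majority error correction); at most ``a_max`` of the
    deepest alleles are kept."""
    if len(reference) == 0:
        raise ValueError("reference is empty")
    uniq, counts = readset.unique()
    if uniq.size == 0:
        return IndividualGenotype(readset.individual, {}, 0)
    cons = reference.consensus_matrix()
    if uniq.shape[1] != cons.shape[1]:
        raise ValueError("read length does not match reference locus length")

    best_idx = np.empty(uniq.shape[0], dtype=np.int64)
    best = np.empty(uniq.shape[0])
    second = np.full(uniq.shape[0], -np.inf)
    for start, ident in _identity_block(uniq, cons):
        sl = slice(start, start + ident.shape[0])
        best_idx[sl] = ident.argmax(axis=1)
        srt = np.sort(ident, axis=1)
        best[sl] = srt[:, -1]
        if ident.shape[1] > 1:
            second[sl] = srt[:, -2]
    assigned = (best >= tau_assign - 1e-12) & (best - second >= margin - 1e-12)

    calls: dict[str, tuple[str, ...]] = {}
    n_unassigned = int(counts[~assigned].sum())
    ids = reference.ids
    for li in np.unique(best_idx[assigned]):
        take = assigned & (best_idx == li)
        seqs, depth = uniq[take], counts[take].copy()
        order = np.lexsort(seqs.T[::-1])  # lexicographic, for determinism
        seqs, depth = seqs[order], depth[order]
        seeds = np.nonzero(depth >= min_depth)[0]
        if len(seeds) == 0:
            continue
        corrected = depth.astype(np.int64)
        for j in np.nonzero(depth < min_depth)[0]:
            dists = (seqs[seeds] != seqs[j]).sum(axis=1)
            k = int(dists.argmin())
            if dists[k] <= correct_radius:
                corrected[seeds[k]] += corrected[j]
            corrected[j] = 0
        alive = [s for s in seeds if corrected[s] >= min_depth]
        alive.sort(key=lambda s: (-corrected[s], _seq.decode(seqs[s])))
        alleles = tuple(_seq.decode(seqs[s]) for s in alive[:a_max])
        if alleles:
            calls[ids[li]] = alleles
    return IndividualGenotype(readset.individual, calls, n_unassigned)


def compile_locus_matrix(genotypes: list[IndividualGenotype],
                         reference: ReferenceLoci) -> LocusMatrix:
    """Assemble the full loci x individuals allele table; empty cells record
    missingness.  Raises on any per-locus length conflict, naming the locus
    and individual."""
    lengths = {l.locus_id: len(l.consensus) for l in reference.loci}
    individuals = sorted(g.individual for g in genotypes)
    cells = {}
    for g in genotypes:
        for locus, alleles in g.calls.items():
            cells[(locus, g.individual)] = alleles
    return LocusMatrix(lengths=lengths, individuals=individuals, cells=cells,
                       provenance={"reference_params": dict(reference.params)})


def pick_representatives(readsets: dict[str, ReadSet], grouping,
                         ) -> list[ReadSet]:
    """One representative per taxon: the individual with the most unique
    reads (ties to the lexicographically smallest id)."""
    by_taxon: dict[str, list[str]] = {}
    for row in grouping.itertuples(index=False):
        by_taxon.setdefault(row.taxon, []).append(row.individual)
    reps = []
    for taxon in sorted(by_taxon):
        members = [i for i in sorted(by_taxon[taxon]) if i in readsets]
        if not members:
            continue
        best = max(members, key=lambda i: (readsets[i].n_unique, ))
        reps.append(readsets[best])
    return reps
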