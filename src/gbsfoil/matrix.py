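"""The loci x individuals allele table produced by assembly (or simulation).

A :class:`LocusMatrix` holds, for every reference locus and every
individual, the set of allele sequences called for that individual (or
nothing, if the locus dropped out).  All sequences at a locus share one
length: GBS fragments are restriction-site anchored, so the per-locus
alignment is positional and gap-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


@dataclass
class LocusMatrix:
    lengths: dict[str, int]
    individuals: list[str]
    cells: dict[tuple[str, str], tuple[str, ...]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (locus, ind), alleles in self.cells.items():
            if locus not in self.lengths:
                raise ValueError(f"cell references unknown locus {locus!r}")
            if ind not in set(self.individuals):
                raise ValueError(f"cell references unknown individual {ind!r}")
            if not alleles:
                raise ValueError(f"empty allele set at ({locus}, {ind})")
            bad = [a for a in alleles if len(a) != self.lengths[locus]]
            if bad:
                raise ValueError(
                    f"length conflict at locus {locus!r}, individual {ind!r}: "
                    f"expected {self.lengths[locus]}, got {len(bad[0])}")

    @property
    def loci(self) -> list[str]:
        return sorted(self.lengths)

    def present(self, locus: str, ind: str) -> bool:
        return (locus, ind) in self.cells

    def alleles(self, locus: str, ind: str) -> tuple[str, ...]:
        return self.cells.get((locus, ind), ())

    def alignment(self, locus: str) -> list[str]:
        """All allele sequences at a locus, individuals in sorted order."""
        out: list[str] = []
        for ind in sorted(self.individuals):
            out.extend(self.cells.get((locus, ind), ()))
        return out

    def presence_fraction(self, ind: str, loci: Iterable[str] | None = None) -> float:
        loci = list(loci) if loci is not None else self.loci
        if not loci:
            return 0.0
        return sum(self.present(l, ind) for l in loci) / len(loci)

    def locus_presence(self, locus: str, individuals: Iterable[str] | None = None) -> float:
        inds = list(individuals) if individuals is not None else self.individuals
        if not inds:
            return 0.0
        return sum(self.present(locus, i) for i in inds) / len(inds)

    def missing_fraction(self) -> float:
        """Overall fraction of empty (locus, individual) cells."""
        total = len(self.lengths) * len(self.individuals)
        return 1.0 - len(self.cells) / total if total else 0.0

    def subset(self, loci: Iterable[str] | None = None,
               individuals: Iterable[str] | None = None) -> "LocusMatrix":
        keep_l = set(loci) if loci is not None else set(self.lengths)
        keep_i = list(individuals) if individuals is not None else list(self.individuals)
        keep_i_set = set(keep_i)
        return LocusMatrix(
            lengths={l: n for l, n in self.lengths.items() if l in keep_l},
            individuals=keep_i,
            cells={(l, i): a for (l, i), a in self.cells.items()
                   if l in keep_l and i in keep_i_set},
            provenance=dict(self.provenance),
        )
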