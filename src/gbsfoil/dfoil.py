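"""Five-taxon D-statistics over polarized site patterns.

For a symmetric five-taxon phylogeny (((P1,P2),(P3,P4)),O) with the
(P1,P2) divergence no older than the (P3,P4) divergence, each biallelic
alignment column is polarized against the outgroup allele and recorded as
a 4-bit pattern b1 b2 b3 b4 (1 = derived).  Four D statistics — DFO, DIL,
DFI, DOL — are signed, normalised differences of pattern-count sums whose
terms pair off with equal expectation under the null (no gene flow)
species tree, so each has expectation zero without introgression.  The
combination of their significant signs identifies which pair of taxa
exchanged genes and, for taxon-to-taxon events, in which direction; gene
flow between the (P1,P2) ancestor and P3 or P4 is detected without
direction.

Each statistic D = (L - R) / (L + R) is tested with the chi-square
statistic (L - R)^2 / (L + R) against a 1-df upper tail, which is the
normal approximation to an equal-split binomial test on (L, R).

The L/R pattern subsets and the sign table below are locked by unit
tests: against hand-enumerated columns, against first-order expected
pattern counts on fixed genealogies, and against coalescent simulation
with pulse admixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2

from . import _seq

__all__ = [
    "PatternCounts", "DStat", "IntrogressionCall", "DfoilResult",
    "count_site_patterns", "dstat", "dfoil_test", "classify_signs",
    "PATTERNS", "STAT_PATTERNS", "SIGN_TABLE",
]

#: the sixteen polarized patterns, indexed b1*8 + b2*4 + b3*2 + b4
PATTERNS = tuple(
    "".join("BA"[1 - ((i >> s) & 1)] for s in (3, 2, 1, 0)) for i in range(16)
)
_IDX = {p: i for i, p in enumerate(PATTERNS)}

#: left / right pattern subsets of the four statistics.  Within each
#: statistic every left pattern is mirrored by a right pattern of equal
#: null expectation (terminal-depth or exchange symmetry of the
#: ultrametric species tree).
STAT_PATTERNS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DFO": (("BABA", "BBBA", "ABAB", "AAAB"),
            ("BAAB", "BBAB", "ABBA", "AABA")),
    "DIL": (("ABBA", "BBBA", "BAAB", "AAAB"),
            ("ABAB", "BBAB", "BABA", "AABA")),
    "DFI": (("BABA", "BABB", "ABAB", "ABAA"),
            ("ABBA", "ABBB", "BAAB", "BAAA")),
    "DOL": (("BABA", "BAAA", "ABAB", "ABBB"),
            ("ABBA", "ABAA", "BAAB", "BABB")),
}

#: singleton-derived patterns; the alternate mode drops terms that depend
#: on them (they are the patterns most inflated by sequencing error).
_SINGLETONS = ("BAAA", "ABAA", "AABA", "AAAB")

STAT_NAMES = tuple(STAT_PATTERNS)

#: sign signature -> (category, donor position, recipient position).
#: Derived from first-order pattern expectations under locus-genealogy
#: replacement (see module docstring); ancestral-donor events are
#: symmetric in direction.
SIGN_TABLE: dict[tuple[int, int, int, int], tuple[str, str | None, str | None]] = {
    (0, 0, 0, 0): ("none", None, None),
    (+1, +1, +1, 0): ("P1-P3", "P1", "P3"),
    (+1, 0, +1, -1): ("P1-P3", "P3", "P1"),
    (+1, +1, -1, 0): ("P2-P3", "P2", "P3"),
    (0, +1, -1, +1): ("P2-P3", "P3", "P2"),
    (-1, -1, 0, -1): ("P1-P4", "P1", "P4"),
    (-1, 0, +1, -1): ("P1-P4", "P4", "P1"),
    (-1, -1, 0, +1): ("P2-P4", "P2", "P4"),
    (0, -1, -1, +1): ("P2-P4", "P4", "P2"),
    (+1, +1, 0, 0): ("anc(P1,P2)-P3", None, None),
    (-1, -1, 0, 0): ("anc(P1,P2)-P4", None, None),
}


@dataclass
class PatternCounts:
    counts: np.ndarray                    # 16 cells, PATTERNS order
    n_sites_used: int
    n_sites_skipped: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (16,):
            raise ValueError("counts must have 16 cells")
        if (self.counts < 0).any():
            raise ValueError("negative pattern count")
        if self.counts.sum() != self.n_sites_used:
            raise ValueError("counts do not sum to n_sites_used")

    def __getitem__(self, pattern: str) -> int:
        return int(self.counts[_IDX[pattern]])

    def total(self, patterns) -> int:
        return int(sum(self.counts[_IDX[p]] for p in patterns))


@dataclass
class DStat:
    name: str
    L: float
    R: float
    value: float
    chi2: float
    p: float
    sign: int  # +1 / 0 / -1; 0 iff not significant at alpha


@dataclass
class IntrogressionCall:
    category: str                         # none | P1-P3 | ... | anc(P1,P2)-P3 | ambiguous
    donor: str | None = None              # position label when polarized
    recipient: str | None = None


@dataclass
class DfoilResult:
    stats: dict[str, DStat]
    call: IntrogressionCall
    mode: str
    alpha: float
    counts: PatternCounts
    quintet: tuple[str, ...] = field(default=())

    @property
    def signs(self) -> tuple[int, int, int, int]:
        return tuple(self.stats[n].sign for n in STAT_NAMES)


def count_site_patterns(seqs) -> PatternCounts:
    """Polarized biallelic pattern counts from five equal-length sequences
    ordered P1, P2, P3, P4, outgroup.

    A column is used iff no sequence has N or a gap there and at most two
    states occur among the five (monomorphic columns fall in the
    all-ancestral cell, which no statistic consumes; columns with three or
    more states cannot be polarized and are skipped); derived (1) means
    different from the outgroup state."""
    arr = seqs if isinstance(seqs, np.ndarray) else _seq.encode_many(list(seqs))
    if arr.shape[0] != 5:
        raise ValueError("need exactly five sequences (P1, P2, P3, P4, O)")
    n_cols = arr.shape[1]
    valid = (arr < 4).all(axis=0)
    present = np.stack([(arr == b).any(axis=0) for b in range(4)])
    biallelic = valid & (present.sum(axis=0) <= 2)
    derived = (arr[:4] != arr[4]).astype(np.int64)
    idx = (derived * np.array([[8], [4], [2], [1]])).sum(axis=0)
    counts = np.bincount(idx[biallelic], minlength=16)
    used = int(biallelic.sum())
    return PatternCounts(counts=counts, n_sites_used=used,
                         n_sites_skipped=n_cols - used)


def dstat(L: float, R: float, alpha: float = 0.01, name: str = "D") -> DStat:
    """One signed D statistic with its chi-square significance.

    Convention: with L + R = 0 the statistic is 0 with sign 0."""
    if L < 0 or R < 0:
        raise ValueError("pattern sums must be >= 0")
    total = L + R
    if total == 0:
        return DStat(name, L, R, 0.0, 0.0, 1.0, 0)
    value = (L - R) / total
    chi2 = (L - R) ** 2 / total
    p = float(_chi2.sf(chi2, df=1))
    sign = 0 if p > alpha else int(np.sign(L - R))
    return DStat(name, L, R, value, chi2, p, sign)


def dfoil_test(counts: PatternCounts, alpha: float = 0.01,
               mode: str = "auto", min_singletons: int = 20) -> DfoilResult:
    """The four statistics plus the sign-pattern classification.

    ``mode``: ``dfoil`` uses the full pattern subsets; ``dfoil_alt`` drops
    the singleton-dependent terms; ``auto`` picks ``dfoil_alt`` when the
    total singleton count falls below ``min_singletons`` (too few
    singletons to estimate their balance)."""
    if mode not in ("dfoil", "dfoil_alt", "auto"):
        raise ValueError("mode must be dfoil, dfoil_alt or auto")
    resolved = mode
    if mode == "auto":
        n_single = counts.total(_SINGLETONS)
        resolved = "dfoil_alt" if n_single < min_singletons else "dfoil"
    stats = {}
    for name, (left, right) in STAT_PATTERNS.items():
        if resolved == "dfoil_alt":
            left = tuple(p for p in left if p not in _SINGLETONS)
            right = tuple(p for p in right if p not in _SINGLETONS)
        stats[name] = dstat(counts.total(left), counts.total(right),
                            alpha=alpha, name=name)
    signs = tuple(stats[n].sign for n in STAT_NAMES)
    call = classify_signs(signs)
    return DfoilResult(stats=stats, call=call, mode=resolved, alpha=alpha,
                       counts=counts)


def classify_signs(signs) -> IntrogressionCall:
    """Map a significant-sign 4-vector (DFO, DIL, DFI, DOL) to an
    introgression call; any vector outside the table is ambiguous."""
    key = tuple(int(s) for s in signs)
    if len(key) != 4 or any(s not in (-1, 0, 1) for s in key):
        raise ValueError("signs must be four values in {-1, 0, +1}")
    if key in SIGN_TABLE:
        category, donor, recipient = SIGN_TABLE[key]
        return IntrogressionCall(category, donor, recipient)
    return IntrogressionCall("ambiguous")
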