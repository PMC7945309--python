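"""Tree-constrained exhaustive five-taxon introgression scan.

Every unordered pair-of-pairs {{P1,P2},{P3,P4}} of distinct ingroup tips
is tested if it is compatible with the ultrametric guide tree: both pair
ancestors must be strictly younger than the joint ancestor of the four
tips, the two pair lineages must be disjoint, and the (P1,P2) divergence
must be no older than the (P3,P4) divergence (the applicability condition
of the five-taxon statistics).  Each test consumes the five supermatrix
rows (quartet plus outgroup), and significant tests are aggregated into
taxon-pair summaries with the reporting thresholds used for the study
(pairs with more than 5% of their eligible tests significant; pairs with
more than 50 predicted events examined in detail).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import _seq
from .datasets import SequenceDataset
from .dfoil import STAT_NAMES, DfoilResult, count_site_patterns, dfoil_test

__all__ = [
    "UltrametricTree", "ScanConfig", "ScanRecord", "ScanTable", "PairSummary",
    "make_ultrametric", "enumerate_quartets", "run_scan", "aggregate",
]

DEFAULT_TOLERANCE = 1e-6


@dataclass
class UltrametricTree:
    """A rooted tree whose tips are the scan units, with node depths
    (time before present) driving quartet enumeration."""

    tree: dendropy.Tree
    tolerance: float = DEFAULT_TOLERANCE
    tips: list[str] = field(init=False)
    _mrca_depth: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        leaves = self.tree.leaf_nodes()
        if len(leaves) < 2:
            raise ValueError("tree needs at least two tips")
        self.tips = sorted(l.taxon.label.replace(" ", "_") for l in leaves)
        depths = _root_tip_distances(self.tree)
        height = max(depths.values())
        scale = max(1.0, height)
        worst = sorted(depths, key=depths.get)
        if height - depths[worst[0]] > self.tolerance * scale:
            raise ValueError(
                "tree is not ultrametric: root-to-tip span "
                f"{depths[worst[0]]:.6g}..{height:.6g} "
                f"(worst tips {worst[0]!r} vs {worst[-1]!r}); "
                "run make_ultrametric first")
        self.height = height
        self._mrca_depth = _mrca_depth_matrix(self.tree, self.tips, height)

    def depth(self, a: str, b: str) -> float:
        """Age of the most recent common ancestor of two tips."""
        i, j = self.tips.index(a), self.tips.index(b)
        return float(self._mrca_depth[i, j])


def _root_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    out = {}

    def walk(node, d):
        for ch in node.child_nodes():
            e = ch.edge.length or 0.0
            if ch.is_leaf():
                out[ch.taxon.label.replace(" ", "_")] = d + e
            else:
                walk(ch, d + e)

    walk(tree.seed_node, 0.0)
    return out


def _mrca_depth_matrix(tree: dendropy.Tree, tips: list[str], height: float
                       ) -> np.ndarray:
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    depth = np.zeros((n, n))

    def walk(node, d):
        """Returns the set of tip indices below node; fills MRCA depths."""
        if node.is_leaf():
            return [idx[node.taxon.label.replace(" ", "_")]]
        below = []
        child_sets = []
        for ch in node.child_nodes():
            s = walk(ch, d + (ch.edge.length or 0.0))
            child_sets.append(s)
            below.extend(s)
        age = height - d
        for sa, sb in itertools.combinations(child_sets, 2):
            for i in sa:
                for j in sb:
                    depth[i, j] = depth[j, i] = age
        return below

    walk(tree.seed_node, 0.0)
    return depth


def make_ultrametric(tree: dendropy.Tree | str, method: str = "require",
                     tolerance: float = DEFAULT_TOLERANCE,
                     terminal_pad: float = 1.0) -> UltrametricTree:
    """Validate or repair a rooted tree into an ultrametric one.

    ``require`` validates within tolerance and fails otherwise;
    ``equal_terminals`` re-assigns every terminal branch so that all tip
    depths equal (deepest internal node plus ``terminal_pad``), given the
    internal branch lengths; ``mean_path`` smooths node ages recursively
    to the mean path length to descendant tips.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree = tree.clone(depth=1)
    if method == "require":
        return UltrametricTree(tree, tolerance=tolerance)
    if method == "equal_terminals":
        parent_depth = {}

        def walk(node, d):
            for ch in node.child_nodes():
                if ch.is_leaf():
                    parent_depth[ch] = d
                else:
                    walk(ch, d + (ch.edge.length or 0.0))

        walk(tree.seed_node, 0.0)
        target = max(parent_depth.values()) + terminal_pad
        for leaf, d in parent_depth.items():
            leaf.edge.length = target - d
        return UltrametricTree(tree, tolerance=tolerance)
    if method == "mean_path":
        age = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                age[node] = 0.0
            else:
                vals = [age[ch] + (ch.edge.length or 0.0)
                        for ch in node.child_nodes()]
                age[node] = max(float(np.mean(vals)),
                                max(age[ch] for ch in node.child_nodes()) + 1e-12)
        for node in tree.preorder_node_iter():
            for ch in node.child_nodes():
                ch.edge.length = age[node] - age[ch]
        return UltrametricTree(tree, tolerance=tolerance)
    raise ValueError("method must be require, equal_terminals or mean_path")


@dataclass
class ScanConfig:
    outgroup: str
    alpha: float = 0.01
    mode: str = "dfoil"
    pair_report_prop: float = 0.05   # "introgression > 5%" reporting rule
    detail_count: int = 50           # events before a pair is examined in detail
    include_equal_depth_pairs: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.pair_report_prop <= 1:
            raise ValueError("pair_report_prop must be in [0, 1]")


def enumerate_quartets(utree: UltrametricTree, outgroup: str,
                       include_equal_depth_pairs: bool = True
                       ) -> list[tuple[str, str, str, str]]:
    """All tree-compatible (P1, P2, P3, P4) tests.

    Emits each unordered pair-of-pairs once; within-pair order is
    lexicographic, with the shallower pair as (P1, P2).  Equal-depth pairs
    are included by default, with the lexicographically smaller pair
    first; set ``include_equal_depth_pairs=False`` to require a strictly
    shallower (P1, P2)."""
    if outgroup not in utree.tips:
        raise KeyError(f"outgroup {outgroup!r} is not a tip")
    ingroup = [t for t in utree.tips if t != outgroup]
    if len(ingroup) < 4:
        raise ValueError("need at least four ingroup tips")
    idx = {t: utree.tips.index(t) for t in ingroup}
    D = utree._mrca_depth
    out = []
    pairs = list(itertools.combinations(ingroup, 2))
    for (a, b), (c, d) in itertools.combinations(pairs, 2):
        if len({a, b, c, d}) != 4:
            continue
        dab = D[idx[a], idx[b]]
        dcd = D[idx[c], idx[d]]
        cross = [D[idx[x], idx[y]] for x in (a, b) for y in (c, d)]
        dall = max(dab, dcd, max(cross))
        # disjoint lineages: every cross MRCA is the joint ancestor,
        # strictly older than both pair ancestors
        if not all(abs(x - dall) <= utree.tolerance for x in cross):
            continue
        if not (dab < dall - utree.tolerance and dcd < dall - utree.tolerance):
            continue
        if abs(dab - dcd) <= utree.tolerance:
            if not include_equal_depth_pairs:
                continue
            first, second = sorted([(a, b), (c, d)])
        elif dab < dcd:
            first, second = (a, b), (c, d)
        else:
            first, second = (c, d), (a, b)
        out.append((*first, *second))
    return sorted(out)


@dataclass
class ScanRecord:
    p1: str
    p2: str
    p3: str
    p4: str
    result: DfoilResult

    @property
    def quartet(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass
class ScanTable:
    records: list[ScanRecord]
    outgroup: str
    config: ScanConfig

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"P1": rec.p1, "P2": rec.p2, "P3": rec.p3, "P4": rec.p4,
                   "n_sites": rec.result.counts.n_sites_used,
                   "mode": rec.result.mode}
            for name in STAT_NAMES:
                s = rec.result.stats[name]
                row.update({f"{name}_L": s.L, f"{name}_R": s.R,
                            f"{name}": s.value, f"{name}_chi2": s.chi2,
                            f"{name}_p": s.p, f"{name}_sign": s.sign})
            row["call"] = rec.result.call.category
            row["donor"] = rec.result.call.donor or ""
            row["recipient"] = rec.result.call.recipient or ""
            rows.append(row)
        return pd.DataFrame(rows)


def run_scan(seqdata: SequenceDataset, utree: UltrametricTree,
             config: ScanConfig) -> ScanTable:
    """One five-taxon test per enumerated quartet, sequences drawn from
    the supermatrix rows of the scan units."""
    missing = [t for t in utree.tips if t not in seqdata.sequences]
    if missing:
        raise KeyError(f"tree tips missing from dataset: {missing[:5]}")
    if config.outgroup not in seqdata.sequences:
        raise KeyError(f"outgroup {config.outgroup!r} missing from dataset")
    encoded = {u: _seq.encode(seqdata.sequences[u]) for u in utree.tips}
    out_row = encoded[config.outgroup]
    quartets = enumerate_quartets(utree, config.outgroup,
                                  config.include_equal_depth_pairs)
    records = []
    for p1, p2, p3, p4 in quartets:
        arr = np.stack([encoded[p1], encoded[p2], encoded[p3], encoded[p4],
                        out_row])
        counts = count_site_patterns(arr)
        result = dfoil_test(counts, alpha=config.alpha, mode=config.mode)
        result.quintet = (p1, p2, p3, p4, config.outgroup)
        records.append(ScanRecord(p1, p2, p3, p4, result))
    return ScanTable(records=records, outgroup=config.outgroup, config=config)


@dataclass
class PairSummary:
    pair: tuple[str, str]
    n_tests: int
    n_events: int
    directed: dict[tuple[str, str], int]  # (donor taxon, recipient taxon) -> count

    @property
    def proportion(self) -> float:
        return self.n_events / self.n_tests if self.n_tests else 0.0


def _anc_label(tax_a: str, tax_b: str) -> str:
    a, b = sorted([tax_a, tax_b])
    return a if a == b else f"anc({a},{b})"


def _record_pairs(rec: ScanRecord, taxon_of: dict[str, str]
                  ) -> list[tuple[str, str]]:
    """Taxon pairs that a test could call: each near-side x far-side taxon
    pair, plus the two ancestral pseudo-taxon pairs."""
    t1, t2 = taxon_of[rec.p1], taxon_of[rec.p2]
    t3, t4 = taxon_of[rec.p3], taxon_of[rec.p4]
    anc = _anc_label(t1, t2)
    cands = {tuple(sorted(p)) for p in
             [(t1, t3), (t1, t4), (t2, t3), (t2, t4), (anc, t3), (anc, t4)]
             if p[0] != p[1]}
    return sorted(cands)


def _call_pair(rec: ScanRecord, taxon_of: dict[str, str]
               ) -> tuple[tuple[str, str] | None, tuple[str, str] | None]:
    """(unordered taxon pair, optional donor->recipient) of a record's call."""
    call = rec.result.call
    if call.category in ("none", "ambiguous"):
        return None, None
    pos = {"P1": rec.p1, "P2": rec.p2, "P3": rec.p3, "P4": rec.p4}
    if call.category.startswith("anc"):
        far = "P3" if call.category.endswith("P3") else "P4"
        anc = _anc_label(taxon_of[rec.p1], taxon_of[rec.p2])
        other = taxon_of[pos[far]]
        if anc == other:
            return None, None
        return tuple(sorted((anc, other))), None
    near, far = call.category.split("-")
    ta, tb = taxon_of[pos[near]], taxon_of[pos[far]]
    if ta == tb:
        return None, None
    donor = taxon_of[pos[call.donor]] if call.donor else None
    recipient = taxon_of[pos[call.recipient]] if call.recipient else None
    directed = (donor, recipient) if donor and recipient else None
    return tuple(sorted((ta, tb))), directed


def aggregate(table: ScanTable, grouping: pd.DataFrame | dict,
              config: ScanConfig | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-level and unit-level summaries of a scan.

    ``grouping`` maps scan units to taxa (a dict or a frame with columns
    individual/population -> taxon is accepted; units not listed map to
    themselves).  Returns (pair summary frame, per-unit frame); the pair
    frame carries the reporting flags at the configured thresholds."""
    config = config or table.config
    if isinstance(grouping, pd.DataFrame):
        cols = [c for c in ("individual", "population", "unit") if
                c in grouping.columns]
        key = cols[0] if cols else grouping.columns[0]
        taxon_of = dict(zip(grouping[key], grouping["taxon"]))
    else:
        taxon_of = dict(grouping)
    units = {u for rec in table.records for u in rec.quartet}
    for u in units:
        taxon_of.setdefault(u, u)

    pair_tests: dict[tuple[str, str], int] = {}
    pair_events: dict[tuple[str, str], int] = {}
    pair_directed: dict[tuple[str, str], dict] = {}
    unit_tests: dict[str, int] = {}
    unit_events: dict[str, int] = {}
    for rec in table.records:
        for pair in _record_pairs(rec, taxon_of):
            pair_tests[pair] = pair_tests.get(pair, 0) + 1
        called, directed = _call_pair(rec, taxon_of)
        if called is not None:
            pair_events[called] = pair_events.get(called, 0) + 1
            if directed is not None:
                d = pair_directed.setdefault(called, {})
                d[directed] = d.get(directed, 0) + 1
        significant = rec.result.call.category != "none"
        for u in rec.quartet:
            unit_tests[u] = unit_tests.get(u, 0) + 1
            if significant:
                unit_events[u] = unit_events.get(u, 0) + 1

    rows = []
    for pair in sorted(pair_tests):
        n_tests = pair_tests[pair]
        n_events = pair_events.get(pair, 0)
        prop = n_events / n_tests if n_tests else 0.0
        directed = pair_directed.get(pair, {})
        dir_str = ";".join(f"{d}->{r}:{c}" for (d, r), c in sorted(directed.items()))
        rows.append({
            "taxon_a": pair[0], "taxon_b": pair[1],
            "n_tests": n_tests, "n_events": n_events, "proportion": prop,
            "directed": dir_str,
            "flag_proportion": prop >= config.pair_report_prop,
            "flag_detail": n_events >= config.detail_count,
        })
    pair_frame = pd.DataFrame(rows)

    unit_rows = [{"unit": u, "taxon": taxon_of[u],
                  "n_tests": unit_tests.get(u, 0),
                  "n_significant": unit_events.get(u, 0),
                  "proportion": (unit_events.get(u, 0) / unit_tests[u]
                                 if unit_tests.get(u) else 0.0)}
                 for u in sorted(units)]
    unit_frame = pd.DataFrame(unit_rows)
    return pair_frame, unit_frame
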