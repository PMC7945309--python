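"""Minimal rooted-tree machinery for sequence simulation.

A :class:`LineageTree` is an ultrametric-ish rooted tree with named tips.
It supports the one structural edit the simulator needs: re-attaching (or
duplicating) a tip lineage onto another tip's terminal branch at a given
time before present, which is how gene flow is modelled at the locus level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class Node:
    label: str | None
    length: float  # branch length to parent (root: 0)
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class LineageTree:
    """Rooted tree with branch lengths and node ages (time before present)."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "LineageTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        if len(dt.leaf_nodes()) < 2:
            raise ValueError("tree must have at least 2 tips")

        def convert(dn) -> Node:
            label = dn.taxon.label.replace(" ", "_") if dn.taxon else None
            length = dn.edge.length if dn.edge.length is not None else 0.0
            if length < 0:
                raise ValueError("negative branch length")
            node = Node(label=label, length=float(length))
            node.children = [convert(c) for c in dn.child_nodes()]
            return node

        root = convert(dt.seed_node)
        root.length = 0.0
        return cls(root)

    def _index(self) -> None:
        self.nodes: list[Node] = []
        self.parent: dict[int, Node | None] = {}
        depth: dict[int, float] = {}

        def walk(node: Node, parent: Node | None, d: float) -> None:
            self.nodes.append(node)
            self.parent[id(node)] = parent
            depth[id(node)] = d
            for ch in node.children:
                walk(ch, node, d + ch.length)

        walk(self.root, None, 0.0)
        self._rootdist = depth
        height = max(depth[id(n)] for n in self.nodes if n.is_tip)
        self.age = {id(n): height - depth[id(n)] for n in self.nodes}
        self.height = height
        tips = [n for n in self.nodes if n.is_tip]
        labels = [t.label for t in tips]
        if None in labels or len(set(labels)) != len(labels):
            raise ValueError("tips must carry unique labels")
        self.tips = {t.label: t for t in tips}

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.tips)

    def tip_parent_age(self, label: str) -> float:
        tip = self.tips[label]
        return self.age[id(self.parent[id(tip)])]

    # -- editing ------------------------------------------------------
    def copy(self) -> "LineageTree":
        def dup(node: Node) -> Node:
            out = Node(label=node.label, length=node.length)
            out.children = [dup(c) for c in node.children]
            return out

        return LineageTree(dup(self.root))

    def grafted(self, donor: str, recipient: str, t_admix: float,
                *, keep_recipient: bool = False,
                graft_label: str | None = None) -> "LineageTree":
        """Attach the recipient lineage onto the donor's terminal branch.

        With ``keep_recipient=False`` the recipient tip is moved (taxon-level
        gene flow: the whole lineage's copy of the locus descends from the
        donor).  With ``keep_recipient=True`` a new tip ``graft_label`` is
        added instead and the original recipient tip stays in place
        (population-level gene flow).
        """
        if donor == recipient:
            raise ValueError("donor and recipient must differ")
        for lab in (donor, recipient):
            if lab not in self.tips:
                raise KeyError(f"tip {lab!r} not in tree")
        if t_admix < 0:
            raise ValueError("t_admix must be >= 0")
        if t_admix >= self.tip_parent_age(donor):
            raise ValueError(
                f"t_admix={t_admix} is older than the donor's divergence "
                f"({self.tip_parent_age(donor)})")
        if t_admix >= self.tip_parent_age(recipient):
            raise ValueError(
                f"t_admix={t_admix} is older than the recipient's divergence "
                f"({self.tip_parent_age(recipient)})")

        tree = self.copy()
        if not keep_recipient:
            # detach recipient tip, suppressing the unifurcation left behind
            tip = tree.tips[recipient]
            par = tree.parent[id(tip)]
            par.children.remove(tip)
            if len(par.children) == 1 and tree.parent[id(par)] is not None:
                only = par.children[0]
                grandpa = tree.parent[id(par)]
                only.length += par.length
                grandpa.children[grandpa.children.index(par)] = only
            new_label = recipient
        else:
            new_label = graft_label or f"{recipient}*"
            if new_label in tree.tips:
                raise ValueError(f"graft label {new_label!r} already used")
        tree._index()

        dtip = tree.tips[donor]
        dpar = tree.parent[id(dtip)]
        dpar_age = tree.age[id(dpar)]
        junction = Node(label=None, length=dpar_age - t_admix)
        new_tip = Node(label=new_label, length=t_admix)
        dtip.length = t_admix
        dpar.children[dpar.children.index(dtip)] = junction
        junction.children = [dtip, new_tip]
        tree._index()
        return tree
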