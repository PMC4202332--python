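"""Rooted species trees with a tagged whole-genome-duplication (WGD) node.

The pipeline maps intron gain/loss characters onto a rooted species tree in
which one internal node is tagged as the WGD: the clade it subtends holds the
post-WGD species, whose genes exist as duplicated A/B loci.  Trees are stored
in a deliberately small node structure (children/parent links plus a handful
of bookkeeping attributes) because the downstream algorithms — clade
duplication, per-site pruning, Dollo parsimony — rewrite tree structure
freely.  Newick text is parsed with dendropy and converted.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

WGD_LABEL = "WGD"


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


class Node:
    """A node in a rooted tree (multifurcations permitted)."""

    __slots__ = ("name", "children", "parent", "locus", "base")

    def __init__(self, name: str = "", children: Optional[list["Node"]] = None):
        self.name = name
        self.children: list[Node] = children if children is not None else []
        self.parent: Optional[Node] = None
        for c in self.children:
            c.parent = self
        # Set on expanded/pruned trees: which simplified-tree branch this
        # node's incoming branch projects to, and the WGD locus it carries.
        self.locus: str = "0"
        self.base: str = name

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        dup = Node(self.name)
        dup.locus = self.locus
        dup.base = self.base
        for c in self.children:
            dup.add(c.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, {len(self.children)} children)"


class SpeciesTree:
    """A rooted species tree, optionally with one node tagged as the WGD.

    Invariants enforced at construction: unique non-empty tip names; the WGD
    node, if set, is internal.  Internal nodes without a Newick label receive
    deterministic preorder names (``n1``, ``n2``, ...) so that every branch can
    be addressed by the name of its child node.
    """

    def __init__(self, root: Node, wgd_node: Optional[Node] = None):
        self.root = root
        self._autoname()
        tips = [n.name for n in root.postorder() if n.is_leaf]
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip names: {dups}")
        if wgd_node is None:
            for n in root.preorder():
                if n.name == WGD_LABEL and not n.is_leaf:
                    wgd_node = n
                    break
        if wgd_node is not None and wgd_node.is_leaf:
            raise TreeError("WGD node must be internal")
        self.wgd_node = wgd_node

    def _autoname(self) -> None:
        counter = 0
        seen = set()
        for n in self.root.preorder():
            if n.name:
                seen.add(n.name)
        for n in self.root.preorder():
            if not n.name:
                counter += 1
                while f"n{counter}" in seen:
                    counter += 1
                n.name = f"n{counter}"
                n.base = n.name
                seen.add(n.name)

    # -- queries ---------------------------------------------------------

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def find(self, name: str) -> Node:
        for n in self.root.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def branches(self) -> list[Node]:
        """Every non-root node, i.e. every branch keyed by its child node."""
        return [n for n in self.root.preorder() if n.parent is not None]

    def wgd_clade_tips(self) -> list[str]:
        if self.wgd_node is None:
            return []
        return [t.name for t in self.wgd_node.leaves()]

    def mrca(self, names: list[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(names)
        if not want:
            raise TreeError("mrca of empty tip set")
        below: dict[Node, set[str]] = {}
        for n in self.root.postorder():
            if n.is_leaf:
                below[n] = {n.name} & want
            else:
                below[n] = set().union(*(below[c] for c in n.children))
        missing = want - below[self.root]
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        node = self.root
        while True:
            nxt = [c for c in node.children if below[c] == want]
            if not nxt:
                return node
            node = nxt[0]

    def copy(self) -> "SpeciesTree":
        root = self.root.copy()
        tree = SpeciesTree(root)
        if self.wgd_node is not None:
            tree.wgd_node = tree.find(self.wgd_node.name)
        return tree

    # -- serialization ---------------------------------------------------

    def to_newick(self, internal_labels: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return n.name
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if internal_labels and (n is self.wgd_node or not n.name.startswith("n")):
                label = n.name
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    def convert(dnode) -> Node:
        name = ""
        if dnode.taxon is not None and dnode.taxon.label:
            name = dnode.taxon.label.replace(" ", "_")
        elif dnode.label:
            name = dnode.label
        node = Node(name)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return SpeciesTree(convert(dtree.seed_node))


def parse_newick(text: str, wgd_label: str = WGD_LABEL) -> SpeciesTree:
    """Parse a Newick string; an internal node labeled *wgd_label* is tagged."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree = from_dendropy(dtree)
    if wgd_label != WGD_LABEL:
        try:
            node = tree.find(wgd_label)
        except KeyError:
            node = None
        if node is not None and not node.is_leaf:
            tree.wgd_node = node
    return tree
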