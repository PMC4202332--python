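"""Dollo parsimony mapping of intron gains and losses on a WGD-expanded tree.

Each ancestral intron site is a binary character (intron present/absent per
(species, locus)).  Under Dollo parsimony a character is gained at most once
and never regained after loss.  Because the post-WGD species carry two gene
loci descending from the whole-genome duplication, the character evolves on
an *expanded* tree in which the clade subtended by the WGD node is duplicated
into isomorphic A and B copies; events are afterwards re-projected onto the
simplified species tree, where each post-WGD branch accumulates the events of
its A and B counterparts.

For a fixed gain node the minimal loss set is unique: one loss on the root
branch of every maximal all-absent clade inside the gain clade.  The gain
node is placed at the MRCA of the present tips; a gain is reported as an
event only when that node is not the root of the (pruned) tree, otherwise
the site is treated as ancestrally present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .matrix import IntronState, StateMatrix  # noqa: F401 (IntronState in type hints)
from .trees import Node, SpeciesTree, TreeError

ORACLE_MAX_TIPS = 14


def tip_name(species: str, locus: str) -> str:
    """Expanded-tree tip name for a (species, locus) pair."""
    return species if locus == "0" else f"{species}|{locus}"


@dataclass
class ExpandedTree:
    """WGD-expanded tree plus the branch map back onto the simplified tree.

    Every expanded node carries ``base`` (the simplified-tree node whose
    branch it projects to) and ``locus`` ("0" outside the duplicated clade,
    "A"/"B" inside).  The WGD node itself and the two locus-clade roots all
    project onto the simplified branch subtending the post-WGD clade.
    """

    tree: SpeciesTree
    simplified: SpeciesTree

    @property
    def branch_map(self) -> dict[str, tuple[str, str]]:
        return {n.name: (n.base, n.locus) for n in self.tree.preorder()}

    def tip_for(self, species: str, locus: str) -> str:
        return tip_name(species, locus)

    def collapse(self) -> SpeciesTree:
        """Inverse of the expansion: rebuild the simplified topology from the
        locus-A copy (the two copies are isomorphic by construction)."""

        def rebuild(n: Node) -> Node:
            if n is wgd_exp:
                a_copy = n.children[0]
                return strip(a_copy)
            m = Node(n.name)
            for c in n.children:
                m.add(rebuild(c))
            return m

        def strip(n: Node) -> Node:
            m = Node(n.base)
            for c in n.children:
                m.add(strip(c))
            return m

        wgd_exp = self.tree.find(self.simplified.wgd_node.name)
        root = rebuild(self.tree.root)
        out = SpeciesTree(root)
        out.wgd_node = out.find(self.simplified.wgd_node.name)
        return out


def identity_expansion(tree: SpeciesTree) -> ExpandedTree:
    """An ExpandedTree for a tree without WGD: every branch maps to itself
    with locus "0".  Lets the same machinery run on pre-WGD-only data."""
    expanded = tree.copy()
    for n in expanded.preorder():
        n.base, n.locus = n.name, "0"
    return ExpandedTree(tree=expanded, simplified=tree)


def expand_wgd_tree(tree: SpeciesTree) -> ExpandedTree:
    """Duplicate the post-WGD clade into A and B locus copies.

    The expanded tree has ``n_pre + 2 * n_post`` tips.  Locus copies are
    labeled deterministically: A is the first child of the WGD node.
    """
    if tree.wgd_node is None:
        raise TreeError("tree has no tagged WGD node")

    def dup(n: Node, locus: str) -> Node:
        m = Node(f"{n.name}|{locus}")
        m.base, m.locus = n.name, locus
        for c in n.children:
            m.add(dup(c, locus))
        return m

    def build(n: Node) -> Node:
        m = Node(n.name)
        m.base, m.locus = n.name, "0"
        if n is tree.wgd_node:
            for locus in ("A", "B"):
                m.add(dup(n, locus))
            return m
        for c in n.children:
            m.add(build(c))
        return m

    expanded = SpeciesTree(build(tree.root))
    expanded.wgd_node = expanded.find(tree.wgd_node.name)
    return ExpandedTree(tree=expanded, simplified=tree)


# ---------------------------------------------------------------------------
# Per-site pruning


@dataclass
class PrunedSite:
    """A site's pruned expanded tree plus its binary tip presence states."""

    site_id: str
    root: Node
    present: dict[str, bool]  # expanded tip name -> intron present

    @property
    def n_tips(self) -> int:
        return len(self.present)

    def present_tips(self) -> list[str]:
        return sorted(t for t, p in self.present.items() if p)


class NoPresenceError(ValueError):
    """A site has no PRESENT tip after pruning; Dollo cannot anchor it."""


def prune_for_site(
    etree: ExpandedTree,
    states: dict[tuple[str, str], IntronState],
    site_id: str = "site",
) -> PrunedSite:
    """Prune the expanded tree to the loci with data for one site.

    Tips whose state is NO_DATA (or absent from *states*) are removed and
    resulting unifurcations suppressed; the surviving child node keeps its
    branch-map attribution, so an event on a merged branch projects to the
    simplified branch of the retained child.
    """
    keep: dict[str, bool] = {}
    for (species, locus), st in states.items():
        if st.is_defined:
            keep[tip_name(species, locus)] = st.is_present

    def rebuild(n: Node) -> Node | None:
        if n.is_leaf:
            if n.name not in keep:
                return None
            m = Node(n.name)
            m.base, m.locus = n.base, n.locus
            return m
        kids = [k for k in (rebuild(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # suppress unifurcation; child keeps attribution
        m = Node(n.name)
        m.base, m.locus = n.base, n.locus
        for k in kids:
            m.add(k)
        return m

    root = rebuild(etree.tree.root)
    if root is None or not any(keep.values()):
        raise NoPresenceError(f"site {site_id}: no PRESENT tip to anchor Dollo")
    tip_set = {t.name for t in root.leaves()}
    return PrunedSite(site_id=site_id, root=root,
                      present={t: keep[t] for t in sorted(tip_set)})


# ---------------------------------------------------------------------------
# Dollo assignment


@dataclass(frozen=True)
class EventAssignment:
    """Gains and losses for one site on its pruned expanded tree.

    ``gain_node`` names the node below which the intron exists.  When
    ``gain_is_event`` is False the site is ancestrally present (gain node is
    the pruned root).  ``losses`` names the child nodes of the loss branches
    (the unique minimal set for the fixed gain node).
    """

    site_id: str
    gain_node: str
    gain_is_event: bool
    losses: tuple[str, ...]

    @property
    def event_count(self) -> int:
        return len(self.losses) + (1 if self.gain_is_event else 0)


def _mrca(root: Node, names: set[str]) -> Node:
    below: dict[Node, int] = {}
    target = len(names)
    for n in root.postorder():
        if n.is_leaf:
            below[n] = 1 if n.name in names else 0
        else:
            below[n] = sum(below[c] for c in n.children)
    node = root
    while True:
        nxt = [c for c in node.children if below[c] == target]
        if not nxt:
            return node
        node = nxt[0]


def dollo_assign(
    pruned: PrunedSite, assume_root_presence: bool = False
) -> EventAssignment:
    """Place the single gain and the unique minimal loss set for one site."""
    present = set(pruned.present_tips())
    if not present:
        raise NoPresenceError(f"site {pruned.site_id}: no PRESENT tips")
    root = pruned.root
    gain = root if assume_root_presence else _mrca(root, present)

    all_absent: dict[Node, bool] = {}
    for n in root.postorder():
        if n.is_leaf:
            all_absent[n] = not pruned.present[n.name]
        else:
            all_absent[n] = all(all_absent[c] for c in n.children)

    losses: list[str] = []

    def collect(n: Node) -> None:
        for c in n.children:
            if all_absent[c]:
                losses.append(c.name)
            else:
                collect(c)

    collect(gain)
    return EventAssignment(
        site_id=pruned.site_id,
        gain_node=gain.name,
        gain_is_event=(gain.parent is not None),
        losses=tuple(sorted(losses)),
    )


def apply_overrides(
    assignments: dict[str, EventAssignment],
    pruned_sites: dict[str, PrunedSite],
    overrides: list[str],
) -> dict[str, EventAssignment]:
    """Reject curated gains: re-assign the named sites with an ancestrally
    present character, turning each rejected gain into losses on alternative
    branches.  Overriding a site already ancestrally present is a no-op with
    a warning."""
    out = dict(assignments)
    for site_id in overrides:
        if site_id not in out:
            warnings.warn(f"override for unknown site {site_id!r} ignored")
            continue
        if not out[site_id].gain_is_event:
            warnings.warn(f"site {site_id} already ancestrally present; "
                          f"override is a no-op")
            continue
        out[site_id] = dollo_assign(pruned_sites[site_id], assume_root_presence=True)
    return out


# ---------------------------------------------------------------------------
# Event projection onto the simplified tree


@dataclass
class EventMap:
    """Per-branch event totals on the simplified tree (A+B loci summed).

    Branches are keyed by the name of their child node.  ``per_site`` keeps
    the expanded-tree event list (branch, event, locus) for traceability.
    """

    branch_gains: dict[str, int]
    branch_losses: dict[str, int]
    per_site: dict[str, list[tuple[str, str, str]]]
    sites_lost_multiple: int

    @property
    def total_losses(self) -> int:
        return sum(self.branch_losses.values())

    @property
    def total_gains(self) -> int:
        return sum(self.branch_gains.values())

    def species_totals(self, species: list[str]) -> pd.DataFrame:
        rows = [
            {"species": sp,
             "terminal_gains": self.branch_gains.get(sp, 0),
             "terminal_losses": self.branch_losses.get(sp, 0)}
            for sp in species
        ]
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site_id in sorted(self.per_site):
            for branch, event, locus in sorted(self.per_site[site_id]):
                rows.append({"site_id": site_id, "branch": branch,
                             "event": event, "locus": locus})
        return pd.DataFrame(rows, columns=["site_id", "branch", "event", "locus"])

    def summary_frame(self) -> pd.DataFrame:
        branches = sorted(set(self.branch_gains) | set(self.branch_losses))
        return pd.DataFrame(
            [{"branch": b,
              "gains": self.branch_gains.get(b, 0),
              "losses": self.branch_losses.get(b, 0)} for b in branches]
        )


def summarize_events(
    assignments: dict[str, EventAssignment],
    etree: ExpandedTree,
    pruned_sites: dict[str, PrunedSite] | None = None,
) -> EventMap:
    """Project per-site events through the branch map and sum per simplified
    branch.  Events on locus-A and locus-B branches of the same species or
    ancestral branch are summed together."""
    # branch attribution must come from the pruned trees when available,
    # because pruning can merge branches; fall back to the full branch map.
    full_map = etree.branch_map

    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    per_site: dict[str, list[tuple[str, str, str]]] = {}
    lost_multiple = 0
    for site_id in sorted(assignments):
        a = assignments[site_id]
        events: list[tuple[str, str, str]] = []
        node_map = full_map
        if pruned_sites is not None and site_id in pruned_sites:
            node_map = {n.name: (n.base, n.locus)
                        for n in pruned_sites[site_id].root.preorder()}
        if a.gain_is_event:
            base, locus = node_map[a.gain_node]
            gains[base] = gains.get(base, 0) + 1
            events.append((a.gain_node, "gain", locus))
        for branch in a.losses:
            base, locus = node_map[branch]
            losses[base] = losses.get(base, 0) + 1
            events.append((branch, "loss", locus))
        if len(a.losses) > 1:
            lost_multiple += 1
        per_site[site_id] = events
    return EventMap(branch_gains=gains, branch_losses=losses,
                    per_site=per_site, sites_lost_multiple=lost_multiple)


# ---------------------------------------------------------------------------
# High-level driver and the exhaustive oracle


def map_events(
    matrix: StateMatrix,
    etree: ExpandedTree,
    overrides: list[str] | None = None,
) -> tuple[dict[str, EventAssignment], EventMap, list[str]]:
    """Prune, assign and summarize every site of a state matrix.

    Returns (assignments, event map, skipped site ids).  Sites with zero
    PRESENT tips after pruning are skipped with a warning.
    """
    assignments: dict[str, EventAssignment] = {}
    pruned_sites: dict[str, PrunedSite] = {}
    skipped: list[str] = []
    for site in matrix.sites:
        states = matrix.site_states(site.site_id)
        try:
            pruned = prune_for_site(etree, states, site_id=site.site_id)
        except NoPresenceError:
            warnings.warn(f"site {site.site_id}: no PRESENT tip; skipped")
            skipped.append(site.site_id)
            continue
        pruned_sites[site.site_id] = pruned
        assignments[site.site_id] = dollo_assign(pruned)
    if overrides:
        assignments = apply_overrides(assignments, pruned_sites, overrides)
    eventmap = summarize_events(assignments, etree, pruned_sites)
    return assignments, eventmap, skipped


def dollo_oracle(pruned: PrunedSite) -> int:
    """Exhaustive minimal Dollo event count, for verification only.

    Enumerates every node as a candidate gain placement (valid when its clade
    contains all PRESENT tips), derives the forced loss set for each via
    leaf-set arithmetic, and returns the global minimum event count.  Refuses
    trees above {ORACLE_MAX_TIPS} tips.
    """
    if pruned.n_tips > ORACLE_MAX_TIPS:
        raise ValueError(f"oracle limited to {ORACLE_MAX_TIPS} tips, "
                         f"got {pruned.n_tips}")
    present = set(pruned.present_tips())
    if not present:
        raise NoPresenceError("oracle needs at least one PRESENT tip")
    nodes = list(pruned.root.preorder())
    leafset = {n: frozenset(t.name for t in n.leaves()) for n in nodes}
    parent = {n: n.parent for n in nodes}

    best = None
    for gain in nodes:
        if not present <= leafset[gain]:
            continue
        clade = [n for n in nodes if leafset[n] <= leafset[gain]]
        n_losses = 0
        for n in clade:
            if n is gain or not leafset[n].isdisjoint(present):
                continue
            p = parent[n]
            if p is not None and not leafset[p].isdisjoint(present):
                n_losses += 1  # maximal all-absent clade root
        cost = n_losses + (0 if parent[gain] is None else 1)
        if best is None or cost < best:
            best = cost
    return best


dollo_oracle.__doc__ = dollo_oracle.__doc__.format(ORACLE_MAX_TIPS=ORACLE_MAX_TIPS)
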