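"""WGD tree expansion, per-site pruning, Dollo assignment vs the exhaustive
oracle, gain overrides and event projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronevo import dollo
from intronevo.matrix import IntronState
from intronevo.trees import Node, SpeciesTree, TreeError, parse_newick

P = IntronState("PRESENT")
L = IntronState("LOST_PERFECT", k=0)
N = IntronState("NO_DATA")


def random_tree(rng: np.random.Generator, n: int) -> SpeciesTree:
    nodes = [Node(f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        k = min(len(nodes), 3 if rng.random() < 0.2 else 2)
        picks = [nodes.pop(int(rng.integers(0, len(nodes)))) for _ in range(k)]
        nodes.append(Node("", picks))
    return SpeciesTree(nodes[0])


def pruned(tree: SpeciesTree, present: dict[str, bool]) -> dollo.PrunedSite:
    return dollo.PrunedSite("s", tree.root, present)


class TestExpandWGD:
    def test_fixture_expansion_has_32_tips(self, default_tree):
        et = dollo.expand_wgd_tree(default_tree)
        assert len(et.tree.tip_names()) == 8 + 2 * 12

    def test_cherry_wgd_gives_four_locus_tips(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        assert sorted(et.tree.tip_names()) == ["A|A", "A|B", "B|A", "B|B", "C"]

    def test_expand_then_collapse_is_identity(self, default_tree):
        et = dollo.expand_wgd_tree(default_tree)
        assert et.collapse().to_newick() == default_tree.to_newick()

    def test_untagged_tree_rejected(self):
        with pytest.raises(TreeError, match="WGD"):
            dollo.expand_wgd_tree(parse_newick("(A,(B,C));"))

    def test_branch_map_is_total(self, default_tree):
        et = dollo.expand_wgd_tree(default_tree)
        bmap = et.branch_map
        assert set(bmap) == {n.name for n in et.tree.preorder()}
        post = set(default_tree.wgd_clade_tips())
        for sp in post:
            assert bmap[f"{sp}|A"] == (sp, "A")
            assert bmap[f"{sp}|B"] == (sp, "B")


class TestPruneForSite:
    def test_all_data_is_identity(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        states = {("A", "A"): P, ("A", "B"): P, ("B", "A"): P,
                  ("B", "B"): L, ("C", "0"): P}
        ps = dollo.prune_for_site(et, states)
        assert sorted(t.name for t in ps.root.leaves()) == \
            sorted(et.tree.tip_names())

    def test_no_data_cherry_collapses(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        states = {("A", "A"): P, ("B", "A"): P, ("C", "0"): P}  # B loci gone
        ps = dollo.prune_for_site(et, states)
        names = sorted(t.name for t in ps.root.leaves())
        assert names == ["A|A", "B|A", "C"]

    def test_zero_present_tips_raises(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        states = {("A", "A"): L, ("C", "0"): N}
        with pytest.raises(dollo.NoPresenceError):
            dollo.prune_for_site(et, states)

    def test_pruned_tips_match_retained_loci(self, truth):
        et = truth.etree
        site = truth.sites[0]
        states = {col: IntronState(
            {"present": "PRESENT", "gene_absent": "NO_DATA"}.get(
                ts.state, "LOST_UNKNOWN"))
            for col, ts in site.states.items()}
        ps = dollo.prune_for_site(et, states)
        retained = {dollo.tip_name(*col) for col, ts in site.states.items()
                    if ts.state != "gene_absent"}
        assert {t.name for t in ps.root.leaves()} == retained


class TestDolloAssign:
    def test_all_present_means_root_presence(self):
        tree = parse_newick("((A,B),(C,D));")
        a = dollo.dollo_assign(pruned(tree, {t: True for t in "ABCD"}))
        assert a.event_count == 0 and not a.gain_is_event

    def test_single_present_tip_is_terminal_gain(self, default_tree):
        present = {t: t == "Scer" for t in default_tree.tip_names()}
        a = dollo.dollo_assign(pruned(default_tree.copy(), present))
        assert a.gain_is_event and a.gain_node == "Scer" and a.losses == ()

    def test_five_tip_pattern_two_losses(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        present = dict(A=True, B=True, C=False, D=True, E=False)
        a = dollo.dollo_assign(pruned(tree, present))
        assert not a.gain_is_event
        assert set(a.losses) == {"C", "E"}
        assert a.event_count == dollo.dollo_oracle(pruned(tree, present)) == 2

    def test_multifurcation_one_loss_per_absent_child(self):
        tree = parse_newick("(A,B,C,D);")
        present = dict(A=True, B=False, C=False, D=True)
        a = dollo.dollo_assign(pruned(tree, present))
        assert set(a.losses) == {"B", "C"}

    def test_loss_set_is_minimal_certificate(self):
        """Each loss clade is maximal: all its tips absent, its parent clade
        holds a present tip, so no loss branch can be dropped."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            tree = random_tree(rng, int(rng.integers(3, 13)))
            tips = tree.tip_names()
            present = {t: bool(rng.random() < 0.5) for t in tips}
            if not any(present.values()):
                present[tips[0]] = True
            ps = pruned(tree, present)
            a = dollo.dollo_assign(ps)
            nodes = {n.name: n for n in tree.preorder()}
            for loss in a.losses:
                clade = [t.name for t in nodes[loss].leaves()]
                assert not any(present[t] for t in clade)
                parent_clade = [t.name for t in nodes[loss].parent.leaves()]
                assert any(present[t] for t in parent_clade)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_assignment_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(2, 15)))
        tips = tree.tip_names()
        present = {t: bool(rng.random() < 0.5) for t in tips}
        if not any(present.values()):
            present[tips[0]] = True
        ps = pruned(tree, present)
        assert dollo.dollo_assign(ps).event_count == dollo.dollo_oracle(ps)

    def test_oracle_refuses_large_trees(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 20)
        ps = pruned(tree, {t: True for t in tree.tip_names()})
        with pytest.raises(ValueError, match="14 tips"):
            dollo.dollo_oracle(ps)

    def test_oracle_all_present_is_zero(self):
        tree = parse_newick("((A,B),(C,D));")
        assert dollo.dollo_oracle(pruned(tree, {t: True for t in "ABCD"})) == 0

    def test_oracle_alternating_caterpillar(self):
        # (((((A,B),C),D),E),F) with A,C,E present: gain at root of
        # {A..E}-containing clade; forced losses on B, D, F -> 3 events
        tree = parse_newick("(((((A,B),C),D),E),F);")
        present = dict(A=True, B=False, C=True, D=False, E=True, F=False)
        assert dollo.dollo_oracle(pruned(tree, present)) == 3


class TestOverrides:
    def test_override_turns_gain_into_losses(self):
        tree = parse_newick("((A,B),(C,D));")
        present = dict(A=True, B=False, C=False, D=False)
        ps = pruned(tree, present)
        a = dollo.dollo_assign(ps)
        assert a.gain_is_event and a.gain_node == "A"
        out = dollo.apply_overrides({"s": a}, {"s": ps}, ["s"])["s"]
        assert not out.gain_is_event
        assert 1 <= len(out.losses) <= 2
        covered = set()
        nodes = {n.name: n for n in tree.preorder()}
        for loss in out.losses:
            covered |= {t.name for t in nodes[loss].leaves()}
        assert covered == {"B", "C", "D"}

    def test_empty_override_list_is_identity(self):
        tree = parse_newick("((A,B),(C,D));")
        ps = pruned(tree, dict(A=True, B=False, C=True, D=True))
        a = dollo.dollo_assign(ps)
        assert dollo.apply_overrides({"s": a}, {"s": ps}, []) == {"s": a}

    def test_override_of_root_present_site_warns_noop(self):
        tree = parse_newick("((A,B),(C,D));")
        ps = pruned(tree, {t: True for t in "ABCD"})
        a = dollo.dollo_assign(ps)
        with pytest.warns(UserWarning, match="no-op"):
            out = dollo.apply_overrides({"s": a}, {"s": ps}, ["s"])
        assert out["s"] == a

    def test_override_then_reassign_recovers_original(self):
        tree = parse_newick("((A,B),(C,D));")
        ps = pruned(tree, dict(A=True, B=False, C=False, D=False))
        a = dollo.dollo_assign(ps)
        overridden = dollo.apply_overrides({"s": a}, {"s": ps}, ["s"])["s"]
        assert overridden != a
        assert dollo.dollo_assign(ps) == a


class TestSummarizeEvents:
    def test_a_and_b_losses_sum_on_simplified_branch(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        states = {("A", "A"): L, ("A", "B"): L, ("B", "A"): P,
                  ("B", "B"): P, ("C", "0"): P}
        ps = dollo.prune_for_site(et, states, "s1")
        a = dollo.dollo_assign(ps)
        emap = dollo.summarize_events({"s1": a}, et, {"s1": ps})
        assert emap.branch_losses == {"A": 2}

    def test_no_events_gives_empty_map(self):
        tree = parse_newick("((A,B)WGD,C);")
        et = dollo.expand_wgd_tree(tree)
        states = {("A", "A"): P, ("A", "B"): P, ("B", "A"): P,
                  ("B", "B"): P, ("C", "0"): P}
        ps = dollo.prune_for_site(et, states, "s1")
        emap = dollo.summarize_events({"s1": dollo.dollo_assign(ps)}, et, {"s1": ps})
        assert emap.total_losses == 0 and emap.total_gains == 0

    def test_summation_conservation(self, state_matrix, truth):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assignments, emap, _ = dollo.map_events(state_matrix, truth.etree)
        assert emap.total_losses == sum(len(a.losses) for a in assignments.values())
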