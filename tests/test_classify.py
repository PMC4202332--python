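"""State classification: presence calls, junction indel accounting, sliding
detection, matrix assembly and tallies."""

import numpy as np
import pytest

import intronevo as ie
import intronevo.io as eio
from intronevo import classify, simulate as sim
from intronevo.classify import ClassifyConfig
from intronevo.io import AnnotatedAlignment, IntronSiteFeature
from intronevo.matrix import IntronState, SiteMeta, StateMatrix


def intron_seq(spacer=40, s2=27):
    return "GTATGT" + "T" * spacer + "TACTAAC" + "T" * (s2 - 2) + "AG"


def two_row_alignment(x_span: str, y_span: str, exon="ACG" * 20):
    """X and Y share flanking exons; the span content differs per row."""
    width = max(len(x_span), len(y_span))
    x_span = x_span.ljust(width, "-")
    y_span = y_span.ljust(width, "-")
    rows = {("X", "0"): exon + x_span + exon,
            ("Y", "0"): exon + y_span + exon}
    site = IntronSiteFeature("s1", len(exon), len(exon) + width)
    return AnnotatedAlignment("fam", rows, sites=[site]), site


class TestClassifySiteState:
    def test_intact_intron_is_present(self):
        aln, site = two_row_alignment(intron_seq(), intron_seq())
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert st.state == "PRESENT" and st.note == ""

    def test_gapped_span_with_zero_indel_is_perfect_loss(self):
        aln, site = two_row_alignment(intron_seq(), "-" * 80)
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert (st.state, st.k) == ("LOST_PERFECT", 0)

    def test_frameshift_goes_to_unknown(self):
        # Y lost the intron and one exon base with it
        exon = "ACG" * 20
        rows = {("X", "0"): exon + intron_seq() + exon,
                ("Y", "0"): exon[:-1] + "-" + "-" * len(intron_seq()) + exon}
        site = IntronSiteFeature("s1", len(exon), len(exon) + len(intron_seq()))
        aln = AnnotatedAlignment("fam", rows, sites=[site])
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert st.state == "LOST_UNKNOWN" and "frameshift" in st.note

    def test_degenerate_two_of_three_signals_still_present(self):
        broken5 = "TTTTTT" + intron_seq()[6:]  # BP + 3'ss remain
        aln, site = two_row_alignment(intron_seq(), broken5)
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert st.state == "PRESENT" and st.note == "degenerate"

    def test_degenerate_one_of_three_signals_is_unknown(self):
        junk = "TTTTTT" + "T" * 40 + "CCCCCCC" + "T" * 25 + "AG"  # only 3'ss
        aln, site = two_row_alignment(intron_seq(), junk)
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert st.state == "LOST_UNKNOWN" and st.note == "degenerate"

    def test_missing_row_is_no_data(self):
        aln, site = two_row_alignment(intron_seq(), intron_seq())
        st = classify.classify_site_state(aln, site, ("Z", "0"))
        assert st.state == "NO_DATA"

    def test_utr_policy_routes_absent_utr_rows_to_unknown(self):
        exon = "ACG" * 20
        rows = {("X", "0"): exon + intron_seq() + exon,
                ("Y", "0"): exon + "-" * len(intron_seq()) + exon}
        site = IntronSiteFeature("s1", len(exon), len(exon) + len(intron_seq()),
                                 utr=True)
        aln = AnnotatedAlignment("fam", rows, sites=[site])
        st = classify.classify_site_state(aln, site, ("Y", "0"))
        assert (st.state, st.note) == ("LOST_UNKNOWN", "utr")

    def test_foreign_site_rejected(self):
        aln, _ = two_row_alignment(intron_seq(), intron_seq())
        other = IntronSiteFeature("sX", 0, 10)
        with pytest.raises(ValueError, match="belong"):
            classify.classify_site_state(aln, other, ("X", "0"))

    def test_config_invariant_enforced(self):
        with pytest.raises(ValueError):
            ClassifyConfig(perfect_max_codons=5, imperfect_min_codons=3)


@pytest.fixture(scope="module")
def rich_loss_run(default_tree, tmp_path_factory):
    cfg = ie.SimConfig(n_genes=60, loss_type_probs=(0.3, 0.4, 0.3),
                       per_branch_loss_prob=0.08, substitution_rate=0.0,
                       seed=23)
    truth = sim.simulate_intron_evolution(default_tree, cfg)
    out = tmp_path_factory.mktemp("rich")
    sim.emit_all(truth, out)
    alns = [eio.read_alignment(fa, fa.with_suffix(".gff3"))
            for fa in sorted((out / "alignments").glob("*.fa"))]
    pillar = eio.read_pillar(out / "pillar.tsv")
    return truth, ie.build_state_matrix(alns, pillar)


class TestEmittedInstanceRecovery:
    """Classifier vs simulator ground truth, including indel magnitudes."""

    def test_every_cell_recovers_truth_state_and_k(self, rich_loss_run):
        truth, m = rich_loss_run
        expected = truth.expected_signature()
        got = {(sid, col): (st.state, st.k) for (sid, col), st in m.cells.items()}
        assert got == expected

    def test_imperfect_losses_recovered_with_exact_codon_counts(self, rich_loss_run):
        truth, m = rich_loss_run
        imperfect = [(s.site_id, col, ts.k)
                     for s in truth.sites
                     for col, ts in s.states.items()
                     if ts.state == "lost_imperfect"]
        assert len(imperfect) >= 10
        assert any(k > 0 for _, _, k in imperfect)
        assert any(k < 0 for _, _, k in imperfect)
        for site_id, col, k in imperfect:
            st = m.get(site_id, col)
            assert (st.state, st.k) == ("LOST_IMPERFECT", k)


class TestDetectSliding:
    def make_slid_alignment(self):
        """Y carries a valid intron 9 columns (3 codons) 3' of the annotated
        site; X splices at the annotated position."""
        exon = "CAT" * 20
        iseq = intron_seq()
        L = len(iseq)
        # columns: exon | span (annotated) | 9 exon cols | insertion block | exon
        x_row = exon + iseq + "CAT" * 3 + "-" * L + exon
        y_row = exon + "-" * L + "CAT" * 3 + iseq + exon
        site = IntronSiteFeature("s1", len(exon), len(exon) + L)
        return AnnotatedAlignment("fam", {("X", "0"): x_row, ("Y", "0"): y_row},
                                  sites=[site]), site

    def test_shifted_intron_reported_with_offset(self):
        aln, site = self.make_slid_alignment()
        reports = classify.detect_sliding(aln, site)
        assert len(reports) == 1
        rep = reports[0]
        assert rep.row == ("Y", "0")
        assert rep.offset_cols == len(intron_seq()) + 9

    def test_all_present_rows_give_empty_report(self):
        aln, site = two_row_alignment(intron_seq(), intron_seq())
        assert classify.detect_sliding(aln, site) == []

    def test_shifted_motif_without_bp_is_not_reported(self):
        exon = "CAT" * 20
        fake = "GTATGT" + "T" * 41 + "AG"  # 5'ss + 3'ss but no BP
        x_row = exon + intron_seq(40, 14) + exon
        y_row = exon + "-" * len(intron_seq(40, 14)) + exon[:10] + fake + exon[10 + len(fake):]
        site = IntronSiteFeature("s1", len(exon), len(exon) + len(intron_seq(40, 14)))
        aln = AnnotatedAlignment("fam", {("X", "0"): x_row, ("Y", "0"): y_row},
                                 sites=[site])
        assert classify.detect_sliding(aln, site) == []

    def test_utr_to_orf_crossing_flagged(self):
        aln, site = self.make_slid_alignment()
        reports = classify.detect_sliding(aln, site,
                                          orf_start_col=site.start + 5)
        assert reports[0].crosses_start_codon


class TestBuildStateMatrix:
    def test_post_wgd_species_contribute_two_columns(self, state_matrix, pillar):
        scer_cols = [c for c in state_matrix.columns if c[0] == "Scer"]
        assert sorted(c[1] for c in scer_cols) == ["A", "B"]

    def test_pillar_alignment_inconsistency_reported(self, alignments, pillar):
        broken = eio.PillarTable(
            species=pillar.species, post_wgd=pillar.post_wgd,
            rows={g: dict(r) for g, r in pillar.rows.items()})
        fam = alignments[0].family
        col = next(c for c, v in broken.rows[fam].items() if v != eio.ABSENT)
        broken.rows[fam][col] = eio.ABSENT  # pillar now disagrees
        with pytest.raises(ValueError, match="inconsistency"):
            ie.build_state_matrix(alignments, broken)

    def test_classification_independent_of_row_order(self, alignments, pillar):
        aln = alignments[0]
        reordered = AnnotatedAlignment(
            aln.family, dict(reversed(list(aln.rows.items()))),
            sites=aln.sites, snornas=aln.snornas, rpg=aln.rpg)
        m1 = ie.build_state_matrix([aln], pillar)
        m2 = ie.build_state_matrix([reordered], pillar)
        assert m1 == m2


class TestTally:
    def make_matrix(self, states):
        m = StateMatrix([SiteMeta("s1", "f1")],
                        [(f"sp{i}", "0") for i in range(len(states))])
        for i, st in enumerate(states):
            m.set("s1", (f"sp{i}", "0"), st)
        return m

    def test_rate_counts_absent_over_defined(self):
        states = [IntronState("PRESENT")] * 8 + \
                 [IntronState("LOST_PERFECT", k=0)] * 2
        tally = classify.tally_states(self.make_matrix(states))
        assert tally.total_defined == 10
        assert tally.missing_per_site_per_species == pytest.approx(0.2)
        assert tally.perfect_fraction == pytest.approx(1.0)

    def test_all_present_has_null_perfect_fraction(self):
        tally = classify.tally_states(self.make_matrix([IntronState("PRESENT")] * 5))
        assert tally.missing_per_site_per_species == 0.0
        assert tally.perfect_fraction is None

    def test_no_data_excluded_and_counts_conserve(self, state_matrix):
        tally = classify.tally_states(state_matrix)
        assert sum(tally.counts.values()) == tally.total_defined
        n_no_data = sum(1 for (_, _), st in state_matrix.cells.items()
                        if not st.is_defined)
        assert tally.total_defined + n_no_data == len(state_matrix.cells)

    def test_empty_matrix_rejected(self):
        m = StateMatrix([SiteMeta("s1", "f1")], [("X", "0")])
        with pytest.raises(ValueError, match="no defined"):
            classify.tally_states(m)
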