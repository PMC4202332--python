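"""Classify the fate of every ancestral intron site per (species, locus).

A row is PRESENT when its intron span contains sequence with valid splice
signals (a degenerate intron still counts when at least two of the three
signals match).  For absent rows the classifier measures the net indel left
at the junction by comparing the row's ungapped exon length against the
modal exon length among intron-bearing rows, over the exon block on the 5'
side of the intron span:

* net indel within +/-``perfect_max_codons`` codons -> LOST_PERFECT
  (the cDNA-replacement signature);
* a net insertion/deletion of ``imperfect_min_codons``..``imperfect_max_codons``
  whole codons -> LOST_IMPERFECT(k);
* frameshifts (net indel not divisible by 3), unalignable flanks, oversized
  indels, and (by default) 5'-UTR sites -> LOST_UNKNOWN, still counted as a
  loss downstream;
* a missing row (gene absent or excluded) -> NO_DATA.

The indel window is the whole inter-span exon block 5' of the junction
rather than a fixed +/-window: a bounded window would truncate deletions
larger than itself, and imperfect losses run to 40 codons.  ``flank_codons``
instead sets the minimum alignable flank required for a confident call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import GAP, AnnotatedAlignment, IntronSiteFeature, PillarTable
from .matrix import IntronState, SiteMeta, StateMatrix
from .splice import SpliceConfig, SpliceError, annotate_intron, count_matching_signals


@dataclass(frozen=True)
class ClassifyConfig:
    perfect_max_codons: int = 2
    imperfect_min_codons: int = 3
    imperfect_max_codons: int = 40
    flank_codons: int = 10
    utr_policy: str = "LOST_UNKNOWN"

    def __post_init__(self):
        if not (self.perfect_max_codons < self.imperfect_min_codons
                <= self.imperfect_max_codons):
            raise ValueError("require perfect_max_codons < imperfect_min_codons "
                             "<= imperfect_max_codons")
        if self.utr_policy not in ("LOST_UNKNOWN", "CLASSIFY"):
            raise ValueError(f"unknown utr_policy {self.utr_policy!r}")


@dataclass(frozen=True)
class SlidingReport:
    """A valid intron found away from the annotated site in one row."""

    row: tuple[str, str]
    site_id: str
    new_start_col: int
    offset_cols: int
    crosses_start_codon: bool


def _window(aln: AnnotatedAlignment, site: IntronSiteFeature) -> tuple[int, int]:
    """The exon block 5' of the intron span: from the end of the previous
    intron span (or column 0) to the span start."""
    left = 0
    for other in aln.sites:
        if other.end <= site.start:
            left = max(left, other.end)
    return left, site.start


def _ungapped_len(seq: str) -> int:
    return len(seq) - seq.count(GAP)


def classify_site_state(
    aln: AnnotatedAlignment,
    site: IntronSiteFeature,
    row: tuple[str, str],
    splice_cfg: SpliceConfig | None = None,
    cls_cfg: ClassifyConfig | None = None,
) -> IntronState:
    """Classify one (site, species, locus) cell; see module docstring."""
    splice_cfg = splice_cfg or SpliceConfig()
    cls_cfg = cls_cfg or ClassifyConfig()
    if site not in aln.sites:
        raise ValueError(f"site {site.site_id} does not belong to family {aln.family}")
    if row not in aln.rows:
        return IntronState("NO_DATA", note="row absent")

    if aln.row_has_intron(row, site):
        seq = aln.intron_sequence(row, site)
        try:
            annotate_intron(seq, splice_cfg)
            return IntronState("PRESENT")
        except SpliceError:
            if count_matching_signals(seq, splice_cfg) >= 2:
                return IntronState("PRESENT", note="degenerate")
            return IntronState("LOST_UNKNOWN", note="degenerate")

    if site.utr and cls_cfg.utr_policy == "LOST_UNKNOWN":
        return IntronState("LOST_UNKNOWN", note="utr")

    # net indel accounting against intron-bearing rows
    lo, hi = _window(aln, site)
    ref_lengths = [
        _ungapped_len(aln.rows[other][lo:hi])
        for other in aln.rows
        if other != row and aln.row_has_intron(other, site)
    ]
    if not ref_lengths:
        return IntronState("LOST_UNKNOWN", note="no intron-bearing reference row")
    counts = Counter(ref_lengths)
    top = max(counts.values())
    mode = min(v for v, c in counts.items() if c == top)
    if mode < cls_cfg.flank_codons * 3:
        return IntronState("LOST_UNKNOWN", note="flank too short")

    obs = _ungapped_len(aln.rows[row][lo:hi])
    delta = obs - mode
    residual = delta % 3 if delta >= 0 else -((-delta) % 3)
    k = int(delta / 3)  # toward zero
    if residual != 0:
        return IntronState("LOST_UNKNOWN", note=f"frameshift (net {delta} nt)")
    if abs(k) <= cls_cfg.perfect_max_codons:
        return IntronState("LOST_PERFECT", k=k)
    if cls_cfg.imperfect_min_codons <= abs(k) <= cls_cfg.imperfect_max_codons:
        return IntronState("LOST_IMPERFECT", k=k)
    return IntronState("LOST_UNKNOWN", note=f"indel of {k} codons exceeds "
                       f"{cls_cfg.imperfect_max_codons}")


def detect_sliding(
    aln: AnnotatedAlignment,
    site: IntronSiteFeature,
    splice_cfg: SpliceConfig | None = None,
    orf_start_col: int | None = None,
) -> list[SlidingReport]:
    """Find valid introns at shifted positions in rows lacking the annotated
    intron.  Reports the column offset from the annotated 5'ss and, when
    *orf_start_col* is given, whether the move crosses the start codon."""
    splice_cfg = splice_cfg or SpliceConfig()
    reports: list[SlidingReport] = []
    motif = splice_cfg.five_ss_motif
    three = splice_cfg.three_ss_motif
    for row in sorted(aln.rows):
        if aln.row_has_intron(row, site):
            try:  # a valid intron at the annotated span is not sliding
                annotate_intron(aln.intron_sequence(row, site), splice_cfg)
                continue
            except SpliceError:
                pass
        gapped = aln.rows[row]
        cols = [i for i, ch in enumerate(gapped) if ch != GAP]
        seq = "".join(gapped[i] for i in cols)
        found: SlidingReport | None = None
        for p in range(len(seq) - splice_cfg.min_intron_len + 1):
            if seq[p : p + len(motif)] != motif:
                continue
            if cols[p] == site.start:
                continue
            q_lo = p + splice_cfg.min_intron_len
            q_hi = min(len(seq), p + splice_cfg.max_intron_len)
            for q in range(q_lo, q_hi + 1):
                if not seq[:q].endswith(three):
                    continue
                try:
                    annotate_intron(seq[p:q], splice_cfg)
                except SpliceError:
                    continue
                new_col = cols[p]
                crosses = False
                if orf_start_col is not None:
                    crosses = (site.start < orf_start_col) != (new_col < orf_start_col)
                found = SlidingReport(
                    row=row, site_id=site.site_id, new_start_col=new_col,
                    offset_cols=new_col - site.start, crosses_start_codon=crosses)
                break
            if found:
                break
        if found:
            reports.append(found)
    return reports


def build_state_matrix(
    alignments: list[AnnotatedAlignment],
    pillar: PillarTable,
    splice_cfg: SpliceConfig | None = None,
    cls_cfg: ClassifyConfig | None = None,
) -> StateMatrix:
    """Classify every cell of every family into one state matrix.

    Each annotated intron feature is one ancestral site (multiple introns in
    a gene are separate sites).  A family whose sites have no PRESENT call in
    any row is dropped.  A gene present in the pillar but missing from its
    family alignment (or vice versa) is an inconsistency error.
    """
    splice_cfg = splice_cfg or SpliceConfig()
    cls_cfg = cls_cfg or ClassifyConfig()

    offenders: list[str] = []
    per_family: dict[str, AnnotatedAlignment] = {}
    for aln in alignments:
        if aln.family not in pillar.rows:
            offenders.append(f"family {aln.family} not in pillar")
            continue
        per_family[aln.family] = aln
        expected = set(pillar.present_columns(aln.family))
        got = set(aln.rows)
        for col in sorted(expected - got):
            offenders.append(f"{aln.family}: pillar gene at {col} lacks an alignment row")
        for col in sorted(got - expected):
            offenders.append(f"{aln.family}: alignment row {col} absent from pillar")
    if offenders:
        raise ValueError("pillar/alignment inconsistency:\n  " + "\n  ".join(offenders))

    sno_by_site: dict[str, str] = {}
    metas: list[SiteMeta] = []
    cells: dict[tuple[str, tuple[str, str]], IntronState] = {}
    kept_sites: list[SiteMeta] = []
    for family in sorted(per_family):
        aln = per_family[family]
        for sno in aln.snornas:
            sno_by_site[sno.site_id] = sno.sno_id
        family_states: dict[str, dict[tuple[str, str], IntronState]] = {}
        any_present = False
        for site in aln.sites:
            site_states: dict[tuple[str, str], IntronState] = {}
            for col in pillar.present_columns(family):
                st = classify_site_state(aln, site, col, splice_cfg, cls_cfg)
                site_states[col] = st
                any_present = any_present or st.is_present
            family_states[site.site_id] = site_states
        if not any_present:
            continue  # family without a single PRESENT call is dropped
        for site in aln.sites:
            meta = SiteMeta(
                site_id=site.site_id, family=family, utr=site.utr,
                rpg=aln.rpg, snorna_id=sno_by_site.get(site.site_id, ""))
            kept_sites.append(meta)
            for col, st in family_states[site.site_id].items():
                cells[(site.site_id, col)] = st

    m = StateMatrix(kept_sites, pillar.columns())
    for (site_id, col), st in cells.items():
        m.set(site_id, col, st)
    return m


@dataclass(frozen=True)
class StateTally:
    """Counts of matrix cells by state (NO_DATA cells excluded)."""

    counts: dict
    total_defined: int
    absent: int
    missing_per_site_per_species: float
    perfect_fraction: float | None
    per_species: "object"  # pandas DataFrame: species x state counts


def tally_states(matrix: StateMatrix) -> StateTally:
    """Totals over defined cells: presence/absence counts, the
    missing-per-site-per-species rate and the perfect-loss fraction."""
    import pandas as pd

    defined = matrix.defined_cells()
    if not defined:
        raise ValueError("state matrix has no defined cells")
    counts: Counter = Counter(st.state for _, _, st in defined)
    total = len(defined)
    absent = sum(counts[s] for s in ("LOST_PERFECT", "LOST_IMPERFECT", "LOST_UNKNOWN"))
    perfect_fraction = counts["LOST_PERFECT"] / absent if absent else None

    per_species: dict[str, Counter] = {}
    for _, (species, _locus), st in defined:
        per_species.setdefault(species, Counter())[st.state] += 1
    species_frame = pd.DataFrame(
        [{"species": sp, **{s: c.get(s, 0) for s in
                            ("PRESENT", "LOST_PERFECT", "LOST_IMPERFECT", "LOST_UNKNOWN")}}
         for sp, c in sorted(per_species.items())]
    )
    return StateTally(
        counts=dict(counts),
        total_defined=total,
        absent=absent,
        missing_per_site_per_species=absent / total,
        perfect_fraction=perfect_fraction,
        per_species=species_frame,
    )
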