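"""Downstream tables: per-species loss profiles, snoRNA post-WGD fates,
ribosomal-protein-gene (RPG) intron statistics and the presence/loss heatmap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dollo import EventMap
from .io import ABSENT, AnnotatedAlignment, PillarTable
from .matrix import StateMatrix
from .splice import IntronAnnotation, SpliceConfig, SpliceError, annotate_intron
from .trees import SpeciesTree

SNORNA_FATES = (
    "BOTH_RETAINED",
    "ONE_COPY_RETAINED_WITH_SNORNA",
    "INTRON_LOST_SNORNA_IN_PARALOG_INTRON",
    "DEINTRONIZED",
    "SNORNA_REMOVED",
)


@dataclass(frozen=True)
class LocusFlags:
    """Post-WGD locus state for a snoRNA host gene."""

    gene: bool
    intron: bool
    snorna: bool


def classify_snorna_fate(a: LocusFlags, b: LocusFlags) -> str:
    """Post-duplication fate of an intronic-snoRNA host gene in one species.

    A fixed priority cascade makes the five categories exhaustive and
    mutually exclusive over the 2^6 locus-flag space:

    1. no snoRNA copy anywhere -> SNORNA_REMOVED;
    2. a snoRNA copy at a locus whose host gene is absent -> DEINTRONIZED;
    3. both loci keep gene, intron and snoRNA -> BOTH_RETAINED;
    4. a single retained gene copy keeping intron and snoRNA ->
       ONE_COPY_RETAINED_WITH_SNORNA;
    5. anything else (typically: both genes kept, the intron+snoRNA surviving
       only in the paralog) -> INTRON_LOST_SNORNA_IN_PARALOG_INTRON.
    """
    if not a.snorna and not b.snorna:
        return "SNORNA_REMOVED"
    if (a.snorna and not a.gene) or (b.snorna and not b.gene):
        return "DEINTRONIZED"
    if a.gene and b.gene and a.intron and b.intron and a.snorna and b.snorna:
        return "BOTH_RETAINED"
    if a.gene != b.gene:
        kept = a if a.gene else b
        if kept.intron and kept.snorna:
            return "ONE_COPY_RETAINED_WITH_SNORNA"
    return "INTRON_LOST_SNORNA_IN_PARALOG_INTRON"


def snorna_fates(
    matrix: StateMatrix,
    snorna_flags: pd.DataFrame,
    pillar: PillarTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every (snoRNA host gene, post-WGD species) into a fate.

    *snorna_flags* columns: family, snorna_id, site_id, species, locus,
    present, in_intron.  Gene presence comes from the pillar, intron presence
    from the state matrix.  Returns (per-case table, per-category counts).
    """
    post = sorted(pillar.post_wgd)
    if not post:
        warnings.warn("pillar has no post-WGD species; no fates to classify")
    flags = {(r.family, r.species, r.locus): bool(r.present)
             for r in snorna_flags.itertuples(index=False)}
    sites = {(r.family): (r.site_id, r.snorna_id)
             for r in snorna_flags.itertuples(index=False)}

    rows = []
    for family in sorted({r.family for r in snorna_flags.itertuples(index=False)}):
        site_id, sno_id = sites[family]
        if family not in pillar.rows:
            warnings.warn(f"snoRNA family {family} not in pillar; skipped")
            continue
        has_post = any(pillar.rows[family].get((sp, loc), ABSENT) != ABSENT
                       for sp in post for loc in ("A", "B"))
        if not has_post:
            warnings.warn(f"snoRNA host {family} has no post-WGD gene; "
                          f"excluded from post-WGD fate counts")
            continue
        for sp in post:
            locus_flags = []
            for loc in ("A", "B"):
                gene = pillar.rows[family].get((sp, loc), ABSENT) != ABSENT
                try:
                    intron = matrix.get(site_id, (sp, loc)).is_present
                except KeyError:
                    intron = False
                sno = flags.get((family, sp, loc), False)
                locus_flags.append(LocusFlags(gene=gene, intron=intron, snorna=sno))
            fate = classify_snorna_fate(*locus_flags)
            rows.append({"family": family, "snorna_id": sno_id, "species": sp,
                         "fate": fate,
                         "gene_A": int(locus_flags[0].gene),
                         "intron_A": int(locus_flags[0].intron),
                         "snorna_A": int(locus_flags[0].snorna),
                         "gene_B": int(locus_flags[1].gene),
                         "intron_B": int(locus_flags[1].intron),
                         "snorna_B": int(locus_flags[1].snorna)})
    table = pd.DataFrame(rows)
    counts = pd.DataFrame(
        [{"fate": f, "count": int((table["fate"] == f).sum()) if len(table) else 0}
         for f in SNORNA_FATES])
    return table, counts


def species_loss_table(matrix: StateMatrix, eventmap: EventMap) -> pd.DataFrame:
    """Per species: introns found, terminal-branch event totals, and the
    proportion of intron-containing ancestral genes with a lost intron.

    The denominator counts ancestral genes with at least one defined locus in
    that species; a gene counts as 'with lost intron' if any of its sites at
    any retained locus is in a LOST_* state.
    """
    species = sorted({sp for sp, _ in matrix.columns})
    rows = []
    for sp in species:
        cols = [c for c in matrix.columns if c[0] == sp]
        found = lost = 0
        genes_defined: set[str] = set()
        genes_lost: set[str] = set()
        for site in matrix.sites:
            for col in cols:
                st = matrix.get(site.site_id, col)
                if not st.is_defined:
                    continue
                genes_defined.add(site.family)
                if st.is_present:
                    found += 1
                else:
                    lost += 1
                    genes_lost.add(site.family)
        prop = len(genes_lost) / len(genes_defined) if genes_defined else 0.0
        rows.append({
            "species": sp,
            "introns_found": found,
            "introns_absent": lost,
            "terminal_gains": eventmap.branch_gains.get(sp, 0),
            "terminal_losses": eventmap.branch_losses.get(sp, 0),
            "prop_genes_with_loss": prop,
        })
    return pd.DataFrame(rows)


def collect_intron_annotations(
    alignments: list[AnnotatedAlignment],
    splice_cfg: SpliceConfig | None = None,
) -> pd.DataFrame:
    """Annotate every present intron row; one record per (site, species,
    locus) with length, S2 and the family RPG flag.  Rows failing the splice
    grammar are skipped."""
    splice_cfg = splice_cfg or SpliceConfig()
    rows = []
    for aln in alignments:
        for site in aln.sites:
            for col in sorted(aln.rows):
                if not aln.row_has_intron(col, site):
                    continue
                seq = aln.intron_sequence(col, site)
                try:
                    ann = annotate_intron(seq, splice_cfg)
                except SpliceError:
                    continue
                rows.append({"family": aln.family, "site_id": site.site_id,
                             "species": col[0], "locus": col[1],
                             "length": ann.length, "s2": ann.s2,
                             "bp_pos": ann.bp_pos, "rpg": int(aln.rpg)})
    return pd.DataFrame(rows, columns=["family", "site_id", "species", "locus",
                                       "length", "s2", "bp_pos", "rpg"])


def annotations_by_species(frame: pd.DataFrame) -> dict[str, list[IntronAnnotation]]:
    """Regroup a collect_intron_annotations frame for s2_summary."""
    out: dict[str, list[IntronAnnotation]] = {}
    for r in frame.itertuples(index=False):
        out.setdefault(r.species, []).append(
            IntronAnnotation(length=int(r.length), bp_pos=int(r.bp_pos),
                             s2=int(r.s2)))
    return out


@dataclass
class RPGStats:
    ancestral_rpg_introns: int
    rpg_loss_rate: float  # losses / defined RPG loci
    other_loss_rate: float
    lengths: pd.DataFrame  # per (species, rpg) log2-length samples
    bimodality: pd.DataFrame  # per species: bic margin and verdict


def bimodality_verdict(log2_lengths: np.ndarray, delta: float = 10.0,
                       seed: int = 0) -> tuple[bool, float]:
    """Two- vs one-component Gaussian mixture comparison on log2 lengths.

    Returns (bimodal?, BIC margin).  Bimodal when the 2-component fit beats
    the 1-component fit by more than *delta* BIC units.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(log2_lengths, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        return False, 0.0
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed)
        gm.fit(x)
        bics.append(gm.bic(x))
    margin = float(bics[0] - bics[1])
    return margin > delta, margin


def rpg_stats(
    matrix: StateMatrix,
    eventmap: EventMap,
    intron_lengths: pd.DataFrame,
    delta: float = 10.0,
    seed: int = 0,
) -> RPGStats:
    """RPG vs non-RPG loss rates and per-species intron-length bimodality.

    The loss-per-locus rate is losses divided by defined loci (cells), for
    RPG-flagged sites and all other sites separately.  Bimodality is judged
    per species on the pooled log2 intron-length sample.
    """
    rpg_sites = {s.site_id for s in matrix.sites if s.rpg}
    if not rpg_sites:
        raise ValueError("no RPG-flagged sites in matrix")

    def rate(site_ids: set) -> float:
        defined = lost = 0
        for sid, _col, st in matrix.defined_cells():
            if sid in site_ids:
                defined += 1
                lost += int(st.is_lost)
        return lost / defined if defined else float("nan")

    other_sites = {s.site_id for s in matrix.sites} - rpg_sites
    lengths = intron_lengths.copy()
    lengths["log2_length"] = np.log2(lengths["length"].astype(float))

    verdicts = []
    for sp, group in lengths.groupby("species"):
        bimodal, margin = bimodality_verdict(
            group["log2_length"].to_numpy(), delta=delta, seed=seed)
        verdicts.append({"species": sp, "bic_margin": margin,
                         "bimodal": bimodal})
    return RPGStats(
        ancestral_rpg_introns=len(rpg_sites),
        rpg_loss_rate=rate(rpg_sites),
        other_loss_rate=rate(other_sites),
        lengths=lengths[["species", "rpg", "length", "log2_length"]],
        bimodality=pd.DataFrame(verdicts, columns=["species", "bic_margin", "bimodal"]),
    )


# ---------------------------------------------------------------------------
# Heatmap export

_HEATMAP_CODE = {
    "PRESENT": "present",
    "LOST_PERFECT": "loss_cdna",
    "LOST_IMPERFECT": "loss_indel",
    "LOST_UNKNOWN": "unknown",
    "NO_DATA": "unknown",
}


def heatmap_matrix(matrix: StateMatrix, tree: SpeciesTree) -> pd.DataFrame:
    """Fig-4-style export: one row per (species, locus) ordered by tree
    traversal (post-WGD species contribute A and B sub-rows), one column per
    ancestral intron site, and the four-way code present / loss_cdna /
    loss_indel / unknown."""
    order = []
    cols_by_species: dict[str, list[tuple[str, str]]] = {}
    for sp, loc in matrix.columns:
        cols_by_species.setdefault(sp, []).append((sp, loc))
    for tip in tree.tip_names():
        for col in sorted(cols_by_species.get(tip, [])):
            order.append(col)
    for sp in sorted(cols_by_species):  # species outside the tree, if any
        for col in cols_by_species[sp]:
            if col not in order:
                order.append(col)

    site_ids = [s.site_id for s in sorted(matrix.sites,
                                          key=lambda s: (s.family, s.site_id))]
    data = {
        "row": [f"{sp}|{loc}" for sp, loc in order],
    }
    for sid in site_ids:
        data[sid] = [_HEATMAP_CODE[matrix.get(sid, col).state] for col in order]
    return pd.DataFrame(data)


def write_heatmap(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_heatmap(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
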