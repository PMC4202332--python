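"""Readers and writers for every file format the pipeline touches.

Coordinate conventions: internal coordinates are 0-based half-open
everywhere.  GFF3 is 1-based inclusive and BED 0-based half-open on disk;
the converters in this module are the only places those conversions happen.

Readers validate strictly and raise rather than silently repairing input;
writers emit deterministic, sorted output so that re-serialization is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from gffutils.iterators import DataIterator

from .matrix import StateMatrix
from .trees import SpeciesTree, parse_newick

ABSENT = "-"
GAP = "-"
PRE_WGD_LOCUS = "0"
POST_WGD_LOCI = ("A", "B")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Newick


def read_newick(path, wgd_label: str = "WGD") -> SpeciesTree:
    """Parse a rooted Newick tree; an internal node labeled *wgd_label*
    becomes the tagged WGD node."""
    text = Path(path).read_text()
    return parse_newick(text, wgd_label=wgd_label)


def write_newick(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Annotated alignments (FASTA + companion GFF3)


@dataclass(frozen=True)
class IntronSiteFeature:
    """One ancestral intron site, in alignment coordinates (half-open)."""

    site_id: str
    start: int
    end: int
    bp_col: int | None = None
    utr: bool = False

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise FormatError(f"bad intron span for {self.site_id}: "
                              f"[{self.start}, {self.end})")


@dataclass(frozen=True)
class SnoRNAFeature:
    sno_id: str
    site_id: str
    start: int
    end: int


@dataclass
class AnnotatedAlignment:
    """A gene-family alignment with intron / branch-point / snoRNA features.

    Rows are keyed by (species, locus); all rows have equal gapped length.
    An intron span that is all gaps in a row means that row lacks the intron.
    """

    family: str
    rows: dict[tuple[str, str], str]
    sites: list[IntronSiteFeature] = field(default_factory=list)
    snornas: list[SnoRNAFeature] = field(default_factory=list)
    rpg: bool = False

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError(f"{self.family}: ragged alignment rows {sorted(lengths)}")
        self.length = lengths.pop() if lengths else 0
        for site in self.sites:
            if site.end > self.length:
                raise FormatError(f"{self.family}/{site.site_id}: intron span "
                                  f"exceeds alignment length {self.length}")
            if site.bp_col is not None and not site.start <= site.bp_col < site.end:
                raise FormatError(f"{self.family}/{site.site_id}: branch point "
                                  f"outside intron span")
        for sno in self.snornas:
            if sno.end > self.length:
                raise FormatError(f"{self.family}/{sno.sno_id}: snoRNA span "
                                  f"exceeds alignment length")

    def row_has_intron(self, col: tuple[str, str], site: IntronSiteFeature) -> bool:
        seq = self.rows[col][site.start : site.end]
        return any(ch != GAP for ch in seq)

    def intron_sequence(self, col: tuple[str, str], site: IntronSiteFeature) -> str:
        return self.rows[col][site.start : site.end].replace(GAP, "")


def _row_key(record_id: str) -> tuple[str, str]:
    if "|" in record_id:
        species, locus = record_id.split("|", 1)
    else:
        species, locus = record_id, PRE_WGD_LOCUS
    return species, locus


_KNOWN_FEATURES = {"gene", "intron", "branch_point", "snoRNA"}


def read_alignment(fasta_path, gff3_path) -> AnnotatedAlignment:
    """Read a family alignment (FASTA, '-' gaps) and its GFF3 feature file.

    GFF3 coordinates (1-based inclusive) are converted to internal half-open
    alignment-column spans.  Unknown feature types and out-of-bounds features
    raise :class:`FormatError` naming the offending record.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    rows: dict[tuple[str, str], str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        key = _row_key(rec.id)
        if key in rows:
            raise FormatError(f"{fasta_path.name}: duplicate row {rec.id}")
        rows[key] = str(rec.seq).upper()
    if not rows:
        raise FormatError(f"{fasta_path.name}: no sequences")

    family = fasta_path.stem
    sites: list[IntronSiteFeature] = []
    snornas: list[SnoRNAFeature] = []
    bp_by_site: dict[str, int] = {}
    rpg = False
    for feat in DataIterator(str(gff3_path)):
        ftype = feat.featuretype
        if ftype not in _KNOWN_FEATURES:
            raise FormatError(f"{gff3_path.name}: unknown feature type {ftype!r} "
                              f"on line for {feat.id or feat.seqid}")
        if feat.start < 1 or feat.end < feat.start:
            raise FormatError(f"{gff3_path.name}: bad coordinates "
                              f"{feat.start}..{feat.end} for {ftype}")
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        fid = feat.attributes.get("ID", [None])[0]
        if ftype == "gene":
            family = fid or family
            rpg = feat.attributes.get("rpg", ["0"])[0] in ("1", "true", "True")
        elif ftype == "intron":
            if not fid:
                raise FormatError(f"{gff3_path.name}: intron feature without ID")
            utr = feat.attributes.get("utr", ["0"])[0] in ("1", "true", "True")
            sites.append(IntronSiteFeature(fid, start, end, utr=utr))
        elif ftype == "branch_point":
            parent = feat.attributes.get("Parent", [None])[0]
            if parent is None:
                raise FormatError(f"{gff3_path.name}: branch_point without Parent")
            bp_by_site[parent] = start
        elif ftype == "snoRNA":
            parent = feat.attributes.get("Parent", [""])[0]
            snornas.append(SnoRNAFeature(fid or "snoRNA", parent, start, end))

    sites = [
        IntronSiteFeature(s.site_id, s.start, s.end,
                          bp_col=bp_by_site.get(s.site_id), utr=s.utr)
        for s in sites
    ]
    return AnnotatedAlignment(family=family, rows=rows, sites=sites,
                              snornas=snornas, rpg=rpg)


def write_alignment(aln: AnnotatedAlignment, fasta_path, gff3_path) -> None:
    """Write an alignment back to FASTA + GFF3 (inverse of read_alignment)."""
    with open(fasta_path, "w") as fh:
        for (species, locus) in sorted(aln.rows):
            fh.write(f">{species}|{locus}\n{aln.rows[(species, locus)]}\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        src = "intronevo"
        fh.write(f"{aln.family}\t{src}\tgene\t1\t{aln.length}\t.\t+\t.\t"
                 f"ID={aln.family};rpg={int(aln.rpg)}\n")
        for s in sorted(aln.sites, key=lambda s: s.start):
            fh.write(f"{aln.family}\t{src}\tintron\t{s.start + 1}\t{s.end}\t.\t+\t.\t"
                     f"ID={s.site_id};utr={int(s.utr)}\n")
            if s.bp_col is not None:
                fh.write(f"{aln.family}\t{src}\tbranch_point\t{s.bp_col + 1}\t"
                         f"{s.bp_col + 7}\t.\t+\t.\tParent={s.site_id}\n")
        for sno in sorted(aln.snornas, key=lambda x: x.start):
            fh.write(f"{aln.family}\t{src}\tsnoRNA\t{sno.start + 1}\t{sno.end}\t.\t+\t.\t"
                     f"ID={sno.sno_id};Parent={sno.site_id}\n")


# ---------------------------------------------------------------------------
# Ortholog pillar table


@dataclass
class PillarTable:
    """Ancestral gene -> per-(species, locus) gene id or absent marker '-'.

    Post-WGD species always carry two locus slots (A/B); pre-WGD species one
    (locus "0").
    """

    species: list[str]
    post_wgd: frozenset
    rows: dict[str, dict[tuple[str, str], str]]

    def loci_for(self, species: str) -> tuple[str, ...]:
        return POST_WGD_LOCI if species in self.post_wgd else (PRE_WGD_LOCUS,)

    def columns(self) -> list[tuple[str, str]]:
        return [(sp, loc) for sp in self.species for loc in self.loci_for(sp)]

    def present_columns(self, gene: str) -> list[tuple[str, str]]:
        row = self.rows[gene]
        return [col for col in self.columns() if row.get(col, ABSENT) != ABSENT]

    def validate(self) -> None:
        cols = set(self.columns())
        for gene, row in self.rows.items():
            extra = set(row) - cols
            if extra:
                raise FormatError(f"pillar row {gene}: unknown columns {sorted(extra)}")
            if not any(v != ABSENT for v in row.values()):
                raise FormatError(f"pillar row {gene}: no gene present in any species")


def read_pillar(path) -> PillarTable:
    """Read the pillar TSV.  Header: ``ancestral_gene`` then one column per
    pre-WGD species (``Sp``) or two per post-WGD species (``Sp|A``, ``Sp|B``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna(ABSENT)
    if frame.columns[0] != "ancestral_gene":
        raise FormatError("pillar file must start with an 'ancestral_gene' column")
    species: list[str] = []
    post: set[str] = set()
    cols: list[tuple[str, str]] = []
    for name in frame.columns[1:]:
        sp, loc = _row_key(name)
        if loc not in (PRE_WGD_LOCUS, *POST_WGD_LOCI):
            raise FormatError(f"pillar column {name!r}: unknown locus {loc!r}")
        if loc != PRE_WGD_LOCUS:
            post.add(sp)
        if sp not in species:
            species.append(sp)
        cols.append((sp, loc))
    for sp in post:
        have = {loc for s, loc in cols if s == sp}
        if have != set(POST_WGD_LOCI):
            raise FormatError(f"post-WGD species {sp} must have exactly loci A and B, "
                              f"got {sorted(have)}")
    rows: dict[str, dict[tuple[str, str], str]] = {}
    for rec in frame.itertuples(index=False):
        gene = rec[0]
        rows[gene] = dict(zip(cols, rec[1:]))
    table = PillarTable(species=species, post_wgd=frozenset(post), rows=rows)
    table.validate()
    return table


def write_pillar(pillar: PillarTable, path) -> None:
    header = ["ancestral_gene"] + [
        sp if loc == PRE_WGD_LOCUS else f"{sp}|{loc}" for sp, loc in pillar.columns()
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for gene in sorted(pillar.rows):
            row = pillar.rows[gene]
            values = [row.get(col, ABSENT) for col in pillar.columns()]
            fh.write("\t".join([gene] + values) + "\n")


# ---------------------------------------------------------------------------
# Splice junctions (BED6; score column carries the read count)


@dataclass(frozen=True)
class Junction:
    chrom: str
    start: int
    end: int
    name: str = "."
    read_count: int = 0
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise FormatError(f"junction {self.name}: end must exceed start >= 0")
        if self.read_count < 0:
            raise FormatError(f"junction {self.name}: negative read count")
        if self.strand not in ("+", "-"):
            raise FormatError(f"junction {self.name}: strand must be '+' or '-'")


_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_junction_bed(path) -> list[Junction]:
    frame = pd.read_csv(path, sep="\t", names=_BED6, header=None,
                        dtype={"chrom": str, "name": str, "strand": str})
    if frame.isna().any().any():
        raise FormatError(f"{path}: expected 6 BED columns")
    return [
        Junction(chrom=r.chrom, start=int(r.start), end=int(r.end),
                 name=r.name, read_count=int(r.score), strand=r.strand)
        for r in frame.itertuples(index=False)
    ]


def write_junction_bed(junctions: list[Junction], path) -> None:
    ordered = sorted(junctions, key=lambda j: (j.chrom, j.start, j.end, j.name))
    with open(path, "w") as fh:
        for j in ordered:
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\t{j.name}\t{j.read_count}\t{j.strand}\n")


# ---------------------------------------------------------------------------
# Genome FASTA, state matrix, events, config


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


def write_state_matrix(matrix: StateMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_state_matrix(path) -> StateMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"site_id": str, "family": str,
                                               "species": str, "locus": str,
                                               "snorna_id": str, "note": str},
                        keep_default_na=False, na_values=[])
    return StateMatrix.from_frame(frame)


def write_events(eventmap, path) -> None:
    """Write per-site events and the per-branch summary of an EventMap."""
    eventmap.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"site_id": str, "branch": str,
                                              "event": str, "locus": str})


def load_config(path) -> dict:
    """Load the structured YAML configuration controlling all parameters."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError("config file must hold a mapping")
    return data
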