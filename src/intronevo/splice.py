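"""Yeast splice-signal grammar, S2 distances and junction statistics.

Saccharomycetaceae introns obey a strict motif grammar: the intron starts with
the 5'-splice-site donor GTATGT, contains the branch-point (BP) heptamer
TACTAAC, and ends in AG.  These yeasts lack the metazoan poly-pyrimidine
tract; the 3'-splice site is instead located by its distance from the BP, the
"S2 distance".  Operationally S2 is defined here as the number of nucleotides
from the end of the BP heptamer to the final intron base, inclusive of the
terminal AG::

    S2 = intron_length - bp_pos - len(bp_motif)

When several BP motif occurrences qualify, the rightmost one (closest to the
3' end) is chosen, matching the 3'-proximal position of the yeast BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SpliceError(ValueError):
    """A sequence violates the intron grammar."""

    def __init__(self, kind: str, message: str):
        self.kind = kind
        super().__init__(f"{kind}: {message}")


@dataclass(frozen=True)
class SpliceConfig:
    """Motifs and length bounds for intron validation.

    Defaults encode the strict Saccharomycetaceae consensus (zero mismatch)
    and the annotated S. cerevisiae intron length range of 49-1050 nt.
    """

    five_ss_motif: str = "GTATGT"
    bp_motif: str = "TACTAAC"
    three_ss_motif: str = "AG"
    five_ss_max_mismatch: int = 0
    bp_max_mismatch: int = 0
    min_intron_len: int = 49
    max_intron_len: int = 1050
    min_s2: int = 1

    def __post_init__(self):
        for m in (self.five_ss_motif, self.bp_motif, self.three_ss_motif):
            if not m or any(ch not in "ACGT" for ch in m):
                raise ValueError(f"motif must be non-empty uppercase DNA: {m!r}")
        if not (0 < self.min_intron_len <= self.max_intron_len):
            raise ValueError("require 0 < min_intron_len <= max_intron_len")
        if self.min_s2 < 1:
            raise ValueError("min_s2 must be >= 1")


@dataclass(frozen=True)
class IntronAnnotation:
    """A validated intron: BP location, S2 distance and motif mismatches."""

    length: int
    bp_pos: int
    s2: int
    five_ss_mismatches: int = 0
    bp_mismatches: int = 0

    def __post_init__(self):
        if not 0 < self.bp_pos + self.s2 < self.length:
            raise ValueError("inconsistent BP position / S2 / length")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _mismatches(seq: str, motif: str) -> int:
    return sum(1 for a, b in zip(seq, motif) if a != b)


def annotate_intron(seq: str, cfg: SpliceConfig | None = None) -> IntronAnnotation:
    """Validate *seq* as an intron and locate its branch point.

    Checks the 5'ss at position 0 (within ``five_ss_max_mismatch``), the exact
    terminal 3'ss motif and the length bounds, then finds the rightmost BP
    motif occurrence (within ``bp_max_mismatch``) leaving S2 >= ``min_s2``.

    Raises
    ------
    SpliceError
        kind ``"length violation"``, ``"invalid splice site"`` or
        ``"no branch point"``.
    """
    cfg = cfg or SpliceConfig()
    n = len(seq)
    if not (cfg.min_intron_len <= n <= cfg.max_intron_len):
        raise SpliceError("length violation", f"length {n} outside "
                          f"[{cfg.min_intron_len}, {cfg.max_intron_len}]")
    if _mismatches(seq[: len(cfg.five_ss_motif)], cfg.five_ss_motif) > cfg.five_ss_max_mismatch:
        raise SpliceError("invalid splice site",
                          f"5'ss {seq[:len(cfg.five_ss_motif)]!r} != {cfg.five_ss_motif}")
    if not seq.endswith(cfg.three_ss_motif):
        raise SpliceError("invalid splice site",
                          f"3'ss {seq[-len(cfg.three_ss_motif):]!r} != {cfg.three_ss_motif}")
    bw = len(cfg.bp_motif)
    five_ss_mm = _mismatches(seq[: len(cfg.five_ss_motif)], cfg.five_ss_motif)
    # rightmost qualifying BP: scan from the largest start leaving min_s2
    latest = n - bw - cfg.min_s2
    for pos in range(latest, len(cfg.five_ss_motif) - 1, -1):
        mm = _mismatches(seq[pos : pos + bw], cfg.bp_motif)
        if mm <= cfg.bp_max_mismatch:
            return IntronAnnotation(
                length=n,
                bp_pos=pos,
                s2=n - pos - bw,
                five_ss_mismatches=five_ss_mm,
                bp_mismatches=mm,
            )
    raise SpliceError("no branch point",
                      f"no {cfg.bp_motif} with S2 >= {cfg.min_s2} in {n} nt intron")


def count_matching_signals(seq: str, cfg: SpliceConfig | None = None) -> int:
    """How many of the three splice signals (5'ss, BP, 3'ss) match in *seq*.

    Used by the state classifier to distinguish a degenerate-but-present
    intron (>= 2 of 3 signals) from an unrecognizable span.  Length bounds
    are not enforced here.
    """
    cfg = cfg or SpliceConfig()
    score = 0
    if _mismatches(seq[: len(cfg.five_ss_motif)], cfg.five_ss_motif) <= cfg.five_ss_max_mismatch:
        score += 1
    if seq.endswith(cfg.three_ss_motif):
        score += 1
    bw = len(cfg.bp_motif)
    for pos in range(len(seq) - bw - cfg.min_s2, -1, -1):
        if _mismatches(seq[pos : pos + bw], cfg.bp_motif) <= cfg.bp_max_mismatch:
            score += 1
            break
    return score


def validate_junction(genome: dict[str, str], junction, cfg: SpliceConfig | None = None):
    """Extract the intron under a splice junction and validate its grammar.

    *junction* carries 0-based half-open genomic coordinates and a strand;
    minus-strand junctions are reverse-complemented before annotation.
    Returns an :class:`IntronAnnotation`; raises ``KeyError``/``IndexError``
    for bad coordinates and :class:`SpliceError` for grammar failures.
    """
    cfg = cfg or SpliceConfig()
    if junction.chrom not in genome:
        raise KeyError(f"unknown sequence {junction.chrom!r}")
    chrom = genome[junction.chrom]
    if not (0 <= junction.start < junction.end <= len(chrom)):
        raise IndexError(
            f"junction {junction.start}-{junction.end} outside {junction.chrom} "
            f"(length {len(chrom)})")
    seq = chrom[junction.start : junction.end].upper()
    if junction.strand == "-":
        seq = reverse_complement(seq)
    return annotate_intron(seq, cfg)


def s2_summary(annotations_by_species: dict[str, list[IntronAnnotation]]):
    """Per-species S2 summary: median, mean, n (natural scale) + log2 mean."""
    import pandas as pd

    rows = []
    for species in sorted(annotations_by_species):
        anns = annotations_by_species[species]
        if not anns:
            continue
        s2 = np.array([a.s2 for a in anns], dtype=float)
        rows.append({
            "species": species,
            "n": len(s2),
            "median_s2": float(np.median(s2)),
            "mean_s2": float(np.mean(s2)),
            "mean_log2_s2": float(np.mean(np.log2(s2))),
        })
    return pd.DataFrame(rows, columns=["species", "n", "median_s2", "mean_s2", "mean_log2_s2"])


def normalize_junction_counts(
    junctions: dict[str, tuple[int, int]],
    library_size: float,
    mode: str = "per_million",
) -> dict[str, float]:
    """Normalize raw junction read counts.

    Parameters
    ----------
    junctions
        id -> (read_count, intron_length_nt).
    mode
        ``per_million``: count * 1e6 / library_size.
        ``per_kb_per_million``: additionally divided by intron length in kb.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if mode not in ("per_million", "per_kb_per_million"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, float] = {}
    for jid, (count, length) in junctions.items():
        value = count * 1e6 / library_size
        if mode == "per_kb_per_million":
            if length <= 0:
                raise ValueError(f"zero-length intron for junction {jid!r}")
            value /= length / 1000.0
        out[jid] = value
    return out


def correlate(x: dict[str, float], y: dict[str, float]) -> CorrelationResult:
    """Pearson product-moment correlation over the shared ids of x and y."""
    shared = sorted(set(x) & set(y))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared ids, got {len(shared)}")
    xv = np.array([x[k] for k in shared], dtype=float)
    yv = np.array([y[k] for k in shared], dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(shared))
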