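"""The ancestral-intron-site state matrix.

The unit of analysis is the *intron site*: an alignment position carrying an
intron in at least one species.  For every site and every (species, locus)
with a gene in the ortholog pillar, the matrix stores one of:

PRESENT         intron present with valid splice signals
LOST_PERFECT    intron absent, coding sequence intact within +/-2 codons
                (the cDNA-replacement signature)
LOST_IMPERFECT  intron absent with a net 3-40 codon insertion/deletion (k)
LOST_UNKNOWN    intron absent, mechanism unresolvable from the alignment
NO_DATA         gene absent at that locus or excluded from the alignment

Post-WGD species contribute two locus columns (A/B); pre-WGD species one
(locus "0").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

STATES = ("PRESENT", "LOST_PERFECT", "LOST_IMPERFECT", "LOST_UNKNOWN", "NO_DATA")
LOSS_STATES = ("LOST_PERFECT", "LOST_IMPERFECT", "LOST_UNKNOWN")


@dataclass(frozen=True)
class IntronState:
    state: str
    k: int | None = None
    note: str = ""

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "LOST_IMPERFECT":
            if self.k is None or abs(self.k) < 3:
                raise ValueError("LOST_IMPERFECT requires a codon count |k| >= 3")

    @property
    def is_present(self) -> bool:
        return self.state == "PRESENT"

    @property
    def is_lost(self) -> bool:
        return self.state in LOSS_STATES

    @property
    def is_defined(self) -> bool:
        return self.state != "NO_DATA"


PRESENT = IntronState("PRESENT")
NO_DATA = IntronState("NO_DATA")


@dataclass(frozen=True)
class SiteMeta:
    site_id: str
    family: str
    utr: bool = False
    rpg: bool = False
    snorna_id: str = ""


class StateMatrix:
    """Site x (species, locus) grid of :class:`IntronState`."""

    def __init__(self, sites: list[SiteMeta], columns: list[tuple[str, str]]):
        if len({s.site_id for s in sites}) != len(sites):
            raise ValueError("duplicate site ids")
        self.sites = list(sites)
        self.columns = list(columns)
        self._meta = {s.site_id: s for s in self.sites}
        self.cells: dict[tuple[str, tuple[str, str]], IntronState] = {
            (s.site_id, col): NO_DATA for s in self.sites for col in self.columns
        }

    def set(self, site_id: str, col: tuple[str, str], state: IntronState) -> None:
        if (site_id, col) not in self.cells:
            raise KeyError((site_id, col))
        self.cells[(site_id, col)] = state

    def get(self, site_id: str, col: tuple[str, str]) -> IntronState:
        return self.cells[(site_id, col)]

    def meta(self, site_id: str) -> SiteMeta:
        return self._meta[site_id]

    def site_states(self, site_id: str) -> dict[tuple[str, str], IntronState]:
        return {col: self.cells[(site_id, col)] for col in self.columns}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def defined_cells(self) -> list[tuple[str, tuple[str, str], IntronState]]:
        return [
            (sid, col, st)
            for (sid, col), st in self.cells.items()
            if st.is_defined
        ]

    # -- (de)serialization ----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            for col in self.columns:
                st = self.cells[(site.site_id, col)]
                rows.append({
                    "site_id": site.site_id,
                    "family": site.family,
                    "species": col[0],
                    "locus": col[1],
                    "state": st.state,
                    "k_codons": "" if st.k is None else st.k,
                    "note": st.note,
                    "utr": int(site.utr),
                    "rpg": int(site.rpg),
                    "snorna_id": site.snorna_id,
                })
        frame = pd.DataFrame(rows)
        return frame.sort_values(["site_id", "species", "locus"], kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StateMatrix":
        sites: dict[str, SiteMeta] = {}
        columns: list[tuple[str, str]] = []
        for r in frame.itertuples(index=False):
            if r.site_id not in sites:
                sites[r.site_id] = SiteMeta(
                    site_id=r.site_id,
                    family=r.family,
                    utr=bool(int(r.utr)),
                    rpg=bool(int(r.rpg)),
                    snorna_id="" if pd.isna(r.snorna_id) else str(r.snorna_id),
                )
            col = (r.species, str(r.locus))
            if col not in columns:
                columns.append(col)
        m = cls(sorted(sites.values(), key=lambda s: s.site_id), sorted(columns))
        for r in frame.itertuples(index=False):
            k = None if r.k_codons in ("", None) or pd.isna(r.k_codons) else int(r.k_codons)
            note = "" if pd.isna(r.note) else str(r.note)
            m.set(r.site_id, (r.species, str(r.locus)),
                  IntronState(r.state, k=k, note=note))
        return m

    def __eq__(self, other) -> bool:
        if not isinstance(other, StateMatrix):
            return NotImplemented
        return (
            sorted(self._meta.items()) == sorted(other._meta.items())
            and sorted(self.columns) == sorted(other.columns)
            and self.cells == other.cells
        )
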