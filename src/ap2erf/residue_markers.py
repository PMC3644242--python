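"""Conservation analysis and group-diagnostic residues of the AP2 domain.

Works on domains anchored to the AtERF1 structural numbering (positions
145-202 plus the "167i" insertion slot).  Marker discovery operationalizes
"group-specific residue" as a *consensus deviation*: a residue that (i)
differs from the cross-group modal background at its position, (ii) is
conserved within the group at >= ``within_min`` percent, (iii) occurs in
background-conforming groups at <= ``outside_max`` percent, and (iv) is
the modal state of at most ``max_shared_groups`` groups.  The sharing cap
separates genuine group markers (e.g. G168, shared by groups IV and VII)
from the four-group DREB subfamily diagnostics V158/E163, which are
handled by :func:`subfamily_call` instead.  Group IX is marked by
occupancy of the insertion slot (+X167), not by a substitution.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .constants import (
    DREB_DIAGNOSTIC,
    DREB_GROUPS,
    EAR_PATTERN,
    ERF_DIAGNOSTIC,
    ERF_GROUPS,
    FIRST_POSITION,
    INSERTION_KEY,
    LAST_POSITION,
    MOTIFS,
    SAKUMA_BANDS,
)
from .errors import InputError

_POSITION_ORDER: list = list(range(FIRST_POSITION, 168)) + [INSERTION_KEY] + list(
    range(168, LAST_POSITION + 1)
)


@dataclass
class ConservationTable:
    """Per-group, per-position residue frequencies over non-gap rows."""

    counts: dict            # (group, position) -> Counter of residues
    group_sizes: dict       # group -> number of sequences
    occupancy: dict         # (group, position) -> non-gap count

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_sizes)

    def freq(self, group: str, position) -> dict:
        occ = self.occupancy.get((group, position), 0)
        if occ == 0:
            return {}
        return {r: c / occ for r, c in self.counts.get((group, position), {}).items()}

    def gap_fraction(self, group: str, position) -> float:
        n = self.group_sizes[group]
        return 1.0 - self.occupancy.get((group, position), 0) / n

    def insertion_occupancy(self, group: str) -> float:
        n = self.group_sizes[group]
        return self.occupancy.get((group, INSERTION_KEY), 0) / n

    def modal(self, group: str, position):
        f = self.freq(group, position)
        if not f:
            return None
        best = max(f.values())
        return sorted(r for r, v in f.items() if v == best)[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (group, pos), counter in sorted(
            self.counts.items(), key=lambda kv: (kv[0][0], _POSITION_ORDER.index(kv[0][1]))
        ):
            occ = self.occupancy[(group, pos)]
            for res, c in sorted(counter.items()):
                rows.append(
                    {"group": group, "position": str(pos), "residue": res,
                     "frequency": c / occ, "gap_fraction": self.gap_fraction(group, pos)}
                )
        return pd.DataFrame(rows, columns=["group", "position", "residue", "frequency", "gap_fraction"])


@dataclass
class MarkerEntry:
    group: str
    position: object          # int or "167i"
    residue: str
    conservation_pct: float


@dataclass
class MarkerTable:
    """Discovered group-diagnostic residues plus the universal set."""

    entries: list[MarkerEntry] = field(default_factory=list)
    universal: dict = field(default_factory=dict)   # position -> residue

    def as_set(self) -> set[tuple[str, object, str]]:
        return {(e.group, e.position, e.residue) for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": e.group, "position": str(e.position), "residue": e.residue,
                 "conservation_pct": e.conservation_pct}
                for e in self.entries
            ],
            columns=["group", "position", "residue", "conservation_pct"],
        )


@dataclass
class MotifReport:
    """Occurrence flags/positions of the conserved AP2-domain elements."""

    gene_id: str
    positions: dict         # motif name -> first 0-based position or None

    def has(self, motif: str) -> bool:
        return self.positions.get(motif) is not None


def column_conservation(labelled_domains) -> ConservationTable:
    """Tally residue frequencies per (group, position).

    ``labelled_domains`` yields ``(group_label, domain)`` pairs, where the
    domain exposes a ``residues`` mapping of structural positions.
    """
    counts: dict = {}
    sizes: dict = {}
    occupancy: dict = {}
    for group, dom in labelled_domains:
        sizes[group] = sizes.get(group, 0) + 1
        for pos, res in dom.residues.items():
            key = (group, pos)
            occupancy[key] = occupancy.get(key, 0) + 1
            counts.setdefault(key, Counter())[res] += 1
    return ConservationTable(counts=counts, group_sizes=sizes, occupancy=occupancy)


def find_universal_residues(
    table: ConservationTable,
    min_conservation: float = 100.0,
    groups: list[str] | None = None,
) -> dict:
    """Positions where a single residue is conserved in every group."""
    groups = groups if groups is not None else table.groups
    if not groups:
        return {}
    out: dict = {}
    for pos in range(FIRST_POSITION, LAST_POSITION + 1):
        freqs = [table.freq(g, pos) for g in groups]
        if any(not f for f in freqs):
            continue
        residues = set().union(*[set(f) for f in freqs])
        qualifying = [
            r for r in sorted(residues)
            if all(f.get(r, 0.0) * 100 >= min_conservation for f in freqs)
        ]
        if qualifying:
            out[pos] = max(qualifying, key=lambda r: (min(f.get(r, 0.0) for f in freqs), r))
    return out


def find_group_markers(
    table: ConservationTable,
    within_min: float = 90.0,
    outside_max: float = 10.0,
    max_shared_groups: int = 3,
    report_min: float = 5.0,
) -> MarkerTable:
    """Discover group-diagnostic residues (see module docstring)."""
    groups = table.groups
    order = {g: i for i, g in enumerate(["AP2", *ERF_GROUPS, "RAV"])}
    entries: list[MarkerEntry] = []

    for pos in range(FIRST_POSITION, LAST_POSITION + 1):
        modal = {g: table.modal(g, pos) for g in groups}
        present = [m for m in modal.values() if m is not None]
        if not present:
            continue
        background = Counter(present).most_common()
        top = background[0][1]
        b = sorted(m for m, c in background if c == top)[0]
        conforming = [g for g in groups if modal[g] == b]
        if len(groups) > 1 and not conforming:
            continue
        for g in groups:
            freqs = table.freq(g, pos)
            if not freqs:
                continue
            deviating = {r: f for r, f in freqs.items() if r != b}
            if len(groups) == 1:
                deviating = dict(freqs)  # exclusivity vacuous for one group
            if sum(deviating.values()) * 100 < within_min:
                continue
            if len(groups) > 1 and modal[g] == b:
                continue
            for r in sorted(deviating, key=lambda x: -deviating[x]):
                pct = deviating[r] * 100
                if pct < report_min:
                    continue
                sharing = sum(1 for g2 in groups if modal[g2] == r)
                if sharing > max_shared_groups:
                    continue
                if any(
                    table.freq(g2, pos).get(r, 0.0) * 100 > outside_max
                    for g2 in conforming
                    if g2 != g
                ):
                    continue
                entries.append(MarkerEntry(g, pos, r, round(pct, 1)))

    # +X167 rule: the group-IX insertion slot, reported by occupancy.
    for g in groups:
        occ = table.insertion_occupancy(g) * 100
        if occ >= within_min and all(
            table.insertion_occupancy(g2) * 100 <= outside_max for g2 in groups if g2 != g
        ):
            entries.append(MarkerEntry(g, INSERTION_KEY, "X", round(occ, 1)))

    entries.sort(
        key=lambda e: (order.get(e.group, 99), _POSITION_ORDER.index(e.position), -e.conservation_pct)
    )
    return MarkerTable(entries=entries)


def subfamily_call(domain) -> str:
    """DREB/ERF subfamily from the position 158/163 diagnostics."""
    r158 = domain.residues.get(158)
    r163 = domain.residues.get(163)
    if r158 == DREB_DIAGNOSTIC[158] and r163 == DREB_DIAGNOSTIC[163]:
        return "DREB"
    if r158 == ERF_DIAGNOSTIC[158] and r163 == ERF_DIAGNOSTIC[163]:
        return "ERF"
    return "UNRESOLVED"


def scan_motifs(peptide: str, gene_id: str = "peptide") -> MotifReport:
    """Literal scans for YRG/WLG/RAYD/KREYD and the EAR repression motif."""
    positions: dict = {}
    for motif in MOTIFS:
        idx = peptide.find(motif)
        positions[motif] = idx if idx >= 0 else None
    m = re.search(EAR_PATTERN, peptide)
    positions["EAR"] = m.start() if m else None
    return MotifReport(gene_id=gene_id, positions=positions)


def map_nomenclature(family: str, group: str | None = None) -> tuple[str, str]:
    """Nakano family/group -> Sakuma subfamily and subgroup band."""
    family = family.upper()
    if family in {"AP2", "RAV", "SOLOIST"}:
        return (family, "-")
    if family == "ERF":
        if group not in SAKUMA_BANDS:
            raise InputError(f"unknown ERF group: {group!r}")
        return SAKUMA_BANDS[group]
    raise InputError(f"unknown family: {family!r}")


def is_dreb_group(group: str) -> bool:
    return group in DREB_GROUPS
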