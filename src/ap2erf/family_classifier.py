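"""Domain-architecture rules for AP2/ERF family assignment.

Two AP2 domains make an AP2-family gene; one AP2 plus one B3 a RAV; a
short AP2 domain (several internal deletions, including R152) a soloist;
a single full or partial AP2 domain an ERF — unless a homology override
(nearest reference is an AP2-family repeat) reassigns it to the AP2
family, the route the ten single-domain AP2 members take.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import INSERTION_KEY
from .domain_scan import DomainHit
from .errors import InputError
from .phylo_group import GroupAssignment, NumberedDomain

FAMILIES = ["AP2", "ERF", "RAV", "SOLOIST"]

# Table-style completeness rows per family
_COMPLETENESS_ROWS = {
    "AP2": ["two-full", "full+partial", "two-partial", "one-full", "one-partial"],
    "ERF": ["full", "partial"],
    "RAV": ["full"],
    "SOLOIST": ["short"],
}


@dataclass
class FamilyCall:
    """Family assignment for one gene with its domain evidence."""

    gene_id: str
    family: str
    evidence: list = field(default_factory=list)       # DomainHit refs
    completeness_summary: str = ""
    homology_override: bool = False
    name: str = ""

    @property
    def has_full_domain(self) -> bool:
        """Complete domain evidence; the soloists' short-but-complete
        domain (spanning both model ends) counts."""
        ap2 = [h for h in self.evidence if h.kind == "AP2"]
        if self.family == "SOLOIST":
            return any(h.completeness == "short" for h in ap2)
        return any(h.completeness == "full" for h in ap2)


def _summary(ap2_hits: list[DomainHit]) -> str:
    classes = [h.completeness for h in ap2_hits]
    if len(classes) >= 2:
        n_full = sum(c == "full" for c in classes)
        if n_full >= 2:
            return "two-full"
        return "full+partial" if n_full == 1 else "two-partial"
    if classes == ["short"]:
        return "short"
    if classes == ["full"]:
        return "one-full"
    if len(classes) == 1:
        return "one-partial"
    return ""


def classify_family(
    hits: list[DomainHit],
    homology_hint: str | None = None,
    gene_id: str | None = None,
) -> FamilyCall:
    """Apply the domain-architecture rules to one gene's hits."""
    sources = {h.peptide.transcript_id for h in hits if h.peptide is not None}
    if len(sources) > 1:
        raise InputError(f"hits span multiple genes: {sorted(sources)}")
    if gene_id is None:
        gene_id = next(iter(sources), "gene")

    ap2 = sorted(
        (h for h in hits if h.kind == "AP2"), key=lambda h: h.pep_interval
    )
    b3 = [h for h in hits if h.kind == "B3"]

    if not ap2:
        return FamilyCall(gene_id=gene_id, family="UNCLASSIFIED", evidence=list(hits))
    if len(ap2) == 1 and b3:
        return FamilyCall(gene_id, "RAV", ap2 + b3, "full" if ap2[0].completeness == "full" else ap2[0].completeness)
    if len(ap2) == 1 and ap2[0].completeness == "short":
        return FamilyCall(gene_id, "SOLOIST", ap2, "short")
    if len(ap2) >= 2:
        return FamilyCall(gene_id, "AP2", ap2, _summary(ap2))
    if homology_hint == "AP2":
        return FamilyCall(gene_id, "AP2", ap2, _summary(ap2), homology_override=True)
    return FamilyCall(gene_id, "ERF", ap2, _summary(ap2))


def nearest_family_hint(
    domain: NumberedDomain | dict,
    references: list[NumberedDomain],
) -> str:
    """Homology override hint: nearest reference by p-distance over shared
    anchored positions, AP2-family repeats versus ERF-group references.
    Ties resolve to ERF (the override must be positive evidence)."""
    residues = domain.residues if isinstance(domain, NumberedDomain) else domain

    def _best(refs):
        best = None
        for ref in refs:
            shared = [p for p in residues if p != INSERTION_KEY and p in ref.residues]
            if not shared:
                continue
            d = sum(residues[p] != ref.residues[p] for p in shared) / len(shared)
            best = d if best is None or d < best else best
        return best

    d_ap2 = _best([r for r in references if r.group == "AP2"])
    d_erf = _best([r for r in references if r.group not in ("AP2", "RAV")])
    if d_ap2 is None or d_erf is None:
        return "ERF"
    return "AP2" if d_ap2 < d_erf else "ERF"


def assign_names(
    calls: list[FamilyCall],
    groups: dict[str, GroupAssignment] | None = None,
) -> list[FamilyCall]:
    """Stable gene names: Hb<family>-<n>, HbSoloist<n>, and
    HbERF-<group><subgroup><n> with numbering per group/subgroup in input
    order."""
    groups = groups or {}
    counters: dict[tuple, int] = {}

    def _next(key) -> int:
        counters[key] = counters.get(key, 0) + 1
        return counters[key]

    for call in calls:
        if call.family == "ERF":
            ga = groups.get(call.gene_id)
            if ga is not None and ga.group:
                key = ("ERF", ga.group, ga.subgroup)
                call.name = f"HbERF-{ga.group}{ga.subgroup}{_next(key)}"
            else:
                call.name = f"HbERF-{_next(('ERF', '?', ''))}"
        elif call.family == "AP2":
            call.name = f"HbAP2-{_next(('AP2',))}"
        elif call.family == "RAV":
            call.name = f"HbRAV-{_next(('RAV',))}"
        elif call.family == "SOLOIST":
            call.name = f"HbSoloist{_next(('SOLOIST',))}"
        else:
            call.name = ""
    return calls


def tabulate_families(calls: list[FamilyCall]) -> pd.DataFrame:
    """Family x completeness summary with totals (Table 3 layout)."""
    rows = []
    for family in FAMILIES:
        fam_calls = [c for c in calls if c.family == family]
        for comp in _COMPLETENESS_ROWS[family]:
            rows.append({"family": family, "completeness": comp,
                         "count": sum(c.completeness_summary == comp for c in fam_calls)})
        rows.append({"family": family, "completeness": "total", "count": len(fam_calls)})
    n_uncl = sum(c.family == "UNCLASSIFIED" for c in calls)
    if n_uncl:
        rows.append({"family": "UNCLASSIFIED", "completeness": "total", "count": n_uncl})
    rows.append({"family": "TOTAL", "completeness": "", "count": len(calls)})
    return pd.DataFrame(rows, columns=["family", "completeness", "count"])


def count_full_domain(calls: list[FamilyCall]) -> int:
    """Genes with complete domain evidence (the complete-domain scope
    used for group inventories and subfamily banding)."""
    return sum(c.has_full_domain for c in calls if c.family in FAMILIES)
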