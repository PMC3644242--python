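"""Labelled synthetic cohorts for the AP2/ERF analysis pipeline.

The generator emulates the structure the analysis assumes in a real
transcriptome: genes of four families (AP2 with two AP2 domains, ERF with
one, RAV with one AP2 plus one B3, soloists with a short AP2 domain
missing six residues including R152), group-diagnostic residues and the
group-IX insertion planted in the domains, per-tissue multinomial read
counts, and miRNA binding sites of the cleavage and translation type.

Default counts follow the published Hevea inventory: 25 AP2 (9 two-full,
4 full+partial, 2 two-partial, 7 one-full, 3 one-partial), 141 ERF (115
full split 12/7/11/3/5/5/23/15/19/9/6 over groups I..X and VI-L, plus 26
partial), 4 RAV and 3 soloists — 173 genes, 142 with a complete domain.

Every draw flows from one seeded generator, so a fixed seed and config
reproduce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio.Data.CodonTable import standard_dna_table

from .constants import (
    AMINO_ACIDS,
    AP2_SIGNATURE,
    AP2_SIGNATURE_RATE,
    B3_SCAFFOLD,
    DEFAULT_TISSUE_WEIGHTS,
    DREB_DIAGNOSTIC,
    DREB_GROUPS,
    ERF_GROUPS,
    FIRST_POSITION,
    GROUP_MARKERS,
    GROUP_SUBGROUPS,
    INSERTION_KEY,
    LAST_POSITION,
    SOLOIST_DELETION,
    VARIABLE_POSITIONS,
    VI_L_FROZEN,
    alternative_residue,
    scaffold_residue,
)
from .domain_scan import reverse_complement
from .errors import ConfigurationError, InputError
from .phylo_group import NumberedDomain

_CODON_OPTIONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODON_OPTIONS.setdefault(_aa, []).append(_codon)

_DEFAULT_ERF_GROUP_COUNTS = {
    "I": 12, "II": 7, "III": 11, "IV": 3, "V": 5, "VI": 5,
    "VII": 23, "VIII": 15, "IX": 19, "X": 9, "VI-L": 6,
}

_PAIR_PARTNERS = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}

MIRNA_REGIONS = ["5'UTR", "CDS-before-AP2", "CDS-inside-AP2", "CDS-after-AP2", "3'UTR"]


@dataclass
class CohortConfig:
    """Cohort composition and sequence-length parameters."""

    ap2_two_full: int = 9
    ap2_full_partial: int = 4
    ap2_two_partial: int = 2
    ap2_one_full: int = 7
    ap2_one_partial: int = 3
    erf_group_counts: dict = field(default_factory=lambda: dict(_DEFAULT_ERF_GROUP_COUNTS))
    erf_partial: int = 26
    rav: int = 4
    soloist: int = 3
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_WEIGHTS))
    seed: int = 1
    utr_len_range: tuple = (50, 300)      # nt
    cds_pad_range: tuple = (75, 240)      # nt of coding sequence per flank
    minor_q: float = 0.05                 # per-position background drift rate

    def validate(self) -> None:
        for name in (
            "ap2_two_full", "ap2_full_partial", "ap2_two_partial", "ap2_one_full",
            "ap2_one_partial", "erf_partial", "rav", "soloist",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for g, c in self.erf_group_counts.items():
            if g not in ERF_GROUPS:
                raise ConfigurationError(f"erf_group_counts: unknown group {g!r}")
            if c < 0:
                raise ConfigurationError(f"erf_group_counts[{g}] must be >= 0")
        total_w = sum(self.tissues.values())
        if self.tissues and abs(total_w - 1.0) > 1e-9:
            raise ConfigurationError(f"tissues: weights sum to {total_w}, expected 1")
        if any(w < 0 for w in self.tissues.values()):
            raise ConfigurationError("tissues: weights must be >= 0")
        if not 0 <= self.minor_q < 0.5:
            raise ConfigurationError("minor_q must be in [0, 0.5)")

    @property
    def n_ap2(self) -> int:
        return (self.ap2_two_full + self.ap2_full_partial + self.ap2_two_partial
                + self.ap2_one_full + self.ap2_one_partial)

    @property
    def n_erf_full(self) -> int:
        return sum(self.erf_group_counts.values())

    @property
    def n_erf(self) -> int:
        return self.n_erf_full + self.erf_partial

    @property
    def n_total(self) -> int:
        return self.n_ap2 + self.n_erf + self.rav + self.soloist

    def to_yaml(self, path) -> None:
        data = {
            k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("utr_len_range", "cds_pad_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class TranscriptContig:
    """A nucleotide transcript with optional CDS interval."""

    id: str
    sequence: str
    cds_interval: tuple | None = None
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TruthDomain:
    kind: str                       # AP2 | B3
    completeness: str               # full | partial_N | partial_C | short
    residues: dict                  # structural position -> residue (AP2 only)
    aa_seq: str
    nt_interval: tuple              # 0-based half-open, forward strand
    has_insertion: bool = False


@dataclass
class TruthRecord:
    """Ground truth for one synthetic gene."""

    gene_id: str
    family: str
    group: str | None
    subgroup: str
    domains: list
    marker_positions: dict
    cds_interval: tuple | None
    strand: str
    transcript_length: int
    tissue_counts: dict = field(default_factory=dict)
    mirna_sites: list = field(default_factory=list)

    @property
    def has_full_domain(self) -> bool:
        """Complete domain evidence: a full AP2 domain, or the soloists'
        complete-but-short architecture."""
        if self.family == "SOLOIST":
            return any(d.completeness == "short" for d in self.domains)
        return any(d.kind == "AP2" and d.completeness == "full" for d in self.domains)

    @property
    def completeness_summary(self) -> str:
        ap2 = [d.completeness for d in self.domains if d.kind == "AP2"]
        if len(ap2) == 2:
            if all(c == "full" for c in ap2):
                return "two-full"
            if "full" in ap2:
                return "full+partial"
            return "two-partial"
        if ap2 == ["short"]:
            return "short"
        if ap2 == ["full"]:
            return "one-full"
        return "one-partial"


@dataclass
class PlantedSite:
    """A planted miRNA binding site (ground truth)."""

    mirna_id: str
    gene_id: str
    interval: tuple                 # 0-based half-open on the transcript
    mode: str                       # cleavage | translation
    region: str
    penalty: float
    skipped: bool = False


# ---------------------------------------------------------------------------
# domain construction


def _domain_residues(
    rng: np.random.Generator,
    family: str,
    group: str | None,
    minor_q: float,
    ap2_150: str = "T",
    ap2_sig_positions=None,
) -> dict:
    """Residues of one planted domain at structural positions.

    ``ap2_sig_positions``: positions of the AP2-family signature to carry;
    None draws each at the signature rate.
    """
    res = {p: scaffold_residue(p) for p in range(FIRST_POSITION, LAST_POSITION + 1)}
    if family == "ERF":
        if group in DREB_GROUPS:
            res.update(DREB_DIAGNOSTIC)
        for pos, r in GROUP_MARKERS.get(group, []):
            if pos != INSERTION_KEY:
                res[pos] = r
        if group == "IX":
            res[INSERTION_KEY] = "STNG"[rng.integers(4)]
    elif family == "AP2":
        res[150] = ap2_150
        if ap2_sig_positions is None:
            ap2_sig_positions = [p for p in AP2_SIGNATURE if rng.random() < AP2_SIGNATURE_RATE]
        for p in ap2_sig_positions:
            res[p] = AP2_SIGNATURE[p]
    elif family == "RAV":
        res[150] = "V"
    elif family == "SOLOIST":
        for p in SOLOIST_DELETION:
            del res[p]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown family {family!r}")

    frozen = VI_L_FROZEN if group == "VI-L" else ()
    for p in VARIABLE_POSITIONS:
        if p in res and p not in frozen and rng.random() < minor_q:
            res[p] = alternative_residue(p)
    return res


def _residues_seq(res: dict) -> str:
    parts = []
    for p in range(FIRST_POSITION, LAST_POSITION + 1):
        if p in res:
            parts.append(res[p])
        if p == 167 and INSERTION_KEY in res:
            parts.append(res[INSERTION_KEY])
    return "".join(parts)


def _rand_aa(rng, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, int(n)))


def _rand_nt(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, int(n)))


def _encode(rng, aa_seq: str) -> str:
    out = []
    for aa in aa_seq:
        opts = _CODON_OPTIONS[aa]
        out.append(opts[rng.integers(len(opts))])
    return "".join(out)


def build_reference_panel(
    seed: int = 0,
    n_per_group: int = 5,
    n_ap2: int = 12,
    n_rav: int = 4,
    minor_q: float = 0.02,
) -> list[NumberedDomain]:
    """Labelled reference domains: 5 per ERF group (55, the representative
    set), 12 AP2-family repeats (11 T150 + 1 A150) and 4 RAV domains.

    Each variable position is additionally forced to its minor residue in
    exactly one non-VI-L ERF reference, so that a position is universally
    conserved across groups only where the scaffold makes it so.
    """
    rng = np.random.default_rng(seed)
    panel: list[NumberedDomain] = []
    for g in ERF_GROUPS:
        letters = GROUP_SUBGROUPS[g]
        for k in range(n_per_group):
            res = _domain_residues(rng, "ERF", g, minor_q)
            panel.append(
                NumberedDomain(
                    gene_id=f"ref_{g}_{k + 1}", residues=res, group=g,
                    subgroup=letters[k % len(letters)],
                )
            )
    sig_list = sorted(AP2_SIGNATURE)
    for k in range(n_ap2):
        # deterministic 10-of-12 carriers per signature position keeps the
        # signature below the marker-discovery conservation threshold
        carried = [
            p for i, p in enumerate(sig_list)
            if k not in ((i % n_ap2), ((i + 1) % n_ap2))
        ]
        res = _domain_residues(
            rng, "AP2", None, minor_q,
            ap2_150=("A" if k == n_ap2 - 1 else "T"),
            ap2_sig_positions=carried,
        )
        panel.append(NumberedDomain(gene_id=f"ref_AP2_{k + 1}", residues=res, group="AP2"))
    for k in range(n_rav):
        res = _domain_residues(rng, "RAV", None, minor_q)
        panel.append(NumberedDomain(gene_id=f"ref_RAV_{k + 1}", residues=res, group="RAV"))

    holders = [d for d in panel if d.group in ERF_GROUPS and d.group != "VI-L"]
    if holders:
        for k, pos in enumerate(VARIABLE_POSITIONS):
            holders[k % len(holders)].residues[pos] = alternative_residue(pos)
    return panel


# ---------------------------------------------------------------------------
# cohort generation


def _truncate(rng, res: dict, how: str, keep_range=(20, 46)) -> dict:
    positions = [p for p in range(FIRST_POSITION, LAST_POSITION + 1) if p in res]
    keep = int(rng.integers(*keep_range))
    keep = min(keep, len(positions) - 1)
    kept = positions[-keep:] if how == "partial_N" else positions[:keep]
    out = {p: res[p] for p in kept}
    if INSERTION_KEY in res and 167 in out and 168 in out:
        out[INSERTION_KEY] = res[INSERTION_KEY]
    return out


def _build_gene(rng, gene_id, family, group, subgroup, plan, config, coverage, ap2_150, flip):
    """Assemble one transcript and its truth record.

    ``plan`` is a list of (kind, completeness) for the gene's domains in
    N->C order.  Partial domains are truncated at the matching transcript
    end (no UTR, no start/stop on that side).
    """
    n_trunc = plan[0][1] == "partial_N"
    c_trunc = plan[-1][1] == "partial_C"
    pad_lo, pad_hi = (max(1, config.cds_pad_range[0] // 3), max(2, config.cds_pad_range[1] // 3))

    domains: list[TruthDomain] = []
    segments: list[str] = []
    aa_offsets: list[tuple[int, int, int]] = []  # (domain index, aa start, aa end)
    cursor = 0

    if not n_trunc:
        npad = "M" + _rand_aa(rng, rng.integers(pad_lo, pad_hi))
        segments.append(npad)
        cursor += len(npad)

    for d_idx, (kind, completeness) in enumerate(plan):
        if d_idx > 0:
            linker = _rand_aa(rng, rng.integers(25, 41))
            segments.append(linker)
            cursor += len(linker)
        if kind == "AP2":
            res = _domain_residues(rng, family, group, config.minor_q, ap2_150=ap2_150)
            for p in coverage:
                if p in res:
                    res[p] = alternative_residue(p)
            if completeness in ("partial_N", "partial_C"):
                keep_range = (28, 46) if family == "AP2" else (20, 46)
                res = _truncate(rng, res, completeness, keep_range)
            aa = _residues_seq(res)
        else:  # B3
            b3 = list(B3_SCAFFOLD)
            for p in range(len(b3)):
                if rng.random() < config.minor_q:
                    b3[p] = AMINO_ACIDS[rng.integers(20)]
            res, aa = {}, "".join(b3)
        segments.append(aa)
        aa_offsets.append((d_idx, cursor, cursor + len(aa)))
        cursor += len(aa)
        domains.append(
            TruthDomain(
                kind=kind, completeness=completeness, residues=res, aa_seq=aa,
                nt_interval=(0, 0), has_insertion=INSERTION_KEY in res,
            )
        )

    if not c_trunc:
        segments.append(_rand_aa(rng, rng.integers(pad_lo, pad_hi)))

    peptide = "".join(segments)
    cds_nt = _encode(rng, peptide) + ("TAA" if not c_trunc else "")
    utr5 = _rand_nt(rng, rng.integers(*config.utr_len_range)) if not n_trunc else ""
    utr3 = _rand_nt(rng, rng.integers(*config.utr_len_range)) if not c_trunc else ""
    transcript = utr5 + cds_nt + utr3
    L = len(transcript)
    cds = (len(utr5), len(utr5) + len(cds_nt))
    for d_idx, a0, a1 in aa_offsets:
        domains[d_idx].nt_interval = (len(utr5) + 3 * a0, len(utr5) + 3 * a1)

    strand = "+"
    if flip:
        strand = "-"
        transcript = reverse_complement(transcript)
        cds = (L - cds[1], L - cds[0])
        for d in domains:
            s, e = d.nt_interval
            d.nt_interval = (L - e, L - s)

    markers = {
        pos: r for pos, r in GROUP_MARKERS.get(group if family == "ERF" else family, [])
        if pos != INSERTION_KEY
    }
    contig = TranscriptContig(
        id=gene_id, sequence=transcript, cds_interval=cds,
        description=f"{family}" + (f" group {group}" if group else ""),
    )
    truth = TruthRecord(
        gene_id=gene_id, family=family, group=group, subgroup=subgroup,
        domains=domains, marker_positions=markers, cds_interval=cds,
        strand=strand, transcript_length=L,
    )
    return contig, truth


def generate_cohort(config: CohortConfig) -> tuple[list[TranscriptContig], list[TruthRecord]]:
    """Generate the synthetic cohort (deterministic for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    plans: list[tuple[str, str, str | None, str, list]] = []  # (id, family, group, subgroup, plan)
    ap2_specs = (
        [("full", "full")] * config.ap2_two_full
        + [("full", "partial_C")] * config.ap2_full_partial
        + [("partial_N", "partial_C")] * config.ap2_two_partial
        + [("full",)] * config.ap2_one_full
        + [("partial_C",)] * config.ap2_one_partial
    )
    for k, spec in enumerate(ap2_specs):
        plans.append(
            (f"synth_AP2_{k + 1:03d}", "AP2", None, "",
             [("AP2", c) for c in spec])
        )
    erf_idx = 0
    full_erf_ids: list[str] = []
    for g in ERF_GROUPS:
        letters = GROUP_SUBGROUPS[g]
        for k in range(config.erf_group_counts.get(g, 0)):
            erf_idx += 1
            gid = f"synth_ERF_{erf_idx:03d}"
            plans.append((gid, "ERF", g, letters[k % len(letters)], [("AP2", "full")]))
            if g != "VI-L":
                full_erf_ids.append(gid)
    partial_groups = (ERF_GROUPS * ((config.erf_partial // len(ERF_GROUPS)) + 1))[: config.erf_partial]
    for k, g in enumerate(partial_groups):
        erf_idx += 1
        side = "partial_N" if k % 2 == 0 else "partial_C"
        plans.append(
            (f"synth_ERF_{erf_idx:03d}", "ERF", g, GROUP_SUBGROUPS[g][0], [("AP2", side)])
        )
    for k in range(config.rav):
        plans.append((f"synth_RAV_{k + 1:03d}", "RAV", None, "",
                      [("AP2", "full"), ("B3", "full")]))
    for k in range(config.soloist):
        plans.append((f"synth_Soloist_{k + 1:03d}", "SOLOIST", None, "", [("AP2", "short")]))

    # each variable position is forced to its minor residue in one
    # full-domain non-VI-L ERF gene, mirroring natural background drift
    coverage: dict[str, set] = {gid: set() for gid, *_ in plans}
    if full_erf_ids:
        for k, pos in enumerate(VARIABLE_POSITIONS):
            coverage[full_erf_ids[k % len(full_erf_ids)]].add(pos)

    contigs: list[TranscriptContig] = []
    truths: list[TruthRecord] = []
    n_ap2_seen = 0
    for idx, (gid, family, group, subgroup, plan) in enumerate(plans):
        ap2_150 = "T"
        if family == "AP2":
            ap2_150 = "A" if n_ap2_seen % 12 == 11 else "T"
            n_ap2_seen += 1
        contig, truth = _build_gene(
            rng, gid, family, group, subgroup, plan, config,
            coverage[gid], ap2_150, flip=(idx % 3 == 2),
        )
        contigs.append(contig)
        truths.append(truth)
    return contigs, truths


# ---------------------------------------------------------------------------
# read membership


def generate_read_membership(
    truths: list[TruthRecord],
    total_reads: int,
    seed: int,
    tissues: dict | None = None,
):
    """Allocate reads multinomially over genes x tissue libraries.

    Returns a long-format pandas DataFrame (contig_id, library,
    read_count) and fills each truth record's ``tissue_counts``.
    """
    import pandas as pd

    if total_reads < 0:
        raise ConfigurationError("total_reads must be >= 0")
    tissues = dict(tissues if tissues is not None else DEFAULT_TISSUE_WEIGHTS)
    if abs(sum(tissues.values()) - 1.0) > 1e-9:
        raise ConfigurationError("tissue weights must sum to 1")
    for t in truths:
        unknown = set(t.tissue_counts) - set(tissues)
        if unknown:
            raise InputError(f"{t.gene_id}: unknown tissue label {sorted(unknown)}")

    libs = list(tissues)
    rows = []
    if truths:
        rng = np.random.default_rng(seed)
        w = rng.lognormal(0.0, 1.0, len(truths))
        w = w / w.sum()
        shares = np.array([tissues[lib] for lib in libs])
        probs = np.outer(w, shares).ravel()
        counts = rng.multinomial(int(total_reads), probs).reshape(len(truths), len(libs))
        for gi, t in enumerate(truths):
            t.tissue_counts = {lib: int(counts[gi, li]) for li, lib in enumerate(libs)}
            for li, lib in enumerate(libs):
                rows.append({"contig_id": t.gene_id, "library": lib,
                             "read_count": int(counts[gi, li])})
    return pd.DataFrame(rows, columns=["contig_id", "library", "read_count"])


# ---------------------------------------------------------------------------
# miRNA site planting


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_rna(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(seq))


def _non_pairing_base(target_base: str) -> str:
    for b in "ACGU":
        if b not in _PAIR_PARTNERS[target_base]:
            return b
    raise RuntimeError  # pragma: no cover


def _segments(truth: TruthRecord) -> dict:
    """Plantable region windows, in transcript coordinates.

    Region labels are relative to the first AP2 domain; the CDS-after
    window starts after the *last* AP2 domain so that windows never fall
    inside the paralogous second repeat of AP2-family genes.
    """
    doms = [d for d in truth.domains if d.kind == "AP2"]
    cds = truth.cds_interval
    if not doms or cds is None:
        return {}
    d0, d1 = doms[0].nt_interval
    last_end = max(d.nt_interval[1] for d in doms)
    return {
        "5'UTR": (0, cds[0]),
        "CDS-before-AP2": (cds[0], d0),
        "CDS-inside-AP2": (d0, d1),
        "CDS-after-AP2": (last_end, cds[1]),
        "3'UTR": (cds[1], truth.transcript_length),
    }


def generate_mirna_pairs(
    contigs: list[TranscriptContig],
    truths: list[TruthRecord],
    n_sites: int = 24,
    seed: int = 0,
    site_length: int = 21,
    energy_cutoff: float = -20.0,
):
    """Plant miRNA binding sites and emit the matching miRNA sequences.

    Even-indexed sites are cleavage-type (Watson-Crick pairing across
    miRNA positions 9-11; every fourth site a perfect complement),
    odd-indexed sites are translation-type (a non-pairing base opposite
    miRNA position 9).  All planted sites satisfy the default scanner
    thresholds; windows whose duplex energy would miss the cutoff are
    re-drawn, and impossible placements are skipped with a warning.
    """
    from .mirna_target import duplex_energy

    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in contigs}
    eligible = [
        t for t in truths
        if t.strand == "+" and t.cds_interval is not None and _segments(t)
    ]
    mirnas: list[tuple[str, str]] = []
    sites: list[PlantedSite] = []
    if n_sites == 0 or not eligible:
        if n_sites > 0:
            warnings.warn("no eligible transcripts for miRNA site planting", stacklevel=2)
        return mirnas, sites

    m = site_length
    for i in range(n_sites):
        mode = "cleavage" if i % 2 == 0 else "translation"
        region = MIRNA_REGIONS[i % len(MIRNA_REGIONS)]
        mir_id = f"synthmir{i + 1:02d}"
        planted = False
        for attempt in range(30):
            truth = eligible[(i + attempt) % len(eligible)]
            seg = _segments(truth).get(region)
            if region == "CDS-inside-AP2":
                # straddle the domain start: midpoint lands just inside the
                # conserved domain while half the window covers the unique
                # flank, keeping the planted miRNA gene-specific
                if seg is None:
                    continue
                start = seg[0] - (m - 1) // 2
                cds0 = truth.cds_interval[0]
                if start < max(0, cds0) or seg[0] + (m - (m - 1) // 2) > seg[1]:
                    continue
            else:
                if seg is None or seg[1] - seg[0] < m + 2:
                    continue
                start = int(rng.integers(seg[0], seg[1] - m + 1))
            target = _rna(by_id[truth.gene_id].sequence[start : start + m])
            mir = list(_revcomp_rna(target))
            penalty = 0.0
            if mode == "translation":
                mir[8] = _non_pairing_base(target[m - 9])
                penalty += 1.0
            elif i % 4 != 0:
                mir[14] = _non_pairing_base(target[m - 15])
                penalty += 1.0
            mir_seq = "".join(mir)
            if duplex_energy(mir_seq, target) > energy_cutoff:
                continue
            mirnas.append((mir_id, mir_seq))
            site = PlantedSite(
                mirna_id=mir_id, gene_id=truth.gene_id,
                interval=(start, start + m), mode=mode, region=region, penalty=penalty,
            )
            sites.append(site)
            truth.mirna_sites.append(site)
            planted = True
            break
        if not planted:
            warnings.warn(f"could not place site {mir_id} in region {region}", stacklevel=2)
            sites.append(
                PlantedSite(mirna_id=mir_id, gene_id="", interval=(0, 0),
                            mode=mode, region=region, penalty=float("nan"), skipped=True)
            )
    return mirnas, sites


# ---------------------------------------------------------------------------
# raw-read emulation (for the length/complexity prefilter stage)


def generate_raw_reads(
    contigs: list[TranscriptContig],
    n_reads: int = 200,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Small synthetic read set: transcript fragments plus planted short
    and low-complexity reads (exercises the cleaning prefilter)."""
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    pool = [c for c in contigs if len(c.sequence) >= 150]
    if not pool:
        return reads
    for k in range(n_reads):
        rid = f"read_{k + 1:04d}"
        if k % 10 == 8:
            reads.append((rid, _rand_nt(rng, int(rng.integers(60, 119)))))
        elif k % 10 == 9:
            reads.append((rid, "A" * int(rng.integers(150, 250))))
        else:
            c = pool[int(rng.integers(len(pool)))]
            n = int(rng.integers(120, min(401, len(c.sequence) + 1)))
            s = int(rng.integers(0, len(c.sequence) - n + 1))
            reads.append((rid, c.sequence[s : s + n]))
    return reads
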