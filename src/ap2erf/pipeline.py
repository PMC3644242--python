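"""End-to-end orchestration: simulate -> scan -> classify -> group ->
markers -> tissues -> miRNA, with a reproducible run manifest.

`analyze_cohort` runs every stage in memory and returns a result object;
`run_all` wraps it with deterministic text outputs per stage.  Re-running
`run_all` over an existing output directory rewrites only stages whose
outputs are missing (and their descendants), so deleting one stage's
files regenerates that stage onward; all outputs are byte-identical for
a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import sys
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .constants import DREB_GROUPS, ERF_GROUPS, INSERTION_KEY
from .domain_scan import (
    DomainHit,
    default_ap2_model,
    default_b3_model,
    scan_ap2,
    detect_b3,
    six_frame_translate,
)
from .errors import InputError
from .family_classifier import (
    FamilyCall,
    assign_names,
    classify_family,
    count_full_domain,
    nearest_family_hint,
    tabulate_families,
)
from .mirna_target import TargetScanParams, scan_targets
from .phylo_group import (
    GroupAssignment,
    NumberedDomain,
    extract_block,
    nearest_reference,
    nj_tree,
    pdistance_matrix,
)
from .residue_markers import (
    column_conservation,
    find_group_markers,
    find_universal_residues,
    scan_motifs,
)
from .synthetic_data import (
    CohortConfig,
    build_reference_panel,
    generate_cohort,
    generate_mirna_pairs,
    generate_raw_reads,
    generate_read_membership,
)
from .tissue_expression import aggregate_by_group, count_reads, tissue_percentages

DEFAULT_TOTAL_READS = 6318   # read total over all AP2/ERF contigs


def _log(stage: str, message: str) -> None:
    print(f"[ap2erf:{stage}] {message}", file=sys.stderr)


# ---------------------------------------------------------------------------
# read prefilter


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping dinucleotide distribution."""
    s = seq.upper()
    if len(s) < 2:
        return 0.0
    counts = Counter(s[i : i + 2] for i in range(len(s) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def filter_reads(records, min_len: int = 120, entropy_floor: float = 1.0):
    """Length and low-complexity prefilter for raw reads.

    ``records`` is an iterable of (id, sequence) pairs, Biopython
    SeqRecords, or a FASTA/FASTQ path.  Returns (kept, report) where
    ``report`` is a DataFrame with one row per read and the discard
    reason (``short`` below ``min_len``, ``low_complexity`` below the
    dinucleotide-entropy floor in bits).
    """
    if isinstance(records, (str, Path)):
        path = Path(records)
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
        records = list(SeqIO.parse(str(path), fmt))
    kept: list[tuple[str, str]] = []
    rows = []
    for idx, rec in enumerate(records):
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            try:
                rid, seq = rec
            except (TypeError, ValueError) as exc:
                raise InputError(f"malformed read record at index {idx}") from exc
        ent = dinucleotide_entropy(seq)
        if len(seq) < min_len:
            status, reason = "discarded", "short"
        elif ent < entropy_floor:
            status, reason = "discarded", "low_complexity"
        else:
            status, reason = "kept", ""
            kept.append((rid, seq))
        rows.append({"read_id": rid, "length": len(seq),
                     "dinucleotide_entropy": round(ent, 4),
                     "status": status, "reason": reason})
    report = pd.DataFrame(rows, columns=["read_id", "length", "dinucleotide_entropy",
                                         "status", "reason"])
    return kept, report


# ---------------------------------------------------------------------------
# in-memory pipeline


@dataclass
class PipelineResult:
    """Everything the pipeline computes on one cohort."""

    config: CohortConfig
    seed: int
    contigs: list
    truths: list
    membership: pd.DataFrame
    mirnas: list
    planted_sites: list
    hits_by_gene: dict
    calls: list
    assignments: dict               # gene id -> GroupAssignment (ERF genes)
    tree_newick: str
    marker_table: object
    conservation: object
    motif_reports: dict
    group_table: pd.DataFrame
    tissue_shares: dict
    mirna_hits: list
    table3: pd.DataFrame
    table4: dict
    sakuma: dict

    @property
    def total_classified(self) -> int:
        return sum(c.family != "UNCLASSIFIED" for c in self.calls)

    @property
    def full_domain_count(self) -> int:
        return count_full_domain(self.calls)

    @property
    def full_by_family(self) -> dict:
        out: dict[str, int] = {}
        for c in self.calls:
            if c.family != "UNCLASSIFIED" and c.has_full_domain:
                out[c.family] = out.get(c.family, 0) + 1
        return out


def domain_nt_interval(hit: DomainHit) -> tuple[int, int]:
    """Forward-strand transcript interval of a domain hit."""
    cand = hit.peptide
    ps, pe = hit.pep_interval
    lo, hi = cand.nt_interval
    if cand.strand == "+":
        return (lo + 3 * ps, lo + 3 * pe)
    return (hi - 3 * pe, hi - 3 * ps)


def _best_ap2(hits: list[DomainHit]) -> DomainHit | None:
    ap2 = [h for h in hits if h.kind == "AP2"]
    return max(ap2, key=lambda h: h.score) if ap2 else None


def _display_domain(call: FamilyCall) -> DomainHit | None:
    """Domain used on the general tree: the first (R1) full AP2 repeat,
    falling back to the second repeat when the first is absent."""
    ap2 = [h for h in call.evidence if h.kind == "AP2"]
    if not ap2:
        return None
    full = [h for h in ap2 if h.completeness in ("full", "short")]
    return full[0] if full else ap2[0]


def analyze_cohort(
    config: CohortConfig | None = None,
    seed: int = 1,
    n_mirna_sites: int = 24,
    total_reads: int = DEFAULT_TOTAL_READS,
) -> PipelineResult:
    """Run every pipeline stage on a synthetic cohort."""
    config = dataclasses.replace(config) if config else CohortConfig()
    config.seed = seed
    config.validate()

    _log("simulate", f"generating cohort of {config.n_total} genes (seed {seed})")
    contigs, truths = generate_cohort(config)
    membership = generate_read_membership(
        truths, total_reads=total_reads, seed=seed + 1, tissues=config.tissues
    )
    mirnas, planted = generate_mirna_pairs(contigs, truths, n_mirna_sites, seed=seed + 2)

    panel = build_reference_panel(seed=0)
    ap2_model, b3_model = default_ap2_model(), default_b3_model()

    _log("scan", f"scanning {len(contigs)} contigs in six frames")
    hits_by_gene: dict[str, list[DomainHit]] = {}
    for c in contigs:
        hits: list[DomainHit] = []
        for cand in six_frame_translate(c.id, c.sequence, min_orf_aa=40):
            hits.extend(scan_ap2(cand, ap2_model))
            hits.extend(detect_b3(cand, b3_model))
        hits_by_gene[c.id] = hits

    _log("classify", "applying domain-architecture rules")
    calls: list[FamilyCall] = []
    for c in contigs:
        hits = hits_by_gene[c.id]
        ap2 = [h for h in hits if h.kind == "AP2"]
        hint = None
        if len(ap2) == 1 and not any(h.kind == "B3" for h in hits) \
                and ap2[0].completeness != "short":
            hint = nearest_family_hint(ap2[0].residues, panel)
        calls.append(classify_family(hits, homology_hint=hint, gene_id=c.id))

    _log("group", "assigning ERF groups by NJ placement + residue markers")
    from .phylo_group import assign_groups

    erf_calls = [c for c in calls if c.family == "ERF"]
    full_queries, partial_calls = [], []
    for call in erf_calls:
        hit = _best_ap2(call.evidence)
        dom = NumberedDomain(gene_id=call.gene_id, residues=dict(hit.residues))
        if hit.completeness == "full":
            full_queries.append(dom)
        else:
            partial_calls.append(dom)
    assignments: dict[str, GroupAssignment] = {}
    if full_queries:
        for ga in assign_groups(full_queries, panel):
            assignments[ga.gene_id] = ga
    erf_refs = [r for r in panel if r.group in ERF_GROUPS]
    for dom in partial_calls:
        ref, _d = nearest_reference(dom, erf_refs)
        assignments[dom.gene_id] = GroupAssignment(
            gene_id=dom.gene_id, group=ref.group, subgroup=ref.subgroup,
            method="homology", marker_group=None, tree_group=None,
        )

    assign_names(calls, assignments)

    # general tree over complete-domain genes, for display/output
    tree_newick = ""
    display = []
    for call in calls:
        if call.family in ("AP2", "ERF", "RAV", "SOLOIST") and call.has_full_domain:
            hit = _display_domain(call)
            if hit is not None:
                display.append(NumberedDomain(gene_id=call.gene_id, residues=dict(hit.residues)))
    if len(display) >= 4:
        block = extract_block(display)
        phylo = nj_tree(pdistance_matrix(block), block.gene_ids)
        tree_newick = phylo.to_newick()

    _log("markers", "conservation and group-diagnostic residues on the reference panel")
    conservation = column_conservation((d.group, d) for d in panel)
    marker_table = find_group_markers(conservation)
    marker_table.universal = find_universal_residues(conservation, 100.0, groups=ERF_GROUPS)
    motif_reports = {}
    for call in calls:
        hit = _best_ap2(call.evidence)
        if hit is not None and hit.peptide is not None:
            motif_reports[call.gene_id] = scan_motifs(hit.peptide.seq, gene_id=call.gene_id)

    _log("tissues", "aggregating read counts per group and tissue")
    rm = count_reads(membership, libraries=list(config.tissues))
    erf_group_of = {
        gid: ga.group for gid, ga in assignments.items()
        if ga.group and any(c.gene_id == gid and c.has_full_domain for c in erf_calls)
    }
    group_table = aggregate_by_group(rm, erf_group_of, row_order=ERF_GROUPS)
    tissue_shares = tissue_percentages(rm.per_tissue()) if rm.total > 0 else {}

    _log("mirna", f"scanning {len(mirnas)} miRNAs against {len(contigs)} contigs")
    params = TargetScanParams()
    dom_interval = {}
    for c in contigs:
        ap2 = [h for h in hits_by_gene[c.id] if h.kind == "AP2"]
        if ap2:
            # site regions are labelled relative to the leftmost AP2 domain
            dom_interval[c.id] = min(domain_nt_interval(h) for h in ap2)
    mirna_hits = []
    for mid, mseq in mirnas:
        for c in contigs:
            mirna_hits.extend(
                scan_targets(
                    mseq, c.sequence, params, mirna_id=mid, transcript_id=c.id,
                    cds_interval=c.cds_interval,
                    domain_interval=dom_interval.get(c.id),
                )
            )

    table3 = tabulate_families(calls)
    table4 = {
        g: sum(
            1 for call in erf_calls
            if call.has_full_domain and assignments.get(call.gene_id) is not None
            and assignments[call.gene_id].group == g
        )
        for g in ERF_GROUPS
    }
    sakuma = {"AP2": 0, "DREB": 0, "ERF": 0, "VI-L": 0, "RAV": 0, "SOLOIST": 0}
    for call in calls:
        if call.family == "UNCLASSIFIED" or not call.has_full_domain:
            continue
        if call.family == "ERF":
            g = assignments.get(call.gene_id)
            g = g.group if g else None
            if g == "VI-L":
                sakuma["VI-L"] += 1
            elif g in DREB_GROUPS:
                sakuma["DREB"] += 1
            elif g is not None:
                sakuma["ERF"] += 1
        else:
            sakuma[call.family] += 1
    sakuma["total"] = sum(v for k, v in sakuma.items() if k != "total")

    return PipelineResult(
        config=config, seed=seed, contigs=contigs, truths=truths,
        membership=membership, mirnas=mirnas, planted_sites=planted,
        hits_by_gene=hits_by_gene, calls=calls, assignments=assignments,
        tree_newick=tree_newick, marker_table=marker_table,
        conservation=conservation, motif_reports=motif_reports,
        group_table=group_table, tissue_shares=tissue_shares,
        mirna_hits=mirna_hits, table3=table3, table4=table4, sakuma=sakuma,
    )


# ---------------------------------------------------------------------------
# file-emitting run


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    version: str
    stages: dict = field(default_factory=dict)
    generated_at: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _write_fasta(path: Path, records) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
            n += 1
    return n


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> int:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
    return len(df)


_STAGES = [
    ("simulate", ["transcripts.fasta", "truth.tsv", "read_membership.tsv",
                  "mirnas.fasta", "mirna_truth.tsv", "reads.fasta", "config.yaml"]),
    ("filter", ["reads_kept.fasta", "read_filter.tsv"]),
    ("scan", ["domain_hits.tsv"]),
    ("classify", ["families.tsv"]),
    ("group", ["group_assignments.tsv", "tree.nwk"]),
    ("markers", ["marker_table.tsv", "universal_residues.tsv", "motif_report.tsv"]),
    ("tissues", ["reads_by_group.tsv", "tissue_shares.tsv"]),
    ("mirna", ["mirna_hits.tsv"]),
    ("summary", ["family_summary.tsv", "group_counts.tsv", "sakuma_summary.tsv"]),
]


def run_all(
    config: CohortConfig | None = None,
    seed: int = 1,
    outdir: str | Path = "ap2erf_run",
    force: bool = False,
) -> RunManifest:
    """Run the pipeline and write per-stage text outputs plus a manifest.

    Stages whose outputs all exist are not rewritten unless ``force`` is
    set or an upstream stage was (re)generated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = analyze_cohort(config, seed=seed)

    writers = {
        "simulate": lambda d: _stage_simulate(d, res),
        "filter": lambda d: _stage_filter(d, res),
        "scan": lambda d: _stage_scan(d, res),
        "classify": lambda d: _stage_classify(d, res),
        "group": lambda d: _stage_group(d, res),
        "markers": lambda d: _stage_markers(d, res),
        "tissues": lambda d: _stage_tissues(d, res),
        "mirna": lambda d: _stage_mirna(d, res),
        "summary": lambda d: _stage_summary(d, res),
    }

    manifest = RunManifest(
        seed=seed,
        config_digest=hashlib.sha256(
            yaml_dump_config(res.config).encode()
        ).hexdigest(),
        version=__version__,
        generated_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    upstream_rerun = False
    for stage, outputs in _STAGES:
        paths = [outdir / name for name in outputs]
        if force or upstream_rerun or not all(p.exists() for p in paths):
            _log(stage, "writing outputs")
            counts = writers[stage](outdir)
            upstream_rerun = True
        else:
            _log(stage, "outputs present, skipped")
            counts = {}
        manifest.stages[stage] = {
            "outputs": [str(p) for p in paths],
            "counts": counts,
        }
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def yaml_dump_config(config: CohortConfig) -> str:
    import yaml

    data = {
        k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    return yaml.safe_dump(data, sort_keys=True)


def _stage_simulate(outdir: Path, res: PipelineResult) -> dict:
    n_tr = _write_fasta(outdir / "transcripts.fasta",
                        ((c.id, c.sequence) for c in res.contigs))
    truth_rows = []
    for t in res.truths:
        truth_rows.append({
            "gene_id": t.gene_id, "family": t.family, "group": t.group or "",
            "subgroup": t.subgroup, "completeness": t.completeness_summary,
            "strand": t.strand,
            "cds_start": t.cds_interval[0] if t.cds_interval else "",
            "cds_end": t.cds_interval[1] if t.cds_interval else "",
            "n_domains": len(t.domains),
            "has_full_domain": int(t.has_full_domain),
            "markers": ";".join(f"{p}{r}" for p, r in sorted(t.marker_positions.items())),
        })
    _write_tsv(outdir / "truth.tsv", pd.DataFrame(truth_rows))
    _write_tsv(outdir / "read_membership.tsv", res.membership)
    _write_fasta(outdir / "mirnas.fasta", res.mirnas)
    site_rows = [{
        "mirna_id": s.mirna_id, "gene_id": s.gene_id,
        "start": s.interval[0], "end": s.interval[1], "mode": s.mode,
        "region": s.region, "penalty": s.penalty, "skipped": int(s.skipped),
    } for s in res.planted_sites]
    _write_tsv(outdir / "mirna_truth.tsv", pd.DataFrame(site_rows))
    reads = generate_raw_reads(res.contigs, seed=res.seed + 3)
    _write_fasta(outdir / "reads.fasta", reads)
    res.config.to_yaml(outdir / "config.yaml")
    return {"transcripts": n_tr, "truth_records": len(truth_rows),
            "mirnas": len(res.mirnas), "raw_reads": len(reads)}


def _stage_filter(outdir: Path, res: PipelineResult) -> dict:
    kept, report = filter_reads(outdir / "reads.fasta")
    _write_fasta(outdir / "reads_kept.fasta", kept)
    _write_tsv(outdir / "read_filter.tsv", report)
    return {"kept": len(kept), "discarded": int((report["status"] == "discarded").sum())}


def _stage_scan(outdir: Path, res: PipelineResult) -> dict:
    rows = []
    for gid in sorted(res.hits_by_gene):
        for h in res.hits_by_gene[gid]:
            rows.append({
                "contig": gid, "frame": h.peptide.frame, "strand": h.peptide.strand,
                "start": h.pep_interval[0], "end": h.pep_interval[1], "kind": h.kind,
                "model_start": h.model_span[0], "model_end": h.model_span[1],
                "score": round(h.score, 2), "completeness": h.completeness,
                "insertion_167": int(h.has_insertion_167),
            })
    _write_tsv(outdir / "domain_hits.tsv", pd.DataFrame(rows))
    return {"hits": len(rows)}


def _stage_classify(outdir: Path, res: PipelineResult) -> dict:
    rows = [{
        "gene": c.gene_id, "family": c.family, "completeness": c.completeness_summary,
        "name": c.name, "homology_override": int(c.homology_override),
        "n_evidence": len(c.evidence),
    } for c in res.calls]
    _write_tsv(outdir / "families.tsv", pd.DataFrame(rows))
    return {"calls": len(rows)}


def _stage_group(outdir: Path, res: PipelineResult) -> dict:
    rows = [{
        "gene": ga.gene_id, "group": ga.group or "", "subgroup": ga.subgroup,
        "method": ga.method, "tree_group": ga.tree_group or "",
        "marker_group": ga.marker_group or "", "subfamily": ga.subfamily,
        "sakuma_subfamily": ga.sakuma_subfamily, "sakuma_band": ga.sakuma_band,
    } for ga in (res.assignments[g] for g in sorted(res.assignments))]
    _write_tsv(outdir / "group_assignments.tsv", pd.DataFrame(rows))
    (outdir / "tree.nwk").write_text(res.tree_newick)
    return {"assignments": len(rows)}


def _stage_markers(outdir: Path, res: PipelineResult) -> dict:
    _write_tsv(outdir / "marker_table.tsv", res.marker_table.to_frame())
    uni = pd.DataFrame(
        [{"position": p, "residue": r} for p, r in sorted(res.marker_table.universal.items())]
    )
    _write_tsv(outdir / "universal_residues.tsv", uni)
    motif_rows = [{
        "gene": rep.gene_id,
        **{m: ("" if rep.positions.get(m) is None else rep.positions[m])
           for m in ("YRG", "WLG", "RAYD", "KREYD", "EAR")},
    } for rep in (res.motif_reports[g] for g in sorted(res.motif_reports))]
    _write_tsv(outdir / "motif_report.tsv", pd.DataFrame(motif_rows))
    return {"markers": len(res.marker_table.entries),
            "universal": len(res.marker_table.universal)}


def _stage_tissues(outdir: Path, res: PipelineResult) -> dict:
    _write_tsv(outdir / "reads_by_group.tsv", res.group_table, index=True)
    shares = pd.DataFrame(
        [{"library": k, "share_pct": v} for k, v in sorted(res.tissue_shares.items())]
    )
    _write_tsv(outdir / "tissue_shares.tsv", shares)
    return {"groups": len(res.group_table) - 1}


def _stage_mirna(outdir: Path, res: PipelineResult) -> dict:
    rows = [{
        "mirna": h.mirna_id, "target": h.gene_id,
        "start": h.interval[0] + 1, "end": h.interval[1],   # 1-based inclusive
        "mir_fragment": h.mir_fragment, "target_fragment": h.target_fragment,
        "penalty": h.penalty, "free_energy": h.energy,
        "inhibition": h.inhibition, "region": h.region,
    } for h in res.mirna_hits]
    _write_tsv(outdir / "mirna_hits.tsv", pd.DataFrame(rows))
    return {"hits": len(rows)}


def _stage_summary(outdir: Path, res: PipelineResult) -> dict:
    _write_tsv(outdir / "family_summary.tsv", res.table3)
    _write_tsv(
        outdir / "group_counts.tsv",
        pd.DataFrame([{"group": g, "count": n} for g, n in res.table4.items()]),
    )
    _write_tsv(
        outdir / "sakuma_summary.tsv",
        pd.DataFrame([{"band": k, "count": v} for k, v in res.sakuma.items()]),
    )
    return {
        "total_classified": res.total_classified,
        "full_domain": res.full_domain_count,
        "erf_full": sum(res.table4.values()),
    }
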