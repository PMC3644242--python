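"""Locate AP2 and B3 domains on translated transcript contigs.

Transcripts are translated in all six frames; stop-free peptide stretches
are scanned with a position-specific scoring model (log-odds over a
58-column reference alignment of AP2 domains, with affine model-deletion
penalties and a dedicated single-residue insertion slot between
structural positions 167 and 168 — the group-IX "+X167" insertion).

A hit's completeness class follows the span of matched model columns:
``full`` covers positions 1-58 (59 residues when the insertion slot is
occupied), ``partial_N``/``partial_C``/``partial_both`` are truncations at
a sequence end, and ``short`` covers both ends but skips four or more
internal columns (the soloist architecture, six missing residues
including R152).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .constants import (
    AMINO_ACIDS,
    B3_SCAFFOLD,
    INSERTION_AFTER,
    INSERTION_KEY,
    MODEL_LENGTH,
    PAPER_OFFSET,
)
from .errors import InputError

_IUPAC_DNA = set("ACGTUNRYSWKMBDHV")
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")

NEG = -1.0e30
_FRESH, _DIAG_M, _DIAG_D, _INS = 0, 1, 2, 3
_OPEN, _EXT = 0, 1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PeptideCandidate:
    """A stop-free translated stretch of a transcript.

    ``nt_interval`` is 0-based half-open on the forward strand of the
    source transcript, regardless of the candidate's strand.
    """

    transcript_id: str
    frame: int
    strand: str
    seq: str
    nt_interval: tuple[int, int]

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PositionSpecificModel:
    """Log-odds model over a fixed-length domain alignment."""

    scores: np.ndarray                 # (length, 20) log2 odds
    gap_open: float = 4.0
    gap_extend: float = 1.0
    insertion_after: int | None = None  # 1-based model position (23 for AP2)
    insertion_penalty: float = 2.0
    threshold_frac: float = 0.6
    kind: str = "AP2"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise InputError("model scores must be finite")
        self.col_max = self.scores.max(axis=1)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def threshold(self) -> float:
        """Acceptance threshold against the full-model maximum score."""
        return self.threshold_frac * float(self.col_max.sum())

    def max_span_score(self, model_start: int, model_end: int) -> float:
        return float(self.col_max[model_start - 1 : model_end].sum())


@dataclass
class DomainHit:
    """A located domain on one peptide candidate."""

    peptide: PeptideCandidate | None
    kind: str
    pep_interval: tuple[int, int]       # 0-based half-open on the peptide
    model_span: tuple[int, int]         # 1-based inclusive model positions
    score: float
    completeness: str
    has_insertion_167: bool = False
    n_internal_deletions: int = 0
    residues: dict = field(default_factory=dict)  # structural pos -> residue

    @property
    def paper_span(self) -> tuple[int, int]:
        return (self.model_span[0] + PAPER_OFFSET, self.model_span[1] + PAPER_OFFSET)


def six_frame_translate(transcript_id: str, sequence: str, min_orf_aa: int = 40) -> list[PeptideCandidate]:
    """All stop-free peptide stretches of at least ``min_orf_aa`` residues.

    Coordinates refer to the forward strand; ambiguity codes translate to X.
    """
    if min_orf_aa < 1:
        raise InputError("min_orf_aa must be >= 1")
    seq = sequence.upper().replace("U", "T")
    for off, ch in enumerate(seq):
        if ch not in _IUPAC_DNA:
            raise InputError(f"non-IUPAC character {ch!r} at offset {off} in {transcript_id}")
    n = len(seq)
    out: list[PeptideCandidate] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            aa = []
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in _STOP_CODONS:
                    aa.append("*")
                else:
                    aa.append(_CODON_TABLE.get(codon, "X"))
            pep = "".join(aa)
            start = 0
            for chunk in pep.split("*"):
                if len(chunk) >= min_orf_aa:
                    a0, a1 = start, start + len(chunk)
                    lo, hi = frame + 3 * a0, frame + 3 * a1
                    if strand == "-":
                        lo, hi = n - (frame + 3 * a1), n - (frame + 3 * a0)
                    out.append(PeptideCandidate(transcript_id, frame, strand, chunk, (lo, hi)))
                start += len(chunk) + 1
    return out


def build_model(aligned: list[str], pseudocount: float = 0.5, **kwargs) -> PositionSpecificModel:
    """Log-odds model from an ungapped reference alignment.

    Columns are scored against a uniform background with additive
    pseudocounts: ``score[p, a] = log2((n_pa + c) / (N + 20 c) * 20)``.
    """
    if len(aligned) < 2:
        raise InputError("need at least two aligned sequences")
    length = len(aligned[0])
    if any(len(s) != length for s in aligned):
        raise InputError("ragged alignment: sequences differ in length")
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    counts = np.zeros((length, 20))
    totals = np.zeros(length)
    for s in aligned:
        for p, aa in enumerate(s.upper()):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[p, idx] += 1
                totals[p] += 1
    freq = (counts + pseudocount) / (totals[:, None] + 20 * pseudocount)
    return PositionSpecificModel(scores=np.log2(freq * 20), **kwargs)


def _score_matrix(model: PositionSpecificModel, peptide: str) -> np.ndarray:
    """(model_length, len(peptide)) score matrix; unknown residues score 0."""
    ext = np.concatenate([model.scores, np.zeros((model.length, 1))], axis=1)
    idx = np.array([_AA_INDEX.get(a, 20) for a in peptide], dtype=int)
    return ext[:, idx]


def _align_once(S: np.ndarray, model: PositionSpecificModel) -> dict | None:
    """Best semi-global alignment of the model to the peptide.

    Free peptide flanks; free model flanks only at a peptide end (domains
    truncate at sequence ends); affine penalties for internal model
    deletions; a dedicated single-residue insertion slot after
    ``model.insertion_after``.
    """
    n, L = S.shape
    if L == 0:
        return None
    op, ext_pen = model.gap_open, model.gap_extend
    ins_row = model.insertion_after + 1 if model.insertion_after else None

    M = np.empty((n, L))
    D = np.full((n, L), NEG)
    mmove = np.zeros((n, L), dtype=np.uint8)
    dmove = np.zeros((n, L), dtype=np.uint8)

    M[0] = S[0]
    mmove[0] = _FRESH
    for i in range(1, n):
        m_prev, d_prev = M[i - 1], D[i - 1]
        open_cand = m_prev - op
        ext_cand = d_prev - ext_pen
        D[i] = np.maximum(open_cand, ext_cand)
        dmove[i] = np.where(open_cand >= ext_cand, _OPEN, _EXT)

        diag_m = np.concatenate(([NEG], m_prev[:-1]))
        diag_d = np.concatenate(([NEG], d_prev[:-1]))
        base = np.where(diag_m >= diag_d, diag_m, diag_d)
        mmove[i] = np.where(diag_m >= diag_d, _DIAG_M, _DIAG_D)
        M[i] = base + S[i]
        if ins_row is not None and i == ins_row - 1 and L > 1:
            ins = np.full(L, NEG)
            ins[2:] = M[i - 1][:-2] - model.insertion_penalty
            cand = ins + S[i]
            better = cand > M[i]
            M[i][better] = cand[better]
            mmove[i][better] = _INS
        # model-prefix truncation: fresh start allowed only at peptide pos 0
        if S[i, 0] > M[i, 0]:
            M[i, 0] = S[i, 0]
            mmove[i, 0] = _FRESH

    # alignment may end at the last model row (anywhere on the peptide) or,
    # for C-truncated domains, at the last peptide column.
    j_best = int(np.argmax(M[n - 1]))
    best_i, best_j, best = n - 1, j_best, M[n - 1, j_best]
    i_col = int(np.argmax(M[:, L - 1]))
    if M[i_col, L - 1] > best:
        best_i, best_j, best = i_col, L - 1, M[i_col, L - 1]
    if best <= NEG / 2:
        return None

    matches: list[tuple[int, int]] = []
    deletions: list[int] = []
    insertion_j: int | None = None
    i, j = best_i, best_j
    model_start = None
    while True:
        mv = mmove[i, j]
        matches.append((i + 1, j))
        if mv == _FRESH:
            model_start = i + 1
            break
        if mv == _DIAG_M:
            i, j = i - 1, j - 1
        elif mv == _INS:
            insertion_j = j - 1
            i, j = i - 1, j - 2
        else:  # _DIAG_D: one or more model columns deleted before this match
            di, dj = i - 1, j - 1
            while True:
                deletions.append(di + 1)
                if dmove[di, dj] == _OPEN:
                    break
                di -= 1
            i, j = di - 1, dj
    matches.reverse()
    return {
        "score": float(best),
        "model_start": model_start,
        "model_end": best_i + 1,
        "pep_start": matches[0][1],
        "pep_end": best_j,
        "matches": matches,
        "deletions": sorted(deletions),
        "insertion_j": insertion_j,
    }


def _completeness(model_start: int, model_end: int, n: int, n_del: int) -> str:
    if model_start == 1 and model_end == n:
        return "short" if n_del >= 4 else "full"
    if model_start > 1 and model_end == n:
        return "partial_N"
    if model_start == 1 and model_end < n:
        return "partial_C"
    return "partial_both"


def scan_peptide(
    peptide: PeptideCandidate,
    model: PositionSpecificModel,
    max_hits: int = 3,
    min_model_span: int = 16,
) -> list[DomainHit]:
    """Non-overlapping above-threshold hits, best score first.

    The acceptance threshold is ``threshold_frac`` of the maximum score
    attainable over the matched model span (the full-model maximum when
    the span covers both ends), so truncated domains remain detectable.
    """
    pep = peptide.seq
    if not pep:
        return []
    S = _score_matrix(model, pep)
    hits: list[DomainHit] = []
    for _ in range(max_hits):
        res = _align_once(S, model)
        if res is None:
            break
        ms, me = res["model_start"], res["model_end"]
        span_max = (
            model.max_span_score(1, model.length)
            if (ms == 1 and me == model.length)
            else model.max_span_score(ms, me)
        )
        if (
            me - ms + 1 < min_model_span
            or res["score"] < model.threshold_frac * span_max
            or res["score"] <= 0
        ):
            break
        residues = {mi + PAPER_OFFSET: pep[j] for mi, j in res["matches"]}
        if res["insertion_j"] is not None:
            residues[INSERTION_KEY] = pep[res["insertion_j"]]
        hits.append(
            DomainHit(
                peptide=peptide,
                kind=model.kind,
                pep_interval=(res["pep_start"], res["pep_end"] + 1),
                model_span=(ms, me),
                score=res["score"],
                completeness=_completeness(ms, me, model.length, len(res["deletions"])),
                has_insertion_167=res["insertion_j"] is not None,
                n_internal_deletions=len(res["deletions"]),
                residues=residues,
            )
        )
        S[:, res["pep_start"] : res["pep_end"] + 1] = NEG
    hits.sort(key=lambda h: h.pep_interval)
    return hits


def scan_ap2(peptide: PeptideCandidate, model: PositionSpecificModel | None = None) -> list[DomainHit]:
    """AP2-domain hits on one peptide (0, 1 or 2 domains expected)."""
    return scan_peptide(peptide, model or default_ap2_model())


def detect_b3(peptide: PeptideCandidate, b3_model: PositionSpecificModel | None = None) -> list[DomainHit]:
    """B3-domain hits (the RAV family's second DNA-binding domain)."""
    return scan_peptide(peptide, b3_model or default_b3_model(), max_hits=1)


@lru_cache(maxsize=1)
def default_ap2_model() -> PositionSpecificModel:
    """AP2 model built from the bundled synthetic reference panel."""
    from .synthetic_data import build_reference_panel

    panel = build_reference_panel(seed=0)
    core = ["".join(d.residues.get(p, "") for p in range(145, 203)) for d in panel
            if len(d.residues) >= MODEL_LENGTH]
    core = [s for s in core if len(s) == MODEL_LENGTH]
    return build_model(core, insertion_after=INSERTION_AFTER - PAPER_OFFSET, kind="AP2")


@lru_cache(maxsize=1)
def default_b3_model() -> PositionSpecificModel:
    """B3 model from the synthetic B3 consensus plus mutated variants."""
    rng = np.random.default_rng(0)
    variants = [B3_SCAFFOLD]
    for _ in range(7):
        s = list(B3_SCAFFOLD)
        for p in rng.choice(len(s), size=3, replace=False):
            s[p] = AMINO_ACIDS[rng.integers(20)]
        variants.append("".join(s))
    return build_model(variants, insertion_after=None, kind="B3")


def log_odds_identity_ceiling(model: PositionSpecificModel) -> float:
    """Convenience: per-column mean of the maximal attainable score."""
    return float(model.col_max.mean())
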