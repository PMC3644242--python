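"""Plant miRNA target prediction with additive penalty scoring.

A miRNA is slid along the transcript and each window alignment is scored
as a sum of penalties counted per miRNA position from its 5' end: 2 per
gap, 1 per non-pairing position, 0.5 per G:U wobble.  Hits are kept when
the total penalty is at most the threshold (default 3), the alignment
spans at least the minimum length (15), the protected positions (10 and
11) are paired, and the duplex free energy under the per-pair additive
model (G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol) is at or below the cutoff
(-20 kcal/mol).  With a penalty budget of 3 and a gap cost of 2 an
alignment carries at most one gap, which the scanner enumerates exactly.

Inhibition mode follows the central-pairing convention: Watson-Crick
pairing across miRNA positions 9-11 predicts transcript cleavage,
anything else translational repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_PAD = 5

# pair categories between a miRNA base (rows) and a target base (columns)
_WC = {(0, 3), (3, 0), (2, 1), (1, 2)}
_WOBBLE = {(2, 3), (3, 2)}

_PEN = np.ones((6, 6))
_ENERGY = np.zeros((6, 6))
for (a, b) in _WC:
    _PEN[a, b] = 0.0
    _ENERGY[a, b] = -3.0 if {a, b} == {1, 2} else -2.0
for (a, b) in _WOBBLE:
    _PEN[a, b] = 0.5
    _ENERGY[a, b] = -1.0
_PEN[_PAD, :] = _PEN[:, _PAD] = 99.0


@dataclass
class TargetScanParams:
    """Penalty parameters of the target scan."""

    gap_penalty: float = 2.0
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    penalty_threshold: float = 3.0
    min_alignment_length: int = 15
    protected_positions: tuple = (10, 11)   # 1-based from the miRNA 5' end
    energy_cutoff: float = -20.0            # kcal/mol

    def __post_init__(self):
        if min(self.gap_penalty, self.mismatch_penalty, self.gu_penalty) < 0:
            raise InputError("penalties must be >= 0")
        if self.penalty_threshold <= 0:
            raise InputError("penalty threshold must be > 0")


@dataclass
class MiRHit:
    """A predicted miRNA binding site."""

    mirna_id: str
    gene_id: str
    interval: tuple                  # 0-based half-open on the transcript
    mir_fragment: str                # 5'->3', with '-' for gaps
    target_fragment: str             # 5'->3', with '-' for gaps
    penalty: float
    energy: float                    # kcal/mol
    pairing: dict = field(default_factory=dict)  # miRNA position -> category
    inhibition: str = ""
    region: str = ""


def _validate_rna(seq: str, what: str, allow_n: bool) -> str:
    s = seq.upper().replace("T", "U")
    allowed = set("ACGUN") if allow_n else set("ACGU")
    for off, ch in enumerate(s):
        if ch not in allowed:
            raise InputError(f"non-RNA/DNA character {ch!r} at offset {off} in {what}")
    return s


def duplex_energy(mir_fragment: str, target_fragment: str) -> float:
    """Additive per-pair duplex free energy of two aligned fragments.

    Fragments are 5'->3' gapped strings of equal length, paired
    antiparallel: position i of the miRNA fragment against position
    L-1-i of the target fragment.  G:C contributes -3.0, A:U -2.0,
    G:U -1.0, gaps and non-pairs 0 kcal/mol.
    """
    if len(mir_fragment) != len(target_fragment):
        raise InputError("aligned fragments differ in length")
    mir = _validate_rna(mir_fragment.replace("-", "N"), "miRNA fragment", allow_n=True)
    tgt = _validate_rna(target_fragment.replace("-", "N"), "target fragment", allow_n=True)
    total = 0.0
    L = len(mir)
    for i in range(L):
        a, b = _CODE[mir[i]], _CODE[tgt[L - 1 - i]]
        total += _ENERGY[a, b]
    return float(total)


def _pair_category(mir_base: int, tgt_base: int) -> str:
    if (mir_base, tgt_base) in _WC:
        return "WC"
    if (mir_base, tgt_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _column_penalty(cat: str, params: TargetScanParams) -> float:
    return {"WC": 0.0, "wobble": params.gu_penalty, "mismatch": params.mismatch_penalty}[cat]


def call_inhibition(hit: MiRHit) -> str:
    """Cleavage when miRNA positions 9-11 are all Watson-Crick paired."""
    return (
        "cleavage"
        if all(hit.pairing.get(p) == "WC" for p in (9, 10, 11))
        else "translation"
    )


def annotate_site(
    interval: tuple,
    cds_interval: tuple | None,
    domain_interval: tuple | None,
    transcript_length: int,
) -> str:
    """Region label of a site; a site spanning two regions takes the
    region containing its midpoint."""
    s, e = interval
    if not (0 <= s < e <= transcript_length):
        raise InputError(f"site interval {interval} outside transcript of length {transcript_length}")
    if cds_interval is None:
        return "unannotated"
    mid = (s + e - 1) // 2
    c0, c1 = cds_interval
    if mid < c0:
        return "5'UTR"
    if mid >= c1:
        return "3'UTR"
    if domain_interval is None:
        return "CDS"
    d0, d1 = domain_interval
    if mid < d0:
        return "CDS-before-AP2"
    if mid < d1:
        return "CDS-inside-AP2"
    return "CDS-after-AP2"


def _columns_for(scheme: str, k: int, s: int, m: int):
    """Alignment columns (mir_rev_index, target_index) in target 5'->3'
    order; None marks the gapped side of a column."""
    if scheme == "ungapped":
        return [(i, s + i) for i in range(m)]
    if scheme == "target_bulge":    # extra target base, gap in the miRNA fragment
        return (
            [(i, s + i) for i in range(k)]
            + [(None, s + k)]
            + [(i, s + i + 1) for i in range(k, m)]
        )
    # miRNA bulge: miRNA base k unpaired opposite a target gap
    return (
        [(i, s + i) for i in range(k)]
        + [(k, None)]
        + [(i, s + i - 1) for i in range(k + 1, m)]
    )


def scan_targets(
    mirna_seq: str,
    transcript_seq: str,
    params: TargetScanParams | None = None,
    *,
    mirna_id: str = "miRNA",
    transcript_id: str = "transcript",
    cds_interval: tuple | None = None,
    domain_interval: tuple | None = None,
) -> list[MiRHit]:
    """Scan one miRNA against one transcript.

    T and U are interchangeable on input.  Overlapping hits resolve to
    the lowest penalty (ties to the leftmost site).
    """
    params = params or TargetScanParams()
    mir = _validate_rna(mirna_seq, f"miRNA {mirna_id}", allow_n=False)
    tgt = _validate_rna(transcript_seq, f"transcript {transcript_id}", allow_n=True)
    m, n = len(mir), len(tgt)
    if not 15 <= m <= 30:
        raise InputError(f"miRNA length must be 15-30 nt, got {m}")
    for p in params.protected_positions:
        if not 1 <= p <= m:
            raise InputError(f"protected position {p} outside miRNA length {m}")
    if n < m - 1:
        return []

    mr = np.array([_CODE[c] for c in reversed(mir)])
    tc = np.array([_CODE[c] for c in tgt] + [_PAD, _PAD])
    PM = _PEN[mr][:, tc]                       # (m, n + 2)
    s_count = max(n - m + 2, 0)
    W0 = np.stack([PM[i, i : i + s_count] for i in range(m)])
    W1 = np.stack([PM[i, i + 1 : i + 1 + s_count] for i in range(m)])
    Wm1 = np.stack(
        [PM[i, max(i - 1, 0) : max(i - 1, 0) + s_count] for i in range(m)]
    )
    C0 = np.cumsum(W0, axis=0)
    S1 = np.cumsum(W1[::-1], axis=0)[::-1]
    Sm1 = np.cumsum(Wm1[::-1], axis=0)[::-1]

    thr = params.penalty_threshold + 1e-9
    candidates: list[tuple[str, int, int]] = []    # (scheme, k, s)
    for s in np.nonzero(C0[m - 1] <= thr)[0]:
        candidates.append(("ungapped", 0, int(s)))
    for k in range(1, m):
        pen = C0[k - 1] + params.gap_penalty + S1[k]
        for s in np.nonzero(pen <= thr)[0]:
            candidates.append(("target_bulge", k, int(s)))
    for k in range(1, m - 1):
        pen = C0[k - 1] + params.gap_penalty + Sm1[k + 1]
        for s in np.nonzero(pen <= thr)[0]:
            candidates.append(("mirna_bulge", k, int(s)))

    hits: list[MiRHit] = []
    for scheme, k, s in candidates:
        columns = _columns_for(scheme, k, s, m)
        tgt_indices = [ti for _, ti in columns if ti is not None]
        if min(tgt_indices) < 0 or max(tgt_indices) >= n:
            continue
        if len(columns) < params.min_alignment_length:
            continue
        penalty = 0.0
        pairing: dict[int, str] = {}
        ok = True
        for ri, ti in columns:
            if ri is None or ti is None:
                penalty += params.gap_penalty
                if ri is not None:
                    pairing[m - ri] = "gap"
                continue
            cat = _pair_category(int(mr[ri]), int(tc[ti]))
            pairing[m - ri] = cat
            penalty += _column_penalty(cat, params)
        if penalty > thr:
            continue
        for p in params.protected_positions:
            if pairing.get(p) not in ("WC", "wobble"):
                ok = False
                break
        if not ok:
            continue
        mir_frag = "".join(
            mir[m - 1 - ri] if ri is not None else "-" for ri, _ in reversed(columns)
        )
        tgt_frag = "".join(tgt[ti] if ti is not None else "-" for _, ti in columns)
        energy = duplex_energy(mir_frag, tgt_frag)
        if energy > params.energy_cutoff:
            continue
        interval = (min(tgt_indices), max(tgt_indices) + 1)
        hit = MiRHit(
            mirna_id=mirna_id, gene_id=transcript_id, interval=interval,
            mir_fragment=mir_frag, target_fragment=tgt_frag,
            penalty=round(penalty, 3), energy=energy, pairing=pairing,
        )
        hit.inhibition = call_inhibition(hit)
        hit.region = annotate_site(interval, cds_interval, domain_interval, n) \
            if cds_interval is not None else ""
        hits.append(hit)

    hits.sort(key=lambda h: (h.penalty, h.interval))
    kept: list[MiRHit] = []
    for h in hits:
        if all(h.interval[1] <= o.interval[0] or h.interval[0] >= o.interval[1] for o in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.interval)
    return kept
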