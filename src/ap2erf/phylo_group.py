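"""Group assignment of ERF-family domains by neighbour joining.

Domains are first anchored to the fixed AtERF1 structural numbering
(positions 145-202 plus the group-IX "167i" insertion slot), a conserved
block is curated from the multiple alignment, pairwise p-distances are
computed on the block, and queries are placed on a neighbour-joining tree
together with a labelled reference panel.  The group of the smallest
reference-containing clade around the query is the primary (tree)
evidence; the group-diagnostic residue profile is recorded as secondary
evidence and decides the call when the tree placement is ambiguous or
contradicts a unique marker match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .constants import (
    ERF_GROUPS,
    FIRST_POSITION,
    GROUP_MARKERS,
    INSERTION_KEY,
    LAST_POSITION,
    SAKUMA_BANDS,
)
from .domain_scan import PositionSpecificModel, _align_once, _score_matrix
from .errors import InputError

ALL_POSITIONS: tuple = tuple(
    list(range(FIRST_POSITION, 168)) + [INSERTION_KEY] + list(range(168, LAST_POSITION + 1))
)


@dataclass
class NumberedDomain:
    """An AP2 domain expressed as residues at structural positions.

    ``residues`` maps positions 145..202 (ints) and optionally the
    insertion key ``"167i"`` to single residues; absent positions are
    gaps (truncations or the soloist deletion).
    """

    gene_id: str
    residues: dict
    group: str | None = None
    subgroup: str = ""

    def __post_init__(self):
        if len(self.residues) > 59:
            raise InputError(f"{self.gene_id}: more than 59 occupied positions")
        if INSERTION_KEY in self.residues and not (
            167 in self.residues and 168 in self.residues
        ):
            raise InputError(f"{self.gene_id}: 167i occupied without flanking 167/168")

    @property
    def occupied(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(self.residues[p] for p in ALL_POSITIONS if p in self.residues)

    def row(self, columns) -> str:
        return "".join(self.residues.get(p, "-") for p in columns)


@dataclass
class CuratedBlock:
    """Conserved alignment block over selected structural columns."""

    gene_ids: list[str]
    columns: list
    rows: list[str]

    def __post_init__(self):
        if any(len(r) != len(self.columns) for r in self.rows):
            raise InputError("block rows and column list disagree in length")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.columns))


@dataclass
class PhyloTree:
    """Unrooted NJ tree; negative branch-length estimates are clamped."""

    tree: TreeNode
    negative_branches_clamped: int = 0

    @property
    def n_leaves(self) -> int:
        return self.tree.count(tips=True)

    def to_newick(self) -> str:
        return str(self.tree)

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(TreeNode.read([text]))


@dataclass
class GroupAssignment:
    """Family/group call for one gene with the evidence that decided it."""

    gene_id: str
    group: str | None
    subgroup: str = ""
    method: str = ""
    tree_group: str | None = None
    marker_group: str | None = None
    subfamily: str = ""
    sakuma_subfamily: str = ""
    sakuma_band: str = ""


def anchor_align(sequence: str, model: PositionSpecificModel, gene_id: str = "query") -> NumberedDomain:
    """Map a domain sequence onto structural positions 145-202 (+167i)."""
    if not 20 <= len(sequence) <= 70:
        raise InputError(f"{gene_id}: domain length {len(sequence)} outside 20-70")
    S = _score_matrix(model, sequence)
    res = _align_once(S, model)
    if res is None:
        raise InputError(f"{gene_id}: not an AP2 domain (no alignment)")
    ms, me = res["model_start"], res["model_end"]
    span_max = (
        model.max_span_score(1, model.length)
        if (ms == 1 and me == model.length)
        else model.max_span_score(ms, me)
    )
    if res["score"] < model.threshold_frac * span_max:
        raise InputError(f"{gene_id}: not an AP2 domain (score below threshold)")
    residues = {mi + FIRST_POSITION - 1: sequence[j] for mi, j in res["matches"]}
    if res["insertion_j"] is not None:
        residues[INSERTION_KEY] = sequence[res["insertion_j"]]
    return NumberedDomain(gene_id=gene_id, residues=residues)


def extract_block(
    msa: list[NumberedDomain],
    conservation_threshold: float = 0.5,
    min_block: int = 10,
) -> CuratedBlock:
    """Curate maximal runs of conserved columns from the anchored MSA.

    A column is conserved when its modal non-gap residue occurs in at
    least ``conservation_threshold`` of all rows; runs of conserved
    columns shorter than ``min_block`` are dropped.
    """
    if len(msa) < 4:
        raise InputError("need at least 4 sequences for block curation")
    n = len(msa)
    candidates = [p for p in ALL_POSITIONS if any(p in d.residues for d in msa)]
    conserved = []
    for p in candidates:
        counts: dict[str, int] = {}
        for d in msa:
            r = d.residues.get(p)
            if r is not None:
                counts[r] = counts.get(r, 0) + 1
        conserved.append(counts and max(counts.values()) / n >= conservation_threshold)
    keep: list = []
    run: list = []
    for p, ok in zip(candidates, conserved):
        if ok:
            run.append(p)
        else:
            if len(run) >= min_block:
                keep.extend(run)
            run = []
    if len(run) >= min_block:
        keep.extend(run)
    if not keep:
        raise InputError(
            f"no conserved run of >= {min_block} columns; "
            "consider lowering the conservation threshold"
        )
    return CuratedBlock(
        gene_ids=[d.gene_id for d in msa],
        columns=keep,
        rows=[d.row(keep) for d in msa],
    )


def pdistance_matrix(block: CuratedBlock) -> np.ndarray:
    """Pairwise p-distances over mutually non-gap block columns."""
    codes = np.array([[ord(c) for c in row] for row in block.rows], dtype=np.int16)
    gap = ord("-")
    nongap = codes != gap
    n = codes.shape[0]
    both = nongap[:, None, :] & nongap[None, :, :]
    comparable = both.sum(axis=2)
    diff = ((codes[:, None, :] != codes[None, :, :]) & both).sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] == 0).any():
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise InputError(
            f"no comparable columns between {block.gene_ids[i]} and {block.gene_ids[j]}"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, diff / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(dist: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lowest (row-major) index pair;
    negative branch-length estimates are clamped to zero and counted.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise InputError("need at least 3 taxa")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-9):
        raise InputError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise InputError("distance matrix diagonal must be zero")
    if len(labels) != n:
        raise InputError("label count must match matrix size")

    nodes = [TreeNode(name=lab) for lab in labels]
    D = D.copy()
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = _clamp(li), _clamp(lj)
        parent.extend([a, b])
        dk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dk[keep]])
        D = np.hstack([D, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    root = TreeNode()
    for node, ln in zip(nodes, lengths):
        node.length = _clamp(ln)
        root.append(node)
    return PhyloTree(tree=root, negative_branches_clamped=clamped)


def marker_profile_group(domain: NumberedDomain) -> str | None:
    """ERF group whose full diagnostic residue set the domain carries.

    Subset matches (e.g. a VIII domain also carrying V's lone K168) are
    resolved to the most specific matching set; ambiguity returns None.
    """
    matches: list[tuple[int, str]] = []
    for group in ERF_GROUPS:
        entries = GROUP_MARKERS[group]
        ok = True
        for pos, res in entries:
            if pos == INSERTION_KEY:
                ok = ok and INSERTION_KEY in domain.residues
            else:
                ok = ok and domain.residues.get(pos) == res
        if ok:
            matches.append((len(entries), group))
    if not matches:
        return None
    matches.sort(key=lambda t: (-t[0], ERF_GROUPS.index(t[1])))
    if len(matches) > 1 and matches[0][0] == matches[1][0]:
        return None
    return matches[0][1]


def _enclosing_clade_group(tree: TreeNode, query_id: str, labels: dict[str, str]) -> str | None:
    """Majority reference label of the query's smallest enclosing clade."""
    query = None
    for tip in tree.tips():
        if tip.name == query_id:
            query = tip
            break
    if query is None:
        return None
    node = query.parent
    while node is not None:
        found = [labels[t.name] for t in node.tips() if t.name in labels]
        if found:
            counts: dict[str, int] = {}
            for g in found:
                counts[g] = counts.get(g, 0) + 1
            best = max(counts.values())
            winners = sorted(g for g, c in counts.items() if c == best)
            if len(winners) == 1:
                return winners[0]
            return None  # tied clade: ambiguous placement
        node = node.parent
    return None


def assign_groups(
    queries: list[NumberedDomain],
    references: list[NumberedDomain],
    conservation_threshold: float = 0.5,
    min_block: int = 10,
) -> list[GroupAssignment]:
    """Assign ERF groups to query domains against a labelled panel."""
    refs = [r for r in references if r.group in ERF_GROUPS]
    if not refs:
        raise InputError("reference panel contains no labelled ERF groups")
    covered = {r.group for r in refs}
    if covered != set(ERF_GROUPS):
        import warnings

        missing = sorted(set(ERF_GROUPS) - covered)
        warnings.warn(f"reference panel missing groups: {missing}", stacklevel=2)

    everything = refs + queries
    block = extract_block(everything, conservation_threshold, min_block)
    dist = pdistance_matrix(block)
    nref = len(refs)
    ref_labels = {r.gene_id: r.group for r in refs}

    from .residue_markers import subfamily_call  # local: avoids module cycle

    out: list[GroupAssignment] = []
    for qi, query in enumerate(queries):
        idx = list(range(nref)) + [nref + qi]
        sub = dist[np.ix_(idx, idx)]
        labels = [refs[k].gene_id for k in range(nref)] + [query.gene_id]
        tree = nj_tree(sub, labels).tree
        tree_group = _enclosing_clade_group(tree, query.gene_id, ref_labels)
        marker_group = marker_profile_group(query)

        if marker_group and tree_group == marker_group:
            group, method = marker_group, "tree+markers"
        elif marker_group:
            group, method = marker_group, "markers"
        elif tree_group:
            group, method = tree_group, "tree"
        else:
            group, method = None, "unresolved"

        subgroup = ""
        if group is not None:
            in_group = [k for k in range(nref) if refs[k].group == group]
            if in_group:
                nearest = min(in_group, key=lambda k: (dist[k, nref + qi], k))
                subgroup = refs[nearest].subgroup
        subfam = subfamily_call(query)
        sak_sub, sak_band = SAKUMA_BANDS.get(group, ("", ""))
        out.append(
            GroupAssignment(
                gene_id=query.gene_id,
                group=group,
                subgroup=subgroup,
                method=method,
                tree_group=tree_group,
                marker_group=marker_group,
                subfamily=subfam,
                sakuma_subfamily=sak_sub,
                sakuma_band=sak_band,
            )
        )
    return out


def assign_group(query: NumberedDomain, references: list[NumberedDomain], **kwargs) -> GroupAssignment:
    """Single-query convenience wrapper over :func:`assign_groups`."""
    return assign_groups([query], references, **kwargs)[0]


def nearest_reference(
    query: NumberedDomain, references: list[NumberedDomain]
) -> tuple[NumberedDomain, float]:
    """Closest reference by p-distance over shared occupied positions."""
    best, best_d = None, None
    for ref in references:
        shared = [p for p in query.residues if p != INSERTION_KEY and p in ref.residues]
        if not shared:
            continue
        diff = sum(query.residues[p] != ref.residues[p] for p in shared)
        d = diff / len(shared)
        if best_d is None or d < best_d:
            best, best_d = ref, d
    if best is None:
        raise InputError(f"{query.gene_id}: no reference shares positions")
    return best, best_d
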