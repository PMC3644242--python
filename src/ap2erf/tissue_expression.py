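"""Read-count aggregation by tissue library and qPCR relative abundance.

Read membership is a contigs x libraries count matrix; aggregation by
family/group mirrors the published layout (row and column margins plus a
grand total).  Tissue shares are percentages of the overall read total,
rounded half-up to one decimal.  qPCR abundance is the
efficiency-corrected normalized ratio
``E_target^(-Cp_target) / E_ref^(-Cp_ref)``, which reduces to
``2^-(Cp_target - Cp_ref)`` at the default amplification factor of 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class ReadMembership:
    """Contigs x libraries read-count matrix."""

    matrix: pd.DataFrame

    @property
    def libraries(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def contigs(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def per_tissue(self) -> dict:
        return {lib: int(v) for lib, v in self.matrix.sum(axis=0).items()}


def count_reads(records, libraries: list[str] | None = None) -> ReadMembership:
    """Aggregate a membership table into the count matrix.

    Accepts a DataFrame or an iterable of rows in either layout:
    ``(contig, library, count)`` (counts summed) or
    ``(contig, read_id, library)`` (each row one read).
    """
    if isinstance(records, pd.DataFrame):
        rows = [tuple(r) for r in records.itertuples(index=False)]
    else:
        rows = [tuple(r) for r in records]
    cells: dict[tuple[str, str], int] = {}
    order: list[str] = []
    for r in rows:
        if len(r) != 3:
            raise InputError(f"expected 3 columns, got {len(r)}: {r!r}")
        contig, b, c = r
        if isinstance(c, (int, np.integer)) or (isinstance(c, str) and c.lstrip("-").isdigit()):
            library, count = str(b), int(c)
            if count < 0:
                raise InputError(f"negative read count for {contig}/{library}")
        else:
            library, count = str(c), 1
        if libraries is not None and library not in libraries:
            raise InputError(f"unknown library {library!r} for contig {contig}")
        contig = str(contig)
        if contig not in order:
            order.append(contig)
        cells[(contig, library)] = cells.get((contig, library), 0) + count

    libs = list(libraries) if libraries is not None else sorted({k[1] for k in cells})
    data = np.zeros((len(order), len(libs)), dtype=int)
    for (contig, lib), v in cells.items():
        data[order.index(contig), libs.index(lib)] = v
    return ReadMembership(pd.DataFrame(data, index=order, columns=libs))


def aggregate_by_group(
    rm: ReadMembership,
    assignments: dict[str, str],
    row_order: list[str] | None = None,
) -> pd.DataFrame:
    """Group x tissue table with 'Total' margins (Table 8 layout).

    ``assignments`` maps contig id -> group label; contigs without an
    assignment are reported in an 'Unassigned' row.
    """
    groups = rm.matrix.groupby(
        [assignments.get(c, "Unassigned") for c in rm.contigs]
    ).sum()
    if row_order:
        present = [g for g in row_order if g in groups.index]
        rest = sorted(g for g in groups.index if g not in row_order)
        groups = groups.loc[present + rest]
    else:
        groups = groups.sort_index()
    out = groups.copy()
    out.insert(0, "Total", groups.sum(axis=1))
    out.loc["Total"] = out.sum(axis=0)
    return out


def tissue_percentages(per_tissue_counts: dict) -> dict:
    """Per-tissue share of reads (%), rounded half-up to one decimal."""
    total = sum(per_tissue_counts.values())
    if total <= 0:
        raise InputError("total read count must be > 0")
    return {
        lib: float(
            (Decimal(int(v)) * 100 / Decimal(int(total))).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for lib, v in per_tissue_counts.items()
    }


@dataclass
class QpcrMeasurement:
    """One real-time RT-PCR measurement against the reference gene."""

    sample_id: str
    target_gene: str
    cp_target: float
    cp_reference: float
    efficiency_target: float = 2.0
    efficiency_reference: float = 2.0

    def __post_init__(self):
        for name in ("cp_target", "cp_reference"):
            v = getattr(self, name)
            if not 0 < v < 60:
                raise InputError(f"{name} must be in (0, 60), got {v}")
        for name in ("efficiency_target", "efficiency_reference"):
            v = getattr(self, name)
            if not 1 < v <= 2.2:
                raise InputError(f"{name} must be in (1, 2.2], got {v}")


def qpcr_ratio(m: QpcrMeasurement) -> float:
    """Efficiency-corrected normalized expression ratio."""
    return (m.efficiency_target ** (-m.cp_target)) / (
        m.efficiency_reference ** (-m.cp_reference)
    )
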