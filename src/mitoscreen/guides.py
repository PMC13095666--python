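"""Per-cell guide-RNA assignment from barcoded guide reads.

In a pooled CRISPR screen the guide transcript is read out from the
single-cell library: each aligned guide read carries a cell barcode, the
guide it aligned to and a mapping quality. A cell receives a unique guide
assignment when, after MAPQ filtering and deduplication, it has at least
``min_reads`` guide reads and the most abundant guide accounts for strictly
more than ``dominance`` (default 2/3) of them. Cells failing the read floor
are *unassigned*; cells with enough reads but no dominant guide are
*ambiguous*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GuideReadRecord",
    "GuideAssignment",
    "filter_guide_reads",
    "count_guides_per_cell",
    "assign_guides",
    "summarize_assignment",
    "percentage",
]

DEFAULT_MAPQ_MIN = 30
DEFAULT_MIN_READS = 2
DEFAULT_DOMINANCE = 2.0 / 3.0


@dataclass(frozen=True)
class GuideReadRecord:
    """One aligned, cell-barcoded guide read."""

    cell_barcode: str
    guide_id: str
    mapq: int
    read_id: str
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cell_barcode:
            raise ValueError("cell_barcode must be non-empty")
        if not np.isfinite(self.mapq) or self.mapq < 0:
            raise ValueError(f"mapq must be a finite non-negative integer, got {self.mapq!r}")


@dataclass(frozen=True)
class GuideAssignment:
    """Assignment outcome for one cell barcode.

    ``status`` is one of ``assigned``, ``ambiguous``, ``unassigned``.
    ``top_reads``/``total_reads`` are deduplicated read counts for the most
    abundant guide and for all guides in the cell.
    """

    cell_barcode: str
    status: str
    guide_id: Optional[str] = None
    top_reads: int = 0
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "ambiguous", "unassigned"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.top_reads > self.total_reads:
            raise ValueError("top_reads cannot exceed total_reads")
        if self.status == "assigned" and self.guide_id is None:
            raise ValueError("assigned cells must carry a guide_id")


def filter_guide_reads(
    records: Sequence[GuideReadRecord], mapq_min: int = DEFAULT_MAPQ_MIN
) -> list[GuideReadRecord]:
    """Retain reads with mapping quality >= ``mapq_min`` (inclusive), order preserved."""
    if mapq_min < 0:
        raise ValueError(f"mapq_min must be >= 0, got {mapq_min}")
    return [r for r in records if r.mapq >= mapq_min]


def count_guides_per_cell(
    records: Iterable[GuideReadRecord], dedup_by_umi: bool = False
) -> pd.DataFrame:
    """Tally deduplicated guide reads per (cell_barcode, guide_id).

    With ``dedup_by_umi`` each unique (cell, guide, UMI) triple counts once,
    collapsing PCR amplicons of the same molecule; otherwise unique read_ids
    count once. Records are assumed MAPQ-filtered already.

    Returns a DataFrame with columns ``cell_barcode``, ``guide_id``,
    ``n_reads`` sorted by (cell_barcode, guide_id).
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if dedup_by_umi:
            if rec.umi is None or rec.umi == "":
                raise ValueError(
                    f"dedup_by_umi requested but read {rec.read_id!r} "
                    f"(cell {rec.cell_barcode!r}) has no UMI"
                )
            key = (rec.cell_barcode, rec.guide_id, rec.umi)
        else:
            key = (rec.cell_barcode, rec.guide_id, rec.read_id)
        if key in seen:
            continue
        seen.add(key)
        cg = (rec.cell_barcode, rec.guide_id)
        counts[cg] = counts.get(cg, 0) + 1
    rows = sorted(counts.items())
    return pd.DataFrame(
        {
            "cell_barcode": [cg[0] for cg, _ in rows],
            "guide_id": [cg[1] for cg, _ in rows],
            "n_reads": [n for _, n in rows],
        }
    )


def _assign_one(
    cell: str,
    guide_counts: Mapping[str, int],
    min_reads: int,
    dominance: float,
) -> GuideAssignment:
    total = int(sum(guide_counts.values()))
    if total == 0 or total < min_reads:
        top = max(guide_counts.values()) if guide_counts else 0
        return GuideAssignment(cell, "unassigned", None, int(top), total)
    top_guide, top = max(guide_counts.items(), key=lambda kv: (kv[1], kv[0]))
    # strict dominance: a tie for the top guide can never pass with >=2 guides
    if top / total > dominance:
        return GuideAssignment(cell, "assigned", top_guide, int(top), total)
    return GuideAssignment(cell, "ambiguous", None, int(top), total)


def assign_guides(
    counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    dominance: float = DEFAULT_DOMINANCE,
    all_cells: Optional[Sequence[str]] = None,
) -> list[GuideAssignment]:
    """Apply the read-floor and dominance rule per cell.

    ``counts`` is the table from :func:`count_guides_per_cell`. Cells listed
    in ``all_cells`` but absent from ``counts`` are reported unassigned with
    zero reads. Negative counts are rejected.
    """
    if not 0.0 < dominance < 1.0:
        raise ValueError(f"dominance must lie in (0, 1), got {dominance}")
    if min_reads < 0:
        raise ValueError(f"min_reads must be >= 0, got {min_reads}")
    if len(counts) and (counts["n_reads"] < 0).any():
        raise ValueError("guide read counts must be non-negative")

    per_cell: dict[str, dict[str, int]] = {}
    for row in counts.itertuples(index=False):
        per_cell.setdefault(row.cell_barcode, {})[row.guide_id] = int(row.n_reads)

    cells = sorted(per_cell)
    if all_cells is not None:
        cells = sorted(set(cells) | set(all_cells))

    return [_assign_one(c, per_cell.get(c, {}), min_reads, dominance) for c in cells]


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``ndigits``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


def summarize_assignment(
    assignments: Sequence[GuideAssignment], n_cells_total: int
) -> dict:
    """Counts and percentages per status, plus per-guide group sizes.

    Percentages are ``100 * count / n_cells_total`` to one decimal; per-guide
    sizes are summarized as mean +/- s.d. (ddof=1) across guides.
    """
    if n_cells_total <= 0:
        raise ValueError("n_cells_total must be positive")
    if n_cells_total < len(assignments):
        raise ValueError("n_cells_total is smaller than the number of assignments")
    status_counts = {"assigned": 0, "ambiguous": 0, "unassigned": 0}
    guide_counts: dict[str, int] = {}
    for a in assignments:
        status_counts[a.status] += 1
        if a.status == "assigned":
            guide_counts[a.guide_id] = guide_counts.get(a.guide_id, 0) + 1
    sizes = np.array(sorted(guide_counts.values()), dtype=float)
    return {
        "n_cells_total": int(n_cells_total),
        "statuses": {
            s: {"count": c, "pct": percentage(c, n_cells_total)}
            for s, c in status_counts.items()
        },
        "per_guide": {
            "n_guides": len(guide_counts),
            "mean": float(sizes.mean()) if sizes.size else 0.0,
            "sd": float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0,
        },
        "guide_counts": dict(sorted(guide_counts.items())),
    }


def assignments_to_frame(assignments: Sequence[GuideAssignment]) -> pd.DataFrame:
    """Tabular view matching the on-disk assignment schema."""
    return pd.DataFrame(
        {
            "cell_barcode": [a.cell_barcode for a in assignments],
            "status": [a.status for a in assignments],
            "guide_id": [a.guide_id if a.guide_id is not None else "" for a in assignments],
            "top_reads": [a.top_reads for a in assignments],
            "total_reads": [a.total_reads for a in assignments],
        }
    )
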