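"""Relative mtDNA copy number from per-cell mitochondrial coverage.

Relative copy number is taken as the mean deduplicated mtDNA read coverage
per cell (total aligned mitochondrial bases divided by mitochondrial genome
length). Coverage is deliberately *not* normalized to total ATAC signal:
total nuclear signal itself rises through S/G2 as nuclear DNA replicates, so
normalizing would erase the cell-cycle trends in mtDNA content that the
coverage readout is meant to expose. A normalized column is emitted
alongside for analyses that want it.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .heteroplasmy import MOUSE_MT_GENOME_LENGTH

logger = logging.getLogger(__name__)

__all__ = [
    "mean_mtdna_coverage",
    "enrichment_fold_change",
    "coverage_table",
    "compare_group_depths",
]


def mean_mtdna_coverage(
    per_base_depth_or_total: Union[int, float, Sequence[float], np.ndarray],
    genome_length: int = MOUSE_MT_GENOME_LENGTH,
) -> float:
    """Mean coverage = total aligned bases / genome length.

    Accepts either a per-base depth vector (summed) or a precomputed total.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    arr = np.asarray(per_base_depth_or_total, dtype=float)
    if np.any(arr < 0):
        raise ValueError("depths must be non-negative")
    total = arr.sum() if arr.ndim > 0 else float(arr)
    return float(total) / genome_length


def enrichment_fold_change(cov_pre: float, cov_post: float) -> float:
    """Fold change in coverage after mtDNA enrichment; NaN when pre-coverage is 0.

    Zero pre-enrichment coverage is flagged (NaN) rather than dropped: cells
    starting below ~2x behave differently under enrichment and deserve
    separate inspection.
    """
    if cov_pre < 0 or cov_post < 0:
        raise ValueError("coverages must be non-negative")
    if cov_pre == 0:
        return float("nan")
    return cov_post / cov_pre


def coverage_table(
    totals: pd.DataFrame, genome_length: int = MOUSE_MT_GENOME_LENGTH
) -> pd.DataFrame:
    """Per-cell coverage profile from a table of total aligned mtDNA bases.

    Input columns: ``cell_barcode``, ``total_mt_bases`` and optionally
    ``nuclear_fragments``. Adds ``mean_coverage`` and, when nuclear fragment
    counts are present, ``normalized_coverage`` (coverage per thousand
    nuclear fragments) for optional use.
    """
    out = totals.copy()
    if (out["total_mt_bases"] < 0).any():
        raise ValueError("total_mt_bases must be non-negative")
    out["mean_coverage"] = out["total_mt_bases"] / genome_length
    if "nuclear_fragments" in out.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["normalized_coverage"] = np.where(
                out["nuclear_fragments"] > 0,
                out["mean_coverage"] / out["nuclear_fragments"] * 1e3,
                np.nan,
            )
    return out


def _log10_with_floor(values: np.ndarray) -> np.ndarray:
    """log10 with zeros floored at half the smallest nonzero value."""
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all coverages are zero; cannot log-transform")
    floor = nonzero.min() / 2.0
    return np.log10(np.where(values > 0, values, floor))


def compare_group_depths(
    profiles: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "mean_coverage",
    log10_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise Welch t-tests on per-cell coverage between groups.

    Each group pair is compared by a two-sided Welch two-sample t-test on
    (optionally log10-transformed) coverage; p-values are Bonferroni-adjusted
    by the number of pairs. Groups with fewer than 2 cells are excluded with
    a warning. Returns one row per pair with group means/medians on the
    original scale.
    """
    groups = {}
    for name, sub in profiles.groupby(group_col):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("group %r has < 2 cells; excluded from comparisons", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 cells")

    pairs = list(combinations(sorted(groups), 2))
    n_pairs = len(pairs)
    rows = []
    for g1, g2 in pairs:
        v1, v2 = groups[g1], groups[g2]
        x1 = _log10_with_floor(v1) if log10_transform else v1
        x2 = _log10_with_floor(v2) if log10_transform else v2
        t, p = stats.ttest_ind(x1, x2, equal_var=False)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "n_1": len(v1),
                "n_2": len(v2),
                "mean_1": float(np.mean(v1)),
                "mean_2": float(np.mean(v2)),
                "median_1": float(np.median(v1)),
                "median_2": float(np.median(v2)),
                "t_statistic": float(t),
                "p_value": float(p),
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)
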