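"""Nuclear transcriptomic response to mtDNA perturbation.

mtDNA depletion changes both nuclear gene expression and the mtDNA-coverage
covariate itself, so the transcriptomic response is quantified on
*residualized* expression: each gene is regressed on per-cell mtDNA copy
number (ordinary least squares, expression_i = b0 + b1 * CN + e) and the
residuals carry the CN-adjusted signal. The top-variable residuals feed a
PCA whose first component (PC1) scores the shared response program; group
scores are compared by rank-based tests, and cell-cycle phase composition by
chi-squared contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .variance import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualModel",
    "PCResult",
    "residualize_expression",
    "select_top_variable",
    "pc_scores",
    "compare_pc1_groups",
    "phase_composition_test",
    "coverage_phase_trend",
]

CELL_CYCLE_PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class ResidualModel:
    """Per-gene OLS of expression on the mtDNA copy-number covariate."""

    beta0: pd.Series
    beta1: pd.Series
    residuals: pd.DataFrame  # cells x genes, same shape as input


@dataclass(frozen=True)
class PCResult:
    loadings: pd.DataFrame        # genes x components
    scores: pd.DataFrame          # cells x components
    explained_variance: np.ndarray


def residualize_expression(expr: pd.DataFrame, covariate: Sequence[float]) -> ResidualModel:
    """Regress every gene on the covariate and return residual expression.

    ``expr`` is a cells x genes matrix of normalized expression; ``covariate``
    is the per-cell mtDNA copy number (coverage), used on the linear scale.
    A constant covariate falls back to intercept-only centering with a
    warning.
    """
    x = np.asarray(covariate, dtype=float)
    if x.size != expr.shape[0]:
        raise ValueError("covariate length must equal the number of cells")
    if expr.shape[0] < 3:
        raise ValueError("need >= 3 cells")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    y = expr.to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        logger.warning("constant covariate: falling back to intercept-only centering")
        beta1 = np.zeros(expr.shape[1])
    else:
        beta1 = (xc @ (y - y.mean(axis=0))) / sxx
    beta0 = y.mean(axis=0) - beta1 * x.mean()
    resid = y - (beta0[None, :] + np.outer(x, beta1))
    return ResidualModel(
        beta0=pd.Series(beta0, index=expr.columns),
        beta1=pd.Series(beta1, index=expr.columns),
        residuals=pd.DataFrame(resid, index=expr.index, columns=expr.columns),
    )


def select_top_variable(residuals: pd.DataFrame, k: int = 2000) -> list[str]:
    """The ``k`` genes with largest residual sample variance (ddof=1).

    Ties at the cutoff are broken by gene identifier order so the selection
    is deterministic. If fewer than ``k`` genes exist, all are kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variances = residuals.var(axis=0, ddof=1)
    if k >= len(variances):
        if k > len(variances):
            logger.warning("requested %d genes but only %d available", k, len(variances))
        return sorted(residuals.columns)
    order = sorted(variances.index, key=lambda g: (-variances[g], g))
    return order[:k]


def pc_scores(
    matrix: pd.DataFrame,
    n_components: int = 2,
    center: bool = True,
    scale: bool = True,
) -> PCResult:
    """PCA of a cells x genes matrix with a deterministic sign convention.

    The matrix is centered and (optionally) unit-scaled per gene;
    zero-variance genes are dropped with a warning when scaling. Loadings are
    unit-norm; each component's sign is fixed so its largest-magnitude
    loading entry is positive. Explained variances use the n-1 denominator.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 cells and >= 2 genes")
    x = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            dropped = [c for c, k in zip(cols, keep) if not k]
            logger.warning("dropping %d zero-variance genes before scaled PCA: %s",
                           len(dropped), dropped[:5])
            x = x[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        x = (x - x.mean(axis=0)) / sd
    elif center:
        x = x - x.mean(axis=0)
    max_rank = min(x.shape[0] - (1 if center or scale else 0), x.shape[1])
    n_components = min(n_components, max_rank)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # genes x components, unit-norm columns
    # sign convention: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCResult(
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance=pca.explained_variance_.copy(),
    )


def compare_pc1_groups(
    scores: pd.Series,
    groups: pd.Series,
    reference: str,
    paired: bool = False,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Rank-based comparison of each group's PC1 scores against a reference.

    Independent groups are compared with a two-sided Mann-Whitney rank-sum
    test (``paired=True`` switches to the Wilcoxon signed-rank test for
    genuinely paired designs). p-values are Benjamini-Hochberg adjusted
    across groups. Groups smaller than ``min_group_size`` are skipped with a
    warning.
    """
    ref = scores[groups == reference].to_numpy(dtype=float)
    if ref.size == 0:
        raise ValueError(f"reference group {reference!r} is empty")
    rows = []
    for name in sorted(set(groups) - {reference}):
        vals = scores[groups == name].to_numpy(dtype=float)
        if vals.size < min_group_size:
            logger.warning("group %r has %d cells (< %d); skipped", name, vals.size, min_group_size)
            continue
        if paired:
            if vals.size != ref.size:
                raise ValueError("paired mode requires equal group sizes")
            res = stats.wilcoxon(vals, ref)
        else:
            res = stats.mannwhitneyu(vals, ref, alternative="two-sided")
        rows.append(
            {
                "group": name,
                "n": int(vals.size),
                "n_reference": int(ref.size),
                "median": float(np.median(vals)),
                "median_reference": float(np.median(ref)),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows, columns=[
        "group", "n", "n_reference", "median", "median_reference", "statistic", "p_value",
    ])
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


def phase_composition_test(phases: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Chi-squared test of cell-cycle phase composition per group vs all others.

    For each group, a 2 x 3 contingency table (group vs rest, phases G1/S/G2M)
    is tested by Pearson chi-squared (no continuity correction); p-values are
    BH-adjusted across groups. Rows where any expected count falls below 1
    carry ``low_expected=True``. Output row order is by group name,
    independent of input order.
    """
    bad = set(phases) - set(CELL_CYCLE_PHASES)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    phases = phases.reset_index(drop=True)
    groups = groups.reset_index(drop=True)
    rows = []
    for name in sorted(set(groups)):
        in_group = (groups == name).to_numpy()
        table = np.array(
            [
                [(phases[in_group] == ph).sum() for ph in CELL_CYCLE_PHASES],
                [(phases[~in_group] == ph).sum() for ph in CELL_CYCLE_PHASES],
            ],
            dtype=float,
        )
        # drop phases absent everywhere to keep the test well-defined
        present = table.sum(axis=0) > 0
        chi2, p, _, expected = stats.chi2_contingency(table[:, present], correction=False)
        n_group = int(in_group.sum())
        row = {
            "group": name,
            "n": n_group,
            "chi2": float(chi2),
            "p_value": float(p),
            "low_expected": bool(np.any(expected < 1)),
        }
        for j, ph in enumerate(CELL_CYCLE_PHASES):
            row[f"prop_{ph}"] = float(table[0, j] / n_group) if n_group else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def coverage_phase_trend(
    profiles: pd.DataFrame,
    coverage_col: str = "mean_coverage",
    phase_col: str = "phase",
    pseudotime_col: Optional[str] = None,
    n_pseudo_bins: int = 20,
) -> dict:
    """mtDNA coverage across cell-cycle phases and (optionally) pseudotime.

    Returns per-phase mean coverage with a one-way ANOVA p-value and, when a
    pseudotime column in [0, 2*pi) is present, per-bin mean coverage over
    equal-width pseudotime bins. mtDNA replicates continuously ("relaxed"
    replication), so coverage rising smoothly through the cycle is the
    expected signature.
    """
    out: dict = {}
    if phase_col in profiles.columns:
        grouped = [
            (name, sub[coverage_col].to_numpy(dtype=float))
            for name, sub in profiles.groupby(phase_col)
            if len(sub) > 0
        ]
        if len(grouped) < 2:
            raise ValueError("need >= 2 cell-cycle phases for the phase contrast")
        _, p = stats.f_oneway(*[v for _, v in grouped])
        out["phase_means"] = {name: float(v.mean()) for name, v in grouped}
        out["anova_p"] = float(p)
    if pseudotime_col is not None and pseudotime_col in profiles.columns:
        t = profiles[pseudotime_col].to_numpy(dtype=float)
        if np.any(t < 0) or np.any(t >= 2 * np.pi):
            raise ValueError("pseudotime must lie in [0, 2*pi)")
        edges = np.linspace(0, 2 * np.pi, n_pseudo_bins + 1)
        which = np.clip(np.digitize(t, edges) - 1, 0, n_pseudo_bins - 1)
        cov = profiles[coverage_col].to_numpy(dtype=float)
        means = [
            float(cov[which == b].mean()) if np.any(which == b) else np.nan
            for b in range(n_pseudo_bins)
        ]
        out["pseudotime_bin_centers"] = ((edges[:-1] + edges[1:]) / 2).tolist()
        out["pseudotime_bin_means"] = means
    if not out:
        raise ValueError("profiles carry neither a phase nor a pseudotime column")
    return out
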