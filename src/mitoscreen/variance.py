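"""Heteroplasmy-variance modeling under read-depth bottlenecks.

Sequencing a cell's mtDNA at finite depth is a sampling bottleneck: the
observed heteroplasmy is a binomial draw around the true fraction, so groups
of cells with lower read depth show inflated heteroplasmy variance even when
the underlying biology is unchanged. This module provides

* a depth-matched binomial resampling null (:func:`simulate_bottleneck_null`)
  that asks whether a perturbed group's variance exceeds what its own depth
  distribution predicts from control cells,
* the closed-form expectation of that null
  (Var(h-hat) = Var(h) + E[h(1-h)] * E[1/depth]),
* equal-count depth binning and quantile regression of
  Variance = beta0 + beta1/depth at the 5th/95th percentiles with bootstrap
  confidence bands,
* an accuracy simulation drawing finite mtDNA pools (hypergeometric
  subsampling) to show how call accuracy grows with depth, and
* the supporting statistics: Brown-Forsythe variance test, Holm and
  Benjamini-Hochberg adjustments, and add-one two-sided empirical p-values.

The bottleneck null uses *binomial* sampling (reads drawn with replacement
from an effectively infinite molecule pool), while the accuracy simulation
subsamples a finite pool of N molecules *without* replacement
(hypergeometric); the two regimes model sequencing reads and molecule
partitioning respectively and are kept distinct on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SimulationConfig",
    "BottleneckNull",
    "DepthBin",
    "QuantileFit",
    "BootstrapBand",
    "brown_forsythe_test",
    "holm_adjust",
    "bh_adjust",
    "empirical_two_sided_p",
    "expected_sampled_variance",
    "simulate_bottleneck_null",
    "bin_equal_count",
    "fit_depth_variance_quantiles",
    "bootstrap_variance_band",
    "simulate_sampling_accuracy",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the heteroplasmy-sampling accuracy simulation.

    Defaults are the measured study conditions: a population of 2,000 cells
    with true heteroplasmy ~ Normal(0.582, 0.113) clipped to [0, 1], an mtDNA
    copy number of 1,750 molecules per cell, and subsample sizes 5/20/50/100.
    """

    n_cells: int = 2000
    true_mean: float = 0.582
    true_sd: float = 0.113
    copy_number: int = 1750
    sample_sizes: tuple[int, ...] = (5, 20, 50, 100)
    n_sims: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_mean < 1.0:
            raise ValueError("true_mean must lie in (0, 1)")
        if self.true_sd <= 0:
            raise ValueError("true_sd must be positive")
        if self.copy_number < max(self.sample_sizes):
            raise ValueError("copy_number must be >= every sample size")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass(frozen=True)
class BottleneckNull:
    """Null distribution of group heteroplasmy variances under depth matching."""

    observed_variance: float
    null_variances: np.ndarray
    p_empirical: float
    p_adjusted: float = field(default=np.nan)

    @property
    def n_sims(self) -> int:
        return len(self.null_variances)


@dataclass(frozen=True)
class DepthBin:
    n_cells: int
    mean_depth: float
    het_variance: float

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("a depth bin needs >= 2 cells")
        if self.het_variance < 0:
            raise ValueError("variance cannot be negative")


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    beta0: float
    beta1: float
    pinball_loss: float

    def predict(self, depth: np.ndarray) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        return self.beta0 + self.beta1 / depth


@dataclass(frozen=True)
class BootstrapBand:
    depth_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    tau: float
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------
# supporting statistics

def brown_forsythe_test(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe test for equality of group variances.

    Each value is transformed to its absolute deviation from the group
    median, and a one-way ANOVA F is run on the transformed values; the F
    statistic is the Brown-Forsythe W. If every transformed value is zero
    (identical spread and no within-group deviation), W = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    transformed = [np.abs(a - np.median(a)) for a in arrays]
    if all(np.all(t == 0) for t in transformed):
        return 0.0, 1.0
    f, p = stats.f_oneway(*transformed)
    return float(f), float(p)


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    arr = np.asarray(pvals, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr))):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-down Holm (Bonferroni-Holm) adjusted p-values, original order."""
    arr = _check_pvals(pvals)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, original order."""
    arr = _check_pvals(pvals)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def empirical_two_sided_p(null: np.ndarray, observed: float) -> float:
    """Two-sided add-one empirical p-value of ``observed`` against ``null``.

    p = min(1, 2 * min((1 + #{null <= obs})/(S+1), (1 + #{null >= obs})/(S+1))).
    The add-one correction keeps p strictly positive and honest for finite S.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    s = null.size
    lo = (1 + np.sum(null <= observed)) / (s + 1)
    hi = (1 + np.sum(null >= observed)) / (s + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def expected_sampled_variance(
    true_var: float, mean_h: float, depth_distribution: Sequence[float]
) -> float:
    """Closed-form expected variance of depth-sampled heteroplasmy.

    By the binomial law of total variance, for h-hat = Binomial(n, h)/n with
    h drawn from a distribution with mean ``mean_h`` and variance
    ``true_var``:

        Var(h-hat) = Var(h) + (E[h](1-E[h]) - Var(h)) * E[1/n]
    """
    if not 0.0 < mean_h < 1.0:
        raise ValueError("mean_h must lie strictly inside (0, 1)")
    depths = np.asarray(depth_distribution, dtype=float)
    if np.any(depths < 1):
        raise ValueError("depths must be >= 1")
    mean_inv_n = float(np.mean(1.0 / depths))
    return float(true_var + (mean_h * (1.0 - mean_h) - true_var) * mean_inv_n)


# ---------------------------------------------------------------------------
# depth-matched bottleneck null

def simulate_bottleneck_null(
    control_het: Sequence[float],
    kd_depths: Sequence[int],
    n_kd: int,
    observed_variance: Optional[float] = None,
    n_sims: int = 5000,
    seed: int = 0,
) -> BottleneckNull:
    """Null distribution of group variance from depth-matched binomial resampling.

    Each simulation draws ``n_kd`` control cells without replacement, assigns
    each a depth drawn with replacement from the perturbed group's depths,
    simulates an alternate-allele count Binomial(depth, control h), and
    records the sample variance (ddof=1) of the simulated heteroplasmies.
    ``observed_variance`` defaults to NaN with p NaN if not given.
    """
    h = np.asarray(control_het, dtype=float)
    depths_pool = np.asarray(kd_depths, dtype=np.int64)
    if np.any(depths_pool < 1):
        raise ValueError("all perturbed-group depths must be >= 1")
    if n_kd > h.size:
        raise ValueError(f"n_kd = {n_kd} exceeds control pool of {h.size} cells")
    if n_kd < 2:
        raise ValueError("n_kd must be >= 2 to define a variance")
    rng = np.random.default_rng(seed)

    # without-replacement subsets for all simulations at once: the n_kd
    # smallest of i.i.d. uniforms per row index a uniform random subset
    u = rng.random((n_sims, h.size))
    idx = np.argpartition(u, n_kd - 1, axis=1)[:, :n_kd]
    probs = h[idx]
    depths = rng.choice(depths_pool, size=(n_sims, n_kd), replace=True)
    alt = rng.binomial(depths, probs)
    sim_h = alt / depths
    null_vars = sim_h.var(axis=1, ddof=1)

    if observed_variance is None:
        return BottleneckNull(float("nan"), null_vars, float("nan"))
    p = empirical_two_sided_p(null_vars, observed_variance)
    return BottleneckNull(float(observed_variance), null_vars, p)


# ---------------------------------------------------------------------------
# depth binning and quantile regression

def bin_equal_count(
    depths: Sequence[float], het: Sequence[float], n_bins: int
) -> list[DepthBin]:
    """Partition cells into contiguous equal-count depth bins.

    Cells are sorted by depth ascending and split into ``n_bins`` contiguous
    bins; when the count is not divisible, the lowest-depth bins each take
    one extra cell. Each bin reports its mean depth and the sample variance
    (ddof=1) of heteroplasmy.
    """
    d = np.asarray(depths, dtype=float)
    h = np.asarray(het, dtype=float)
    if d.size != h.size:
        raise ValueError("depths and heteroplasmy vectors differ in length")
    if d.size < 2 * n_bins:
        raise ValueError(f"need >= {2 * n_bins} cells for {n_bins} bins of >= 2")
    order = np.argsort(d, kind="stable")
    d, h = d[order], h[order]
    base, extra = divmod(d.size, n_bins)
    sizes = [base + 1 if i < extra else base for i in range(n_bins)]
    bins = []
    start = 0
    for size in sizes:
        sl = slice(start, start + size)
        bins.append(
            DepthBin(
                n_cells=size,
                mean_depth=float(d[sl].mean()),
                het_variance=float(h[sl].var(ddof=1)),
            )
        )
        start += size
    return bins


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Check loss rho_tau(u) = u * (tau - 1{u < 0}), summed."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _fit_quantile_1overd(x_inv: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact pinball-loss minimizer of y ~ b0 + b1 * x_inv via linear programming.

    minimize sum(tau*u + (1-tau)*v) s.t. y - b0 - b1*x = u - v, u,v >= 0.
    The LP formulation finds an exact optimum (zero loss on zero-residual
    designs) where iterative solvers stall.
    """
    n = y.size
    # variables: [b0+, b0-, b1+, b1-, u (n), v (n)]
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    a_eq = np.zeros((n, 4 + 2 * n))
    a_eq[:, 0] = 1.0
    a_eq[:, 1] = -1.0
    a_eq[:, 2] = x_inv
    a_eq[:, 3] = -x_inv
    a_eq[:, 4:4 + n] = np.eye(n)
    a_eq[:, 4 + n:] = -np.eye(n)
    res = optimize.linprog(c, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    b0 = res.x[0] - res.x[1]
    b1 = res.x[2] - res.x[3]
    return float(b0), float(b1)


def fit_depth_variance_quantiles(
    bins: Sequence[DepthBin], taus: Sequence[float] = (0.05, 0.95)
) -> list[QuantileFit]:
    """Quantile fits of bin variance on 1/depth: Variance = beta0 + beta1/depth.

    The depth-dependent component of heteroplasmy variance scales as
    1/depth; the intercept absorbs the true biological variance, which does
    not vanish at infinite depth. Each tau is fit by minimizing the pinball
    loss exactly (LP).
    """
    if len(bins) < 3:
        raise ValueError("need >= 3 bins to fit")
    depths = np.array([b.mean_depth for b in bins], dtype=float)
    if np.any(depths <= 0):
        raise ValueError("bin depths must be positive")
    if np.allclose(depths, depths[0]):
        raise ValueError("all bin depths equal: design is collinear")
    y = np.array([b.het_variance for b in bins], dtype=float)
    x_inv = 1.0 / depths
    fits = []
    for tau in taus:
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        b0, b1 = _fit_quantile_1overd(x_inv, y, tau)
        loss = pinball_loss(y - (b0 + b1 * x_inv), tau)
        fits.append(QuantileFit(tau=float(tau), beta0=b0, beta1=b1, pinball_loss=loss))
    return fits


def bootstrap_variance_band(
    bins: Sequence[DepthBin],
    tau: float,
    n_boot: int = 200,
    seed: int = 0,
    depth_grid: Optional[np.ndarray] = None,
    max_redraws: int = 10,
) -> BootstrapBand:
    """95% pointwise bootstrap band for the tau-quantile variance-depth curve.

    Bins are resampled with replacement (same count) ``n_boot`` times and the
    quantile fit repeated; the band is the pointwise 2.5/97.5 percentile of
    the fitted curves over ``depth_grid``. A degenerate replicate (all bin
    depths equal) is redrawn up to ``max_redraws`` times.
    """
    if len(bins) < 3:
        raise ValueError("need >= 3 bins")
    rng = np.random.default_rng(seed)
    depths = np.array([b.mean_depth for b in bins], dtype=float)
    if depth_grid is None:
        depth_grid = np.linspace(depths.min(), depths.max(), 50)
    depth_grid = np.asarray(depth_grid, dtype=float)
    curves = np.empty((n_boot, depth_grid.size))
    for i in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, len(bins), size=len(bins))
            resampled = [bins[j] for j in idx]
            d = np.array([b.mean_depth for b in resampled])
            if not np.allclose(d, d[0]):
                break
        else:
            raise RuntimeError("bootstrap replicate degenerate after max redraws")
        fit = fit_depth_variance_quantiles(resampled, taus=[tau])[0]
        curves[i] = fit.predict(depth_grid)
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    return BootstrapBand(depth_grid, lower, upper, float(tau), int(n_boot), int(seed))


# ---------------------------------------------------------------------------
# accuracy-of-calling simulation

def simulate_sampling_accuracy(
    config: SimulationConfig,
    depth_distribution: Optional[Sequence[int]] = None,
) -> dict:
    """Simulate heteroplasmy calling accuracy at fixed subsample sizes.

    Each cell receives a true heteroplasmy ~ Normal(mu, sigma) clipped to
    [0, 1] and a finite pool of N molecules with round(h*N) mutant copies.
    For each sample size n, n molecules are drawn without replacement
    (hypergeometric) and the sampled heteroplasmy is their mutant fraction.
    Per sample size, an ordinary least-squares regression of sampled on true
    heteroplasmy is reported with its R^2.

    If ``depth_distribution`` is given (matched-population mode), each cell
    is instead sampled once at a depth drawn from that empirical
    distribution (capped at N), and a single table is returned under the key
    ``"matched"``.
    """
    rng = np.random.default_rng(config.seed)
    true_h = np.clip(
        rng.normal(config.true_mean, config.true_sd, size=config.n_cells), 0.0, 1.0
    )
    n_mutant = np.rint(true_h * config.copy_number).astype(np.int64)
    n_wt = config.copy_number - n_mutant

    def sample_at(depths: np.ndarray) -> np.ndarray:
        drawn = rng.hypergeometric(n_mutant, n_wt, depths)
        return drawn / depths

    tables: dict = {"true_h": true_h, "per_size": {}, "fits": {}}
    if depth_distribution is not None:
        depths = rng.choice(np.asarray(depth_distribution, dtype=np.int64), config.n_cells)
        depths = np.minimum(depths, config.copy_number)
        if np.any(depths < 1):
            raise ValueError("depths must be >= 1")
        sampled = sample_at(depths)
        tables["matched"] = pd.DataFrame(
            {"true_h": true_h, "sampled_h": sampled, "depth": depths}
        )
        return tables

    for n in config.sample_sizes:
        if n > config.copy_number:
            raise ValueError(f"sample size {n} exceeds copy number {config.copy_number}")
        sampled = sample_at(np.full(config.n_cells, n, dtype=np.int64))
        fit = stats.linregress(true_h, sampled)
        tables["per_size"][n] = pd.DataFrame({"true_h": true_h, "sampled_h": sampled})
        tables["fits"][n] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
        }
    return tables
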