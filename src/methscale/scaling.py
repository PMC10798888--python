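"""Power-law inference: log-log regression, threshold scan, KDE mode.

The cumulative rate-ratio series y_i of the chain satisfies
``log(y_i) = s * (log(l_i) - log(l_0))`` when rates follow ``rate ∝ l**s``,
so an OLS of log10(cumulative ratio) on log10(maximum lifespan) estimates
the scaling exponent s. The CpG-selection R-squared threshold is a free
parameter; a grid of thresholds is scanned and the final scaling is the mode
of a Gaussian kernel density over the per-threshold exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFitError,
    InsufficientCpGsError,
    InsufficientDataError,
)
from .rates import build_comparison_chain, evaluate_chain
from .types import MethylationDataset, ScalingFit, ScalingSeries, SpeciesTraitTable

__all__ = [
    "fit_scaling_law",
    "scan_r2_thresholds",
    "select_optimal_scaling_kde",
    "estimate_scaling_law",
    "ThresholdScan",
    "ScalingEstimate",
    "DEFAULT_R2_GRID",
]

#: Default CpG-selection threshold grid: 0 to 0.2 in steps of 0.01.
DEFAULT_R2_GRID = np.round(np.arange(0.0, 0.2000001, 0.01), 10)

#: Number of evaluation points for the KDE mode search.
KDE_GRID_POINTS = 10_001


def _loglog_ols(
    x: np.ndarray, y: np.ndarray, r2_threshold: float | None = None
) -> ScalingFit:
    """Closed-form OLS of log10(y) on log10(x) with a t-based 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 points for a scaling fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log regression requires positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    dx = lx - lx.mean()
    sxx = float(dx @ dx)
    if sxx == 0:
        raise DegenerateFitError("regressor has zero variance")
    dy = ly - ly.mean()
    slope = float(dx @ dy) / sxx
    intercept = float(ly.mean() - slope * lx.mean())
    ss_res = float(dy @ dy) - slope * float(dx @ dy)
    ss_res = max(ss_res, 0.0)
    syy = float(dy @ dy)
    r2 = 0.0 if syy == 0 else 1.0 - ss_res / syy
    stderr = np.sqrt(ss_res / (n - 2) / sxx)
    half_width = stats.t.ppf(0.975, n - 2) * stderr
    return ScalingFit(
        exponent=slope,
        intercept=intercept,
        ci_low=slope - half_width,
        ci_high=slope + half_width,
        r_squared=r2,
        n_species=n,
        stderr=float(stderr),
        r2_threshold=r2_threshold,
    )


def fit_scaling_law(
    series: ScalingSeries, r2_threshold: float | None = None
) -> ScalingFit:
    """Fit the power law rate ∝ lifespan**s to a cumulative-ratio series.

    The baseline species contributes the point (log10 lifespan, 0). Requires
    at least 3 species with positive cumulative ratios and lifespans.
    """
    return _loglog_ols(
        series.max_lifespans, series.cumulative_ratios, r2_threshold
    )


@dataclass
class ThresholdScan:
    """Per-threshold chain evaluations over the R-squared grid.

    ``fits[i]``/``series[i]`` are None where the threshold was invalid (some
    comparison selected fewer than ``min_cpgs`` CpGs).
    """

    thresholds: np.ndarray
    fits: list[ScalingFit | None]
    series: list[ScalingSeries | None] = field(repr=False, default_factory=list)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([f is not None for f in self.fits])

    @property
    def valid_exponents(self) -> np.ndarray:
        return np.array([f.exponent for f in self.fits if f is not None])

    @property
    def valid_thresholds(self) -> np.ndarray:
        return self.thresholds[self.valid_mask]


def scan_r2_thresholds(
    panels: dict[str, MethylationDataset],
    traits: SpeciesTraitTable,
    grid: np.ndarray | None = None,
    min_cpgs: int = 10,
    direction: str | None = None,
) -> ThresholdScan:
    """Run the chain + scaling fit at every threshold of the grid.

    The chain (ordering, matching, inclusion, per-CpG fits) is built once;
    only CpG selection varies with the threshold. Raises
    :class:`InsufficientDataError` if every threshold is invalid.
    """
    grid = DEFAULT_R2_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1) or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending within [0, 1]")
    chain = build_comparison_chain(panels, traits)

    fits: list[ScalingFit | None] = []
    all_series: list[ScalingSeries | None] = []
    for threshold in grid:
        try:
            series = evaluate_chain(chain, threshold, min_cpgs, direction)
            fits.append(fit_scaling_law(series, r2_threshold=float(threshold)))
            all_series.append(series)
        except (InsufficientCpGsError, InsufficientDataError):
            fits.append(None)
            all_series.append(None)
    if not any(f is not None for f in fits):
        raise InsufficientDataError(
            "every R2 threshold was invalid (too few CpGs in some comparison)"
        )
    return ThresholdScan(thresholds=grid, fits=fits, series=all_series)


def select_optimal_scaling_kde(exponents: np.ndarray) -> float:
    """Mode of a Gaussian KDE (Scott bandwidth) over per-threshold exponents.

    The density is evaluated on a uniform 10,001-point grid spanning
    [min - 3h, max + 3h] with h the bandwidth; the argmax is returned. A
    single or degenerate sample returns its value directly.
    """
    exponents = np.asarray(exponents, dtype=float)
    if exponents.size == 0:
        raise InsufficientDataError("no exponents to select from")
    if exponents.size == 1 or np.ptp(exponents) == 0:
        return float(exponents[0])
    kde = stats.gaussian_kde(exponents)  # Scott's rule
    bandwidth = kde.factor * exponents.std(ddof=1)
    grid = np.linspace(
        exponents.min() - 3 * bandwidth,
        exponents.max() + 3 * bandwidth,
        KDE_GRID_POINTS,
    )
    density = kde(grid)
    return float(grid[np.argmax(density)])


@dataclass
class ScalingEstimate:
    """Final result of the primary pipeline.

    ``optimal_exponent`` is the KDE density mode over valid per-threshold
    exponents; ``fit``/``series`` are the chain evaluation at the valid grid
    threshold whose exponent lies closest to that mode.
    """

    optimal_exponent: float
    selected_threshold: float
    fit: ScalingFit
    series: ScalingSeries
    scan: ThresholdScan = field(repr=False)


def estimate_scaling_law(
    panels: dict[str, MethylationDataset],
    traits: SpeciesTraitTable,
    grid: np.ndarray | None = None,
    min_cpgs: int = 10,
    direction: str | None = None,
) -> ScalingEstimate:
    """Threshold scan + KDE mode selection: the primary analysis endpoint."""
    scan = scan_r2_thresholds(panels, traits, grid, min_cpgs, direction)
    optimal = select_optimal_scaling_kde(scan.valid_exponents)
    valid_idx = np.flatnonzero(scan.valid_mask)
    best = valid_idx[
        np.argmin(
            [abs(scan.fits[i].exponent - optimal) for i in valid_idx]
        )
    ]
    return ScalingEstimate(
        optimal_exponent=optimal,
        selected_threshold=float(scan.thresholds[best]),
        fit=scan.fits[best],
        series=scan.series[best],
        scan=scan,
    )
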