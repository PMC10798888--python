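"""Pairwise age-range-matched methylation-rate comparison chain.

Comparing per-CpG regression slopes across species with very different
sampled age ranges is biased: beta values are bounded in [0, 1] (long-lived
species plateau) and R-squared selection favours slow sites in long-lived
species. The chain estimator avoids this by ordering species by maximum
observed age and comparing neighbours over matched age ranges only:

1. order species ascending by maximum (re-referenced) sample age;
2. for each neighbouring pair, trim both panels to a common maximum age
   (within a tolerance of min(2% of the shorter species' lifespan, 1 year));
3. drop species with too few samples or poor lifespan coverage;
4. fit per-CpG rates on the matched data, keep CpGs age-related in both
   species with the same drift direction and mid-range mean methylation;
5. take the median of per-CpG slope ratios (longer / shorter);
6. chain medians by cumulative product: each species' rate relative to the
   baseline (shortest-sampled) species.

Because the per-pair ratios telescope, the cumulative product estimates each
species' rate relative to the baseline even though no two distant species
are ever compared directly.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    InsufficientCpGsError,
    InsufficientDataError,
)
from .types import (
    CpGRateFit,
    MethylationDataset,
    PairwiseComparison,
    ScalingSeries,
    SpeciesTraitTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "fit_cpg_rate",
    "fit_panel_rates",
    "order_species",
    "match_age_ranges",
    "MatchedRanges",
    "apply_inclusion_filters",
    "FilterResult",
    "select_common_age_related_cpgs",
    "median_rate_ratio",
    "build_comparison_chain",
    "evaluate_chain",
    "chain_comparisons",
    "ComparisonChain",
]

#: Inclusion thresholds from the primary analysis: species need >= 20 samples
#: initially, >= 15 after any pairwise restriction, and a maximum sampled age
#: of at least 25% of the reported maximum lifespan.
MIN_INITIAL_SAMPLES = 20
MIN_RESTRICTED_SAMPLES = 15
MIN_LIFESPAN_COVERAGE = 0.25

#: Minimum non-missing samples for a per-CpG regression.
MIN_FIT_SAMPLES = 3

#: Mean-methylation bounds: CpGs averaging outside [0.1, 0.9] after trimming
#: are excluded as boundary-adjacent (plateau-prone).
MEAN_METH_BOUNDS = (0.1, 0.9)


# ---------------------------------------------------------------------------
# per-CpG regression

def fit_cpg_rate(
    ages: np.ndarray, betas: np.ndarray, cpg_id: str = ""
) -> CpGRateFit:
    """Simple linear regression of methylation proportion on age for one CpG.

    Missing betas (NaN) are dropped pairwise. Requires at least 3 usable
    pairs (:class:`InsufficientDataError`) and non-constant ages
    (:class:`DegenerateFitError`).
    """
    ages = np.asarray(ages, dtype=float)
    betas = np.asarray(betas, dtype=float)
    keep = np.isfinite(betas)
    x, y = ages[keep], betas[keep]
    n = len(x)
    if n < MIN_FIT_SAMPLES:
        raise InsufficientDataError(f"{cpg_id or 'CpG'}: fewer than 3 pairs")
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sxx = float(dx @ dx)
    if sxx == 0:
        raise DegenerateFitError(f"{cpg_id or 'CpG'}: ages have zero variance")
    sxy = float(dx @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    ss_res = syy - slope * sxy
    r2 = 0.0 if syy == 0 else min(max(1.0 - ss_res / syy, 0.0), 1.0)
    return CpGRateFit(
        cpg_id=cpg_id,
        slope=slope,
        intercept=my - slope * mx,
        r_squared=r2,
        mean_methylation=float(my),
        n_samples=n,
    )


def fit_panel_rates(
    dataset: MethylationDataset, min_samples: int = MIN_FIT_SAMPLES
) -> pd.DataFrame:
    """Vectorized per-CpG OLS of beta on age for a whole panel.

    Returns a DataFrame indexed by cpg_id with columns slope, intercept,
    r_squared, mean_methylation, n and valid; CpGs with fewer than
    ``min_samples`` non-missing values or degenerate ages are marked invalid
    (NaN statistics).
    """
    x = dataset.ages
    B = dataset.betas
    mask = np.isfinite(B)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(mask, x[None, :], 0.0).sum(axis=1) / n
        my = np.where(mask, B, 0.0).sum(axis=1) / n
        dx = np.where(mask, x[None, :] - mx[:, None], 0.0)
        dy = np.where(mask, B - my[:, None], 0.0)
        sxx = (dx * dx).sum(axis=1)
        sxy = (dx * dy).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        valid = (n >= min_samples) & (sxx > 0)
        slope = np.where(valid, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        ss_res = syy - slope * sxy
        r2 = np.where(syy > 0, 1.0 - ss_res / syy, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": my - slope * mx,
            "r_squared": np.where(valid, r2, np.nan),
            "mean_methylation": np.where(n > 0, my, np.nan),
            "n": n,
            "valid": valid,
        },
        index=pd.Index(dataset.cpg_ids, name="cpg_id"),
    )
    return out


# ---------------------------------------------------------------------------
# ordering, matching, inclusion

def order_species(datasets: Sequence[MethylationDataset]) -> list[str]:
    """Species ids ascending by maximum sample age; ties break
    lexicographically. The first species is the baseline."""
    for ds in datasets:
        if ds.n_samples == 0:
            raise InsufficientDataError(f"{ds.species_id}: empty panel")
    return [
        ds.species_id
        for ds in sorted(datasets, key=lambda d: (d.max_age, d.species_id))
    ]


@dataclass
class MatchedRanges:
    """Result of age-range matching: both panels trimmed to matched maxima."""

    shorter: MethylationDataset
    longer: MethylationDataset
    matched_max_age_shorter: float
    matched_max_age_longer: float
    tolerance: float


def match_age_ranges(
    shorter: MethylationDataset,
    longer: MethylationDataset,
    shorter_lifespan: float,
) -> MatchedRanges | None:
    """Trim two panels to a common maximum sample age.

    Starting from the shorter-observed species' maximum sample age A, find
    the longer species' sample age closest to A (above or below). If the gap
    exceeds min(2% of the shorter species' lifespan, 1 year), retry with the
    shorter species' next-oldest distinct age. Returns None when no candidate
    matches (the pair is skipped upstream).
    """
    tolerance = min(0.02 * shorter_lifespan, 1.0)
    longer_ages = longer.ages
    for a_short in np.unique(shorter.ages)[::-1]:
        gaps = np.abs(longer_ages - a_short)
        best_gap = gaps.min()
        if best_gap <= tolerance:
            # tie-break deterministically on the smaller candidate age
            a_long = float(longer_ages[gaps == best_gap].min())
            return MatchedRanges(
                shorter=shorter.subset_samples(shorter.ages <= a_short),
                longer=longer.subset_samples(longer_ages <= a_long),
                matched_max_age_shorter=float(a_short),
                matched_max_age_longer=a_long,
                tolerance=tolerance,
            )
    return None


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None


def apply_inclusion_filters(
    dataset: MethylationDataset,
    traits: SpeciesTraitTable,
    initial_n: int,
) -> FilterResult:
    """Species-level inclusion rules, applied to a (possibly restricted)
    panel: >= 20 samples initially, >= 15 after restriction, and a maximum
    sampled age (on the raw, pre-re-referencing scale) of at least 25% of
    the reported maximum lifespan. All boundaries are inclusive.
    """
    if initial_n < MIN_INITIAL_SAMPLES:
        return FilterResult(False, "min_initial_samples")
    if dataset.n_samples < MIN_RESTRICTED_SAMPLES:
        return FilterResult(False, "min_samples_after_restriction")
    t = traits[dataset.species_id]
    raw_max_age = dataset.max_age + t.age_sexual_maturity
    if raw_max_age < MIN_LIFESPAN_COVERAGE * t.max_lifespan:
        return FilterResult(False, "lifespan_coverage")
    return FilterResult(True)


# ---------------------------------------------------------------------------
# CpG selection and ratios

def select_common_age_related_cpgs(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    r2_threshold: float,
    direction: str | None = None,
) -> np.ndarray:
    """Common age-related CpGs for a matched pair.

    A CpG is kept iff it has a valid fit in both species, R-squared at or
    above the threshold in both, the same non-zero slope sign in both, and
    mean methylation within [0.1, 0.9] in both. ``direction`` optionally
    restricts to hypermethylating ('hyper') or hypomethylating ('hypo')
    sites. The empty set is allowed; callers decide.
    """
    if fits_a.index.equals(fits_b.index):
        common, a, b = fits_a.index, fits_a, fits_b
    else:
        common = fits_a.index.intersection(fits_b.index)
        a = fits_a.loc[common]
        b = fits_b.loc[common]
    lo, hi = MEAN_METH_BOUNDS
    sign_a = np.sign(a["slope"].to_numpy())
    sign_b = np.sign(b["slope"].to_numpy())
    keep = (
        a["valid"].to_numpy()
        & b["valid"].to_numpy()
        & (a["r_squared"].to_numpy() >= r2_threshold)
        & (b["r_squared"].to_numpy() >= r2_threshold)
        & (sign_a == sign_b)
        & (sign_a != 0)
        & (a["mean_methylation"].to_numpy() >= lo)
        & (a["mean_methylation"].to_numpy() <= hi)
        & (b["mean_methylation"].to_numpy() >= lo)
        & (b["mean_methylation"].to_numpy() <= hi)
    )
    if direction is not None:
        if direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper', 'hypo' or None")
        keep &= sign_a > 0 if direction == "hyper" else sign_a < 0
    return common.to_numpy()[keep]


def median_rate_ratio(
    fits_shorter: pd.DataFrame,
    fits_longer: pd.DataFrame,
    selected: np.ndarray,
    shorter_species: str = "",
    longer_species: str = "",
    matched_max_age_shorter: float = float("nan"),
    matched_max_age_longer: float = float("nan"),
    tolerance: float = float("nan"),
) -> PairwiseComparison:
    """Per-CpG slope ratios (longer / shorter) and their median.

    Ratios are positive because selection enforces a shared non-zero slope
    sign. The median uses the midpoint convention for even counts; it was
    preferred over the mean, which explodes when a shorter-species slope is
    tiny.
    """
    selected = np.asarray(selected)
    if selected.size == 0:
        raise InsufficientCpGsError(
            f"{shorter_species} vs {longer_species}: no CpGs selected"
        )
    s_short = fits_shorter.loc[selected, "slope"].to_numpy()
    s_long = fits_longer.loc[selected, "slope"].to_numpy()
    nonzero = s_short != 0
    if not nonzero.all():
        logger.warning(
            "%s vs %s: dropping %d CpG(s) with zero shorter-species slope",
            shorter_species, longer_species, int((~nonzero).sum()),
        )
        selected, s_short, s_long = (
            selected[nonzero], s_short[nonzero], s_long[nonzero],
        )
        if selected.size == 0:
            raise InsufficientCpGsError("all selected CpGs had zero slope")
    ratios = s_long / s_short
    return PairwiseComparison(
        shorter_species=shorter_species,
        longer_species=longer_species,
        matched_max_age_shorter=matched_max_age_shorter,
        matched_max_age_longer=matched_max_age_longer,
        tolerance=tolerance,
        selected_cpgs=selected,
        per_cpg_ratios=ratios,
        median_ratio=float(np.median(ratios)),
    )


# ---------------------------------------------------------------------------
# the chain

@dataclass
class PairLink:
    """Threshold-independent cache for one neighbouring comparison: matched
    ages plus per-CpG fits on both restricted panels."""

    shorter_species: str
    longer_species: str
    matched_max_age_shorter: float
    matched_max_age_longer: float
    tolerance: float
    fits_shorter: pd.DataFrame = field(repr=False)
    fits_longer: pd.DataFrame = field(repr=False)


@dataclass
class ComparisonChain:
    """Ordered retained species and their cached pairwise links.

    Matching, inclusion filtering and per-CpG fitting do not depend on the
    R-squared selection threshold, so the chain is built once and evaluated
    at many thresholds.
    """

    species: list[str]
    max_lifespans: np.ndarray
    links: list[PairLink]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def baseline_species(self) -> str:
        return self.species[0]


def build_comparison_chain(
    panels: dict[str, MethylationDataset],
    traits: SpeciesTraitTable,
) -> ComparisonChain:
    """Order species and cache matched-range per-CpG fits for each link.

    Species failing the initial inclusion filters, lacking traits, or
    failing matching/filters within a pairwise comparison are dropped and
    the walk continues by comparing the next species with the last retained
    one (which preserves the telescoping identity of the cumulative
    product); every exclusion is recorded with its reason.
    """
    excluded: list[tuple[str, str]] = []
    eligible: list[MethylationDataset] = []
    for species in sorted(panels):
        ds = panels[species]
        if species not in traits:
            excluded.append((species, "missing_traits"))
            logger.warning("%s: no trait record; excluded", species)
            continue
        if ds.n_samples == 0:
            excluded.append((species, "empty_panel"))
            continue
        check = apply_inclusion_filters(ds, traits, initial_n=ds.n_samples)
        if not check.passed:
            excluded.append((species, check.reason))
            logger.info("%s: excluded before ordering (%s)", species, check.reason)
            continue
        eligible.append(ds)
    if len(eligible) < 2:
        raise InsufficientDataError(
            "fewer than 2 species pass the inclusion filters"
        )

    ordered = order_species(eligible)
    by_id = {ds.species_id: ds for ds in eligible}

    retained = [ordered[0]]
    links: list[PairLink] = []
    current = by_id[ordered[0]]
    for species in ordered[1:]:
        nxt = by_id[species]
        matched = match_age_ranges(
            current, nxt, traits[current.species_id].max_lifespan
        )
        if matched is None:
            excluded.append((species, "no_age_match"))
            logger.info(
                "%s: no matchable age vs %s; excluded from chain",
                species, current.species_id,
            )
            continue
        ok_short = apply_inclusion_filters(
            matched.shorter, traits, initial_n=current.n_samples
        )
        ok_long = apply_inclusion_filters(
            matched.longer, traits, initial_n=nxt.n_samples
        )
        if not (ok_short.passed and ok_long.passed):
            reason = ok_short.reason or ok_long.reason
            excluded.append((species, f"restricted_{reason}"))
            logger.info(
                "%s vs %s: restricted panels fail filters (%s); %s excluded",
                current.species_id, species, reason, species,
            )
            continue
        links.append(
            PairLink(
                shorter_species=current.species_id,
                longer_species=species,
                matched_max_age_shorter=matched.matched_max_age_shorter,
                matched_max_age_longer=matched.matched_max_age_longer,
                tolerance=matched.tolerance,
                fits_shorter=fit_panel_rates(matched.shorter),
                fits_longer=fit_panel_rates(matched.longer),
            )
        )
        retained.append(species)
        current = nxt

    if len(retained) < 2:
        raise InsufficientDataError("fewer than 2 species survive the chain")
    lifespans = np.array([traits[s].max_lifespan for s in retained])
    return ComparisonChain(
        species=retained, max_lifespans=lifespans, links=links,
        excluded=excluded,
    )


def evaluate_chain(
    chain: ComparisonChain,
    r2_threshold: float,
    min_cpgs: int = 10,
    direction: str | None = None,
) -> ScalingSeries:
    """Apply CpG selection at one threshold and chain the median ratios.

    Raises :class:`InsufficientCpGsError` if any single comparison selects
    fewer than ``min_cpgs`` sites, invalidating this threshold.
    """
    comparisons: list[PairwiseComparison] = []
    for link in chain.links:
        selected = select_common_age_related_cpgs(
            link.fits_shorter, link.fits_longer, r2_threshold, direction
        )
        if len(selected) < min_cpgs:
            raise InsufficientCpGsError(
                f"{link.shorter_species} vs {link.longer_species}: "
                f"{len(selected)} CpGs < {min_cpgs} at R2 >= {r2_threshold}"
            )
        comparisons.append(
            median_rate_ratio(
                link.fits_shorter,
                link.fits_longer,
                selected,
                shorter_species=link.shorter_species,
                longer_species=link.longer_species,
                matched_max_age_shorter=link.matched_max_age_shorter,
                matched_max_age_longer=link.matched_max_age_longer,
                tolerance=link.tolerance,
            )
        )
    cumulative = np.cumprod([1.0] + [c.median_ratio for c in comparisons])
    return ScalingSeries(
        species=list(chain.species),
        cumulative_ratios=cumulative,
        max_lifespans=chain.max_lifespans.copy(),
        comparisons=comparisons,
    )


def chain_comparisons(
    panels: dict[str, MethylationDataset],
    traits: SpeciesTraitTable,
    r2_threshold: float,
    min_cpgs: int = 10,
    direction: str | None = None,
) -> ScalingSeries:
    """Full chain walk at a single R-squared threshold."""
    chain = build_comparison_chain(panels, traits)
    return evaluate_chain(chain, r2_threshold, min_cpgs, direction)
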