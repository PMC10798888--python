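"""Core domain containers.

The pipeline operates on per-(species, tissue) methylation panels — a CpG x
sample matrix of methylation proportions (beta values in [0, 1]) with a
chronological age per sample — together with an AnAge-style species-trait
table (maximum lifespan, age of sexual maturity, adult body mass).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError

__all__ = [
    "MethylationDataset",
    "SpeciesTraits",
    "SpeciesTraitTable",
    "CpGRateFit",
    "PairwiseComparison",
    "ScalingSeries",
    "ScalingFit",
    "ValidationResult",
    "normalize_species_id",
]

#: Beta values outside [0, 1] by at most this much are clipped; beyond it they
#: are treated as corrupt input.
BETA_TOLERANCE = 1e-9


def normalize_species_id(species_id: str) -> str:
    """Case-folded, space/underscore/hyphen-insensitive species key."""
    return "".join(ch for ch in species_id.casefold() if ch not in " _-")


@dataclass
class MethylationDataset:
    """One species x tissue methylation panel.

    Parameters
    ----------
    species_id, tissue
        Labels identifying the panel.
    cpg_ids
        Ordered, unique CpG identifiers (rows of ``betas``).
    sample_ids
        Ordered, unique sample identifiers (columns of ``betas``).
    betas
        ``(n_cpgs, n_samples)`` array of methylation proportions in [0, 1];
        missing values are NaN.
    ages
        Per-sample chronological age in years (non-negative, finite). After
        sexual-maturity trimming these are re-referenced so that 0 is the age
        of sexual maturity.
    """

    species_id: str
    tissue: str
    cpg_ids: np.ndarray
    sample_ids: np.ndarray
    betas: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = np.asarray(self.cpg_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        self.betas = np.asarray(self.betas, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.betas.ndim != 2:
            raise FormatError("betas must be a 2-D (CpG x sample) matrix")
        n_cpgs, n_samples = self.betas.shape
        if len(self.cpg_ids) != n_cpgs or len(self.sample_ids) != n_samples:
            raise FormatError(
                f"dimension mismatch: betas {self.betas.shape} vs "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        if len(np.unique(self.sample_ids)) != n_samples:
            raise FormatError("sample_ids must be unique")
        if len(np.unique(self.cpg_ids)) != n_cpgs:
            raise FormatError("cpg_ids must be unique")
        if self.ages.shape != (n_samples,):
            raise FormatError("ages must be one value per sample")
        if not np.all(np.isfinite(self.ages)) or np.any(self.ages < 0):
            raise FormatError("ages must be finite and non-negative")
        with np.errstate(invalid="ignore"):
            out_of_range = (self.betas < -BETA_TOLERANCE) | (
                self.betas > 1 + BETA_TOLERANCE
            )
        if np.any(out_of_range):
            raise FormatError("beta values outside [0, 1] beyond tolerance")
        np.clip(self.betas, 0.0, 1.0, out=self.betas)

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    @property
    def n_cpgs(self) -> int:
        return self.betas.shape[0]

    @property
    def max_age(self) -> float:
        return float(np.max(self.ages)) if self.n_samples else float("nan")

    def subset_samples(self, index: np.ndarray) -> "MethylationDataset":
        """New dataset keeping the samples selected by ``index`` (bool mask
        or integer indices), preserving order."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return MethylationDataset(
            species_id=self.species_id,
            tissue=self.tissue,
            cpg_ids=self.cpg_ids.copy(),
            sample_ids=self.sample_ids[index].copy(),
            betas=self.betas[:, index].copy(),
            ages=self.ages[index].copy(),
        )

    def with_ages(self, ages: np.ndarray) -> "MethylationDataset":
        return replace(self, ages=np.asarray(ages, dtype=float))


@dataclass(frozen=True)
class SpeciesTraits:
    """AnAge-style life-history record for one species.

    ``max_lifespan`` (years, > 0) is the longest recorded lifespan;
    ``age_sexual_maturity`` (years, >= 0) re-references ages; ``body_mass``
    (grams, > 0) may be missing (None).
    """

    species_id: str
    max_lifespan: float
    age_sexual_maturity: float = 0.0
    body_mass: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.max_lifespan) or self.max_lifespan <= 0:
            raise FormatError(
                f"{self.species_id}: max_lifespan must be positive"
            )
        asm = self.age_sexual_maturity
        if not np.isfinite(asm) or asm < 0:
            raise FormatError(
                f"{self.species_id}: age_sexual_maturity must be >= 0"
            )
        if self.max_lifespan <= asm:
            raise FormatError(
                f"{self.species_id}: max_lifespan must exceed age of sexual maturity"
            )
        if self.body_mass is not None and not self.body_mass > 0:
            raise FormatError(f"{self.species_id}: body_mass must be positive")


class SpeciesTraitTable(Mapping):
    """Species-trait lookup keyed by normalized species id."""

    def __init__(self, traits: Iterable[SpeciesTraits]):
        self._by_norm: dict[str, SpeciesTraits] = {}
        for t in traits:
            key = normalize_species_id(t.species_id)
            if key in self._by_norm:
                raise FormatError(f"duplicate species id: {t.species_id!r}")
            self._by_norm[key] = t

    def __getitem__(self, species_id: str) -> SpeciesTraits:
        return self._by_norm[normalize_species_id(species_id)]

    def __contains__(self, species_id: object) -> bool:
        return (
            isinstance(species_id, str)
            and normalize_species_id(species_id) in self._by_norm
        )

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_norm)

    def __len__(self) -> int:
        return len(self._by_norm)

    def records(self) -> list[SpeciesTraits]:
        return list(self._by_norm.values())


@dataclass(frozen=True)
class CpGRateFit:
    """Per-CpG simple linear regression of beta on age.

    ``slope`` is the methylation rate in proportion per year; ``r_squared``
    the coefficient of determination; ``mean_methylation`` the mean beta over
    the (trimmed) samples used in the fit.
    """

    cpg_id: str
    slope: float
    intercept: float
    r_squared: float
    mean_methylation: float
    n_samples: int


@dataclass
class PairwiseComparison:
    """Age-range-matched comparison of two neighbouring species.

    ``per_cpg_ratios`` are slope_longer / slope_shorter over the selected
    common age-related CpGs; ``median_ratio`` is their exact median (midpoint
    convention for even counts).
    """

    shorter_species: str
    longer_species: str
    matched_max_age_shorter: float
    matched_max_age_longer: float
    tolerance: float
    selected_cpgs: np.ndarray
    per_cpg_ratios: np.ndarray
    median_ratio: float

    @property
    def n_cpgs(self) -> int:
        return len(self.selected_cpgs)


@dataclass
class ScalingSeries:
    """Cumulative rate-ratio series along the ordered species chain.

    The baseline (shortest-sampled) species has cumulative ratio 1; each
    subsequent entry multiplies by the median rate ratio of the comparison
    linking it to the previous retained species.
    """

    species: list[str]
    cumulative_ratios: np.ndarray
    max_lifespans: np.ndarray
    comparisons: list[PairwiseComparison] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.cumulative_ratios = np.asarray(self.cumulative_ratios, dtype=float)
        self.max_lifespans = np.asarray(self.max_lifespans, dtype=float)

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class ScalingFit:
    """Power-law fit: log10(cumulative ratio) ~ log10(max lifespan).

    ``exponent`` is the scaling law s in rate ∝ lifespan^s; ``intercept`` is
    the log10 constant (relative to the baseline species); the 95% CI comes
    from the t distribution with n - 2 degrees of freedom.
    """

    exponent: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    n_species: int
    stderr: float = float("nan")
    r2_threshold: float | None = None


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of one robustness experiment."""

    experiment: str
    exponent: float
    ci_low: float
    ci_high: float
    r_squared: float
    notes: str = ""
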