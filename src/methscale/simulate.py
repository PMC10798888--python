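"""Synthetic multi-species methylation panels with known ground truth.

Each CpG drifts linearly with age; measurement noise is Gaussian; values are
clipped to the [0, 1] beta range, which produces the plateaus that make naive
cross-species rate comparisons biased. Per-species rates can follow a
configurable power law in maximum lifespan (``slope = b_c * lifespan**s``) or
be lifespan-independent (null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import MethylationDataset, SpeciesTraits, SpeciesTraitTable

__all__ = [
    "SimulationSpec",
    "generate_power_law_scenario",
    "generate_naive_null_scenario",
    "generate_empirical_null_scenario",
]

#: Default lifespan range in years, spanning the bulk of mammalian lifespans.
LIFESPAN_RANGE = (3.0, 120.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated multi-species study.

    ``true_exponent`` is the ground-truth scaling law s linking per-species
    rates to maximum lifespan (0 for a null). ``baseline_slope_mean/sd``
    parameterize the per-CpG slope magnitude b_c at a reference lifespan of
    1 year; the realized slope in species m is ``sign_c * b_c * l_m**s``.
    ``sampled_fraction`` is the fraction of each lifespan covered by sampling;
    ``hyper_fraction`` the fraction of CpGs drifting upward (sign shared
    across species). Lifespans default to log-uniform draws over 3-120 years.
    """

    n_species: int = 40
    n_cpgs: int = 500
    samples_per_species: int | tuple[int, ...] = 30
    lifespans: tuple[float, ...] | None = None
    sampled_fraction: float = 0.5
    true_exponent: float = -1.0
    baseline_slope_mean: float = 0.2
    baseline_slope_sd: float = 0.1
    intercept_mean: float = 0.5
    intercept_sd: float = 0.15
    noise_sd: float = 0.03
    hyper_fraction: float = 0.5
    tissue: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_cpgs < 1:
            raise ConfigError("n_species and n_cpgs must be positive")
        counts = self.sample_counts()
        if any(c < 1 for c in counts):
            raise ConfigError("samples_per_species must be positive")
        if not 0 < self.sampled_fraction <= 1:
            raise ConfigError("sampled_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.hyper_fraction <= 1:
            raise ConfigError("hyper_fraction must be in [0, 1]")
        if not 0 < self.intercept_mean < 1:
            raise ConfigError(
                "intercept_mean must lie strictly inside (0, 1); values "
                "outside produce all-saturated betas"
            )
        if not np.isfinite(self.true_exponent):
            raise ConfigError("true_exponent must be finite")
        if self.lifespans is not None and len(self.lifespans) != self.n_species:
            raise ConfigError("lifespans must have one value per species")

    def sample_counts(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_species, int):
            return (self.samples_per_species,) * self.n_species
        return tuple(self.samples_per_species)


def _species_rng(seed: int, index: int) -> np.random.Generator:
    # per-species substream: adding a species never perturbs earlier ones
    return np.random.default_rng([seed, index])


def _draw_shared(spec: SimulationSpec):
    """Lifespans, per-CpG signed baseline slopes and intercepts (shared
    across species), plus lifespan-independent body masses."""
    rng = np.random.default_rng(spec.seed)
    if spec.lifespans is not None:
        lifespans = np.asarray(spec.lifespans, dtype=float)
    else:
        lo, hi = np.log10(LIFESPAN_RANGE)
        lifespans = 10 ** rng.uniform(lo, hi, spec.n_species)
    signs = np.where(rng.random(spec.n_cpgs) < spec.hyper_fraction, 1.0, -1.0)
    baselines = np.abs(
        rng.normal(spec.baseline_slope_mean, spec.baseline_slope_sd, spec.n_cpgs)
    )
    intercepts = np.clip(
        rng.normal(spec.intercept_mean, spec.intercept_sd, spec.n_cpgs), 0.0, 1.0
    )
    # body mass log-uniform over 5 g .. 5 t, independent of lifespan
    masses = 10 ** rng.uniform(np.log10(5.0), np.log10(5e6), spec.n_species)
    return lifespans, signs, baselines, intercepts, masses


def _panel(
    spec: SimulationSpec,
    index: int,
    lifespan: float,
    slopes: np.ndarray,
    intercepts: np.ndarray,
    n_samples: int,
    cpg_ids: np.ndarray,
) -> MethylationDataset:
    rng = _species_rng(spec.seed, index)
    ages = np.sort(rng.uniform(0.0, spec.sampled_fraction * lifespan, n_samples))
    betas = intercepts[:, None] + slopes[:, None] * ages[None, :]
    if spec.noise_sd > 0:
        betas = betas + rng.normal(0.0, spec.noise_sd, betas.shape)
    np.clip(betas, 0.0, 1.0, out=betas)
    species = f"species_{index:03d}"
    return MethylationDataset(
        species_id=species,
        tissue=spec.tissue,
        cpg_ids=cpg_ids,
        sample_ids=np.array([f"{species}_s{j:03d}" for j in range(n_samples)]),
        betas=betas,
        ages=ages,
    )


def generate_power_law_scenario(
    spec: SimulationSpec,
) -> tuple[dict[str, MethylationDataset], SpeciesTraitTable, pd.DataFrame]:
    """Generate panels whose true rates scale as lifespan**true_exponent.

    Returns ``(datasets, traits, truth)`` where ``truth`` holds, per species,
    the lifespan and the true rate multiplier ``lifespan**s`` relative to a
    1-year-lifespan reference, and ``datasets`` maps species id -> panel.
    The same spec (including seed) always produces bit-identical output.
    """
    lifespans, signs, baselines, intercepts, masses = _draw_shared(spec)
    cpg_ids = np.array([f"cpg_{c:05d}" for c in range(spec.n_cpgs)])
    counts = spec.sample_counts()

    datasets: dict[str, MethylationDataset] = {}
    truth_rows = []
    for i, lifespan in enumerate(lifespans):
        multiplier = lifespan ** spec.true_exponent
        slopes = signs * baselines * multiplier
        panel = _panel(spec, i, lifespan, slopes, intercepts, counts[i], cpg_ids)
        datasets[panel.species_id] = panel
        truth_rows.append(
            {
                "species_id": panel.species_id,
                "max_lifespan": lifespan,
                "rate_multiplier": multiplier,
            }
        )
    traits = SpeciesTraitTable(
        SpeciesTraits(
            species_id=f"species_{i:03d}",
            max_lifespan=float(lifespans[i]),
            age_sexual_maturity=0.0,
            body_mass=float(masses[i]),
        )
        for i in range(spec.n_species)
    )
    return datasets, traits, pd.DataFrame(truth_rows)


def true_slope_table(spec: SimulationSpec) -> pd.DataFrame:
    """Noise-free truth: the exact per-(species, CpG) slopes the generator
    uses, as a species x CpG table. Useful as an oracle."""
    lifespans, signs, baselines, _, _ = _draw_shared(spec)
    slopes = (
        (signs * baselines)[None, :]
        * (lifespans ** spec.true_exponent)[:, None]
    )
    return pd.DataFrame(
        slopes,
        index=[f"species_{i:03d}" for i in range(spec.n_species)],
        columns=[f"cpg_{c:05d}" for c in range(spec.n_cpgs)],
    )


def generate_naive_null_scenario(
    spec: SimulationSpec,
) -> tuple[dict[str, MethylationDataset], SpeciesTraitTable, pd.DataFrame]:
    """Lifespan-independent rates with ages spanning the whole lifespan.

    Requires ``true_exponent == 0`` and ``sampled_fraction == 1`` so the
    bounded-range clipping artifact is fully expressed: long-lived species
    saturate and their naively fitted slopes shrink.
    """
    if spec.true_exponent != 0:
        raise ConfigError("naive null requires true_exponent = 0")
    if spec.sampled_fraction != 1:
        raise ConfigError("naive null requires sampled_fraction = 1")
    return generate_power_law_scenario(spec)


def generate_empirical_null_scenario(
    observed_slopes: np.ndarray,
    observed_intercepts: np.ndarray,
    datasets_template: dict[str, MethylationDataset],
    seed: int,
    noise_sd: float = 0.03,
) -> dict[str, MethylationDataset]:
    """Null panels built from pooled observed rates and real sample ages.

    For every species and CpG a (slope, intercept) pair is drawn with
    replacement from the pools, independently of lifespan; sample ages are
    copied verbatim from the template panels. This mirrors the robustness
    simulation in which the primary analysis should find no scaling.
    """
    observed_slopes = np.asarray(observed_slopes, dtype=float)
    observed_intercepts = np.asarray(observed_intercepts, dtype=float)
    if observed_slopes.size == 0 or observed_intercepts.size == 0:
        raise ConfigError("slope and intercept pools must be non-empty")

    null_datasets: dict[str, MethylationDataset] = {}
    for i, (species, template) in enumerate(sorted(datasets_template.items())):
        rng = np.random.default_rng([seed, i])
        n_cpgs, n_samples = template.betas.shape
        slopes = rng.choice(observed_slopes, size=n_cpgs, replace=True)
        intercepts = np.clip(
            rng.choice(observed_intercepts, size=n_cpgs, replace=True), 0.0, 1.0
        )
        betas = intercepts[:, None] + slopes[:, None] * template.ages[None, :]
        if noise_sd > 0:
            betas = betas + rng.normal(0.0, noise_sd, betas.shape)
        np.clip(betas, 0.0, 1.0, out=betas)
        null_datasets[species] = MethylationDataset(
            species_id=species,
            tissue=template.tissue,
            cpg_ids=template.cpg_ids.copy(),
            sample_ids=template.sample_ids.copy(),
            betas=betas,
            ages=template.ages.copy(),
        )
    return null_datasets
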