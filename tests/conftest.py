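import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from methscale.types import (
    MethylationDataset,
    SpeciesTraits,
    SpeciesTraitTable,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_linear_panel(
    species: str,
    slopes,
    ages,
    intercepts=0.5,
    tissue: str = "blood",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    clip: bool = True,
) -> MethylationDataset:
    """Panel whose CpGs follow beta = intercept + slope * age (+ noise)."""
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    ages = np.asarray(ages, dtype=float)
    intercepts = np.broadcast_to(
        np.asarray(intercepts, dtype=float), slopes.shape
    )
    betas = intercepts[:, None] + slopes[:, None] * ages[None, :]
    if noise_sd > 0:
        betas = betas + (rng or np.random.default_rng(0)).normal(
            0.0, noise_sd, betas.shape
        )
    if clip:
        betas = np.clip(betas, 0.0, 1.0)
    return MethylationDataset(
        species_id=species,
        tissue=tissue,
        cpg_ids=np.array([f"cpg_{i:03d}" for i in range(len(slopes))]),
        sample_ids=np.array(
            [f"{species}_s{j:03d}" for j in range(len(ages))]
        ),
        betas=betas,
        ages=ages,
    )


def make_traits(**species_kwargs) -> SpeciesTraitTable:
    """Trait table from species_id -> (lifespan[, asm[, mass]]) tuples."""
    records = []
    for sid, vals in species_kwargs.items():
        if np.isscalar(vals):
            vals = (vals,)
        lifespan = vals[0]
        asm = vals[1] if len(vals) > 1 else 0.0
        mass = vals[2] if len(vals) > 2 else None
        records.append(
            SpeciesTraits(
                species_id=sid,
                max_lifespan=lifespan,
                age_sexual_maturity=asm,
                body_mass=mass,
            )
        )
    return SpeciesTraitTable(records)


@pytest.fixture
def three_species_chain():
    """Three noise-free species with identical ages and exactly proportional
    slopes: per-CpG ratios are 0.94 (b vs a) and 0.53 (c vs b)."""
    ages = np.linspace(0.0, 20.0, 21)
    base = np.full(12, 0.01)
    panels = {
        "sp_a": make_linear_panel("sp_a", base, ages),
        "sp_b": make_linear_panel("sp_b", base * 0.94, ages),
        "sp_c": make_linear_panel("sp_c", base * 0.94 * 0.53, ages),
    }
    traits = make_traits(sp_a=40.0, sp_b=40.0, sp_c=40.0)
    return panels, traits
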