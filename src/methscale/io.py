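"""Reading and writing of methylation panels, trait tables and reports.

All interchange is delimited text: CSV or TSV auto-detected from the file
extension. The beta matrix has CpG ids in a first ``cpg_id`` column and one
column per sample; the metadata table has columns ``sample_id``, ``species``,
``tissue``, ``age``; the trait table has ``species_id``, ``max_lifespan``,
``age_sexual_maturity`` and optionally ``body_mass``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError
from .types import (
    BETA_TOLERANCE,
    MethylationDataset,
    ScalingFit,
    ScalingSeries,
    SpeciesTraits,
    SpeciesTraitTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_methylation_dataset",
    "write_methylation_dataset",
    "load_species_traits",
    "write_species_traits",
    "write_scaling_report",
    "read_scaling_report",
]

_METADATA_COLUMNS = ("sample_id", "species", "tissue", "age")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_methylation_dataset(
    beta_table_path: str | Path, metadata_path: str | Path
) -> dict[tuple[str, str], MethylationDataset]:
    """Load a beta table + metadata into per-(species, tissue) panels.

    Samples present in only one of the two tables are dropped with a logged
    warning. Beta values outside [0, 1] by more than 1e-9 raise
    :class:`FormatError`; values within tolerance are clipped.
    """
    beta_table_path = Path(beta_table_path)
    metadata_path = Path(metadata_path)

    betas = pd.read_csv(
        beta_table_path, sep=_sep_for(beta_table_path),
        float_precision="round_trip",
    )
    if betas.columns[0] != "cpg_id":
        raise FormatError("beta table must have 'cpg_id' as its first column")
    betas = betas.set_index("cpg_id")

    meta = pd.read_csv(
        metadata_path, sep=_sep_for(metadata_path),
        float_precision="round_trip",
    )
    missing = set(_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing required columns: {sorted(missing)}")
    meta = meta.astype({"sample_id": str})

    beta_samples = set(map(str, betas.columns))
    meta_samples = set(meta["sample_id"])
    common = beta_samples & meta_samples
    if not common:
        raise EmptyInputError("no samples shared between beta table and metadata")
    for side, extra in (
        ("beta table", beta_samples - meta_samples),
        ("metadata", meta_samples - beta_samples),
    ):
        if extra:
            logger.warning(
                "dropping %d sample(s) present only in the %s: %s",
                len(extra), side, sorted(extra)[:5],
            )

    values = betas.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < -BETA_TOLERANCE) | (values > 1 + BETA_TOLERANCE)
    if np.any(bad):
        raise FormatError("beta values outside [0, 1] beyond tolerance 1e-9")

    meta = meta[meta["sample_id"].isin(common)]
    datasets: dict[tuple[str, str], MethylationDataset] = {}
    for (species, tissue), group in meta.groupby(["species", "tissue"], sort=True):
        sample_ids = group["sample_id"].to_numpy()
        datasets[(species, tissue)] = MethylationDataset(
            species_id=species,
            tissue=tissue,
            cpg_ids=betas.index.to_numpy(),
            sample_ids=sample_ids,
            betas=betas[sample_ids].to_numpy(dtype=float),
            ages=group["age"].to_numpy(dtype=float),
        )
    return datasets


def write_methylation_dataset(
    datasets: dict[tuple[str, str], MethylationDataset] | list[MethylationDataset],
    beta_table_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write panels back to a combined beta table + metadata table.

    CpG sets are unioned across panels; cells absent from a panel are empty.
    Floats are written with full ``repr`` precision so a round trip through
    :func:`load_methylation_dataset` reproduces betas and ages exactly.
    """
    if isinstance(datasets, dict):
        datasets = list(datasets.values())
    if not datasets:
        raise EmptyInputError("no datasets to write")
    beta_table_path = Path(beta_table_path)
    metadata_path = Path(metadata_path)

    frames = [
        pd.DataFrame(ds.betas, index=ds.cpg_ids, columns=ds.sample_ids)
        for ds in datasets
    ]
    combined = pd.concat(frames, axis=1)
    combined.index.name = "cpg_id"
    combined.to_csv(beta_table_path, sep=_sep_for(beta_table_path))

    meta = pd.DataFrame(
        {
            "sample_id": np.concatenate([ds.sample_ids for ds in datasets]),
            "species": np.concatenate(
                [np.repeat(ds.species_id, ds.n_samples) for ds in datasets]
            ),
            "tissue": np.concatenate(
                [np.repeat(ds.tissue, ds.n_samples) for ds in datasets]
            ),
            "age": np.concatenate([ds.ages for ds in datasets]),
        }
    )
    meta.to_csv(metadata_path, sep=_sep_for(metadata_path), index=False)


def load_species_traits(path: str | Path) -> SpeciesTraitTable:
    """Load the AnAge-style trait table.

    Rows with non-positive maximum lifespan are rejected with a logged
    warning; duplicated species raise :class:`FormatError`. A missing
    ``body_mass`` column or cell marks mass as unavailable.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    required = {"species_id", "max_lifespan", "age_sexual_maturity"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"trait table missing columns: {sorted(missing)}")

    records: list[SpeciesTraits] = []
    for row in table.itertuples(index=False):
        lifespan = float(row.max_lifespan)
        if not np.isfinite(lifespan) or lifespan <= 0:
            logger.warning(
                "rejecting species %r: non-positive max_lifespan %r",
                row.species_id, row.max_lifespan,
            )
            continue
        mass = getattr(row, "body_mass", None)
        if mass is not None and not np.isfinite(float(mass)):
            mass = None
        asm = float(row.age_sexual_maturity)
        if not np.isfinite(asm):
            logger.warning(
                "species %r has no age of sexual maturity; treating it as 0",
                row.species_id,
            )
            asm = 0.0
        records.append(
            SpeciesTraits(
                species_id=str(row.species_id),
                max_lifespan=lifespan,
                age_sexual_maturity=asm,
                body_mass=None if mass is None else float(mass),
            )
        )
    return SpeciesTraitTable(records)


def write_species_traits(traits: SpeciesTraitTable, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "species_id": [t.species_id for t in traits.records()],
            "max_lifespan": [t.max_lifespan for t in traits.records()],
            "age_sexual_maturity": [t.age_sexual_maturity for t in traits.records()],
            "body_mass": [
                np.nan if t.body_mass is None else t.body_mass
                for t in traits.records()
            ],
        }
    ).to_csv(path, sep=_sep_for(path), index=False)


def write_scaling_report(
    fit: ScalingFit,
    series: ScalingSeries,
    out_prefix: str | Path,
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write the series table (TSV) and fit summary (JSON).

    Returns the (table_path, summary_path) pair. ``extra`` (e.g. a seed or
    config echo) is embedded verbatim in the summary.
    """
    if series.n_species == 0:
        raise EmptyInputError("empty scaling series")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    table_path = out_prefix.with_name(out_prefix.name + "_series.tsv")
    summary_path = out_prefix.with_name(out_prefix.name + "_summary.json")

    with np.errstate(divide="ignore"):
        pd.DataFrame(
            {
                "species": series.species,
                "max_lifespan": series.max_lifespans,
                "cumulative_ratio": series.cumulative_ratios,
                "log10_max_lifespan": np.log10(series.max_lifespans),
                "log10_cumulative_ratio": np.log10(series.cumulative_ratios),
            }
        ).to_csv(table_path, sep="\t", index=False)

    summary = {
        "exponent": fit.exponent,
        "intercept": fit.intercept,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "r_squared": fit.r_squared,
        "n_species": fit.n_species,
        "r2_threshold": fit.r2_threshold,
    }
    if extra:
        summary["config"] = extra
    summary_path.write_text(json.dumps(summary, indent=2))
    return table_path, summary_path


def read_scaling_report(out_prefix: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back what :func:`write_scaling_report` wrote."""
    out_prefix = Path(out_prefix)
    table = pd.read_csv(
        out_prefix.with_name(out_prefix.name + "_series.tsv"), sep="\t",
        float_precision="round_trip",
    )
    summary = json.loads(
        out_prefix.with_name(out_prefix.name + "_summary.json").read_text()
    )
    return table, summary
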