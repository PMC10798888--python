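"""Sample curation: PCA + DBSCAN outlier removal and sexual-maturity trimming.

Outlier detection runs on all species of a tissue jointly projected onto the
first two principal components, with density-based clustering applied per
species; DBSCAN noise points are the outliers. Samples younger than the age
of sexual maturity are then removed and ages re-referenced so that 0 is
sexual maturity (young samples show non-linear methylation dynamics).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .errors import ConfigError, InsufficientDataError
from .types import MethylationDataset, SpeciesTraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "pca_embed",
    "flag_outliers_dbscan",
    "remove_outlier_samples",
    "trim_to_sexual_maturity",
]


def pca_embed(datasets: Sequence[MethylationDataset]) -> pd.DataFrame:
    """Project all samples of one tissue onto PC1/PC2.

    Uses the CpGs shared by every panel; any remaining missing cells are
    imputed with the CpG mean (for the embedding only — never in rate
    fitting). The matrix is mean-centered but not scaled, preserving beta
    units. Component signs are fixed so the largest-magnitude loading is
    positive, making scores reproducible across library versions.
    """
    if not datasets:
        raise InsufficientDataError("no datasets given")
    common = datasets[0].cpg_ids
    for ds in datasets[1:]:
        common = np.intersect1d(common, ds.cpg_ids)
    if len(common) < 2:
        raise InsufficientDataError("fewer than 2 CpGs shared across panels")

    blocks, sample_ids, species_ids = [], [], []
    for ds in datasets:
        idx = {c: i for i, c in enumerate(ds.cpg_ids)}
        rows = np.array([idx[c] for c in common])
        blocks.append(ds.betas[rows, :].T)  # samples x CpGs
        sample_ids.extend(ds.sample_ids)
        species_ids.extend([ds.species_id] * ds.n_samples)
    matrix = np.vstack(blocks)
    if matrix.shape[0] < 3:
        raise InsufficientDataError("need at least 3 samples for PCA")

    col_mean = np.nanmean(matrix, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(matrix))
    matrix[nan_rows, nan_cols] = col_mean[nan_cols]

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(matrix)
    for k in range(2):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] = -scores[:, k]

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "species_id": species_ids,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
        }
    )


def flag_outliers_dbscan(
    coords: pd.DataFrame,
    eps: float = 1.0,
    min_samples: int = 5,
    standardize: bool = True,
) -> pd.DataFrame:
    """Flag DBSCAN noise points as outliers, per species.

    ``coords`` must have columns sample_id, species_id, pc1, pc2 (one species
    or several; clustering is always per species). Coordinates are
    standardized per species to unit variance by default so a single ``eps``
    works across species of different spreads. All clustered points are
    retained regardless of which cluster they fall in.
    """
    if eps <= 0:
        raise ConfigError("eps must be positive")
    out = coords.copy()
    out["is_outlier"] = False
    for _, group in coords.groupby("species_id", sort=False):
        xy = group[["pc1", "pc2"]].to_numpy(dtype=float)
        if standardize:
            sd = xy.std(axis=0)
            sd[sd == 0] = 1.0
            xy = (xy - xy.mean(axis=0)) / sd
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xy)
        out.loc[group.index, "is_outlier"] = labels == -1
    return out


def remove_outlier_samples(
    datasets: Sequence[MethylationDataset],
    eps: float = 1.0,
    min_samples: int = 5,
    standardize: bool = True,
) -> tuple[list[MethylationDataset], pd.DataFrame]:
    """Run the PCA + DBSCAN step and drop flagged samples from every panel.

    Returns the curated panels and the full outlier report.
    """
    report = flag_outliers_dbscan(
        pca_embed(datasets), eps=eps, min_samples=min_samples,
        standardize=standardize,
    )
    flagged = set(report.loc[report["is_outlier"], "sample_id"])
    curated = []
    for ds in datasets:
        keep = ~np.isin(ds.sample_ids, list(flagged))
        if not keep.all():
            logger.info(
                "%s/%s: removed %d outlier sample(s)",
                ds.species_id, ds.tissue, int((~keep).sum()),
            )
        curated.append(ds.subset_samples(keep))
    return curated, report


def trim_to_sexual_maturity(
    dataset: MethylationDataset, traits: SpeciesTraitTable
) -> MethylationDataset:
    """Drop samples younger than sexual maturity and re-reference ages.

    The boundary is inclusive: a sample exactly at the age of sexual maturity
    is retained with re-referenced age 0. A species missing from the trait
    table is treated as maturing at age 0 with a logged warning. The returned
    panel may be empty; callers exclude such species.
    """
    if dataset.species_id in traits:
        asm = traits[dataset.species_id].age_sexual_maturity
    else:
        logger.warning(
            "no traits for %s; treating age of sexual maturity as 0",
            dataset.species_id,
        )
        asm = 0.0
    keep = dataset.ages >= asm
    trimmed = dataset.subset_samples(keep)
    if trimmed.n_samples == 0:
        logger.warning(
            "%s/%s: no samples at or above sexual maturity (%.3g yr)",
            dataset.species_id, dataset.tissue, asm,
        )
        return trimmed
    return trimmed.with_ages(trimmed.ages - asm)
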