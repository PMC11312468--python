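"""Preprocessing chain for single-cell features and the average-profile baseline.

Two routes share the head of the chain (plate-level standardization, NaN-row
removal, negative-control removal). The model consumes the standardized
single-cell table directly; the population-average baseline additionally
aggregates per well, RobustMAD-normalizes per plate, and applies
variance/correlation feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProfileTable, SingleCellTable

__all__ = [
    "PreprocessConfig",
    "standardize_per_plate",
    "drop_nan_rows",
    "remove_controls",
    "average_profiles",
    "robust_mad_normalize",
    "feature_select",
    "baseline_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Constants of the preprocessing chain.

    control_sentinel: compound_id marking negative-control (solvent) wells.
    mad_epsilon: additive guard on the MAD denominator.
    var_threshold: features with variance below this are dropped.
    corr_threshold: one member of each feature pair with |r| above this is dropped.
    std_epsilon: guard for zero-variance features during standardization.
    mad_statistic: "median" for the conventional median absolute deviation,
        "mean" for the literal mean absolute deviation about the median.
    """

    control_sentinel: str = "DMSO"
    mad_epsilon: float = 1e-18
    var_threshold: float = 1e-5
    corr_threshold: float = 0.9
    std_epsilon: float = 1e-12
    mad_statistic: str = "median"

    def __post_init__(self) -> None:
        if self.mad_epsilon <= 0 or self.std_epsilon <= 0:
            raise ValueError("epsilons must be positive")
        if self.var_threshold < 0:
            raise ValueError("var_threshold must be non-negative")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.mad_statistic not in ("median", "mean"):
            raise ValueError("mad_statistic must be 'median' or 'mean'")


def standardize_per_plate(
    table: SingleCellTable, std_epsilon: float = 1e-12
) -> SingleCellTable:
    """Zero-mean / unit-variance each feature within each plate, over all cells.

    Run before control removal so that control cells contribute to the plate
    statistics. Population (ddof=0) variance. Zero-variance features map to
    all-zeros rather than erroring.
    """
    if table.n_cells == 0:
        raise ValueError("empty table")
    X = table.X.copy()
    for plate, idx in table.meta.groupby("plate_id", sort=False).groups.items():
        rows = np.asarray(idx)
        if len(rows) < 2:
            raise ValueError(f"plate {plate!r} has a single cell; cannot standardize")
        block = X[rows]
        mu = np.nanmean(block, axis=0)
        sd = np.nanstd(block, axis=0)  # population std
        Z = (block - mu) / np.where(sd < std_epsilon, 1.0, sd)
        Z[:, sd < std_epsilon] = 0.0
        X[rows] = Z
    return SingleCellTable(meta=table.meta.copy(), X=X, features=list(table.features))


def drop_nan_rows(table: SingleCellTable) -> SingleCellTable:
    """Remove every cell row containing any missing feature value."""
    keep = ~np.isnan(table.X).any(axis=1)
    if not keep.any():
        raise ValueError("all rows contain missing values")
    if keep.all():
        return table
    return table.subset_rows(keep)


def remove_controls(table: SingleCellTable, control_sentinel: str = "DMSO") -> SingleCellTable:
    """Drop negative-control wells (identified by the compound_id sentinel)."""
    keep = (table.meta["compound_id"] != control_sentinel).to_numpy()
    if keep.all():
        return table
    if not keep.any():
        warnings.warn("all wells are negative controls; returning empty table")
        return SingleCellTable(
            meta=table.meta.iloc[0:0], X=table.X[0:0], features=list(table.features)
        )
    return table.subset_rows(keep)


def average_profiles(table: SingleCellTable) -> ProfileTable:
    """Population-averaged profiling: per-well, per-feature arithmetic mean."""
    metas = []
    rows = []
    for s in table.iter_wells():
        mask = (
            (table.meta["plate_id"] == s.well_key.plate_id)
            & (table.meta["well_id"] == s.well_key.well_id)
            & (table.meta["compound_id"] == s.well_key.compound_id)
        ).to_numpy()
        first = int(np.flatnonzero(mask)[0])
        metas.append(
            {
                "plate_id": s.well_key.plate_id,
                "well_id": s.well_key.well_id,
                "compound_id": s.well_key.compound_id,
                "moa": table.meta["moa"].iloc[first],
                "dose": table.meta["dose"].iloc[first],
            }
        )
        rows.append(s.X.mean(axis=0))
    return ProfileTable(
        meta=pd.DataFrame(metas),
        values=np.vstack(rows),
        method="average",
        features=list(table.features),
    )


def robust_mad_normalize(
    profiles: ProfileTable,
    mad_epsilon: float = 1e-18,
    mad_statistic: str = "median",
) -> ProfileTable:
    """RobustMAD: per plate and feature, subtract the median and divide by the
    (median or mean) absolute deviation about the median, plus epsilon.

    Raw deviation statistic — no 1.4826 consistency constant. With an odd
    number of wells per plate the output medians are exactly zero (the median
    is a data point); with an even count the midpoint median can leave a
    ~1-ulp residue.
    """
    V = profiles.values.copy()
    for plate, idx in profiles.meta.groupby("plate_id", sort=False).groups.items():
        rows = np.asarray(idx)
        if len(rows) < 3:
            warnings.warn(f"plate {plate!r} has {len(rows)} wells; MAD statistics degenerate")
        block = V[rows]
        med = np.median(block, axis=0)
        dev = np.abs(block - med)
        mad = np.median(dev, axis=0) if mad_statistic == "median" else dev.mean(axis=0)
        norm = (block - med) / (mad + mad_epsilon)
        norm[:, mad == 0] = 0.0  # constant features -> exact zeros
        V[rows] = norm
    return ProfileTable(
        meta=profiles.meta.copy(),
        values=V,
        method=profiles.method,
        features=list(profiles.features),
    )


def feature_select(
    profiles: ProfileTable,
    var_threshold: float = 1e-5,
    corr_threshold: float = 0.9,
) -> ProfileTable:
    """Drop low-variance features, then one member of each highly correlated pair.

    Features are scanned in canonical (stored) order; of an offending pair the
    later member is dropped, for determinism.
    """
    V = profiles.values
    var = V.var(axis=0)  # population variance
    keep = var >= var_threshold
    if not keep.any():
        raise ValueError("variance threshold removed all features")
    idx = np.flatnonzero(keep)
    sub = V[:, idx]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr))
    alive = np.ones(len(idx), dtype=bool)
    for a in range(len(idx)):
        if not alive[a]:
            continue
        for b in range(a + 1, len(idx)):
            if alive[b] and abs(corr[a, b]) > corr_threshold:
                alive[b] = False
    final = idx[alive]
    if final.size == 0:
        raise ValueError("feature selection removed all features")
    return ProfileTable(
        meta=profiles.meta.copy(),
        values=V[:, final],
        method=profiles.method,
        features=[profiles.features[i] for i in final],
    )


def baseline_profiles(
    table: SingleCellTable, cfg: PreprocessConfig | None = None
) -> ProfileTable:
    """Full average-profile baseline chain: standardize -> drop NaN rows ->
    remove controls -> per-well mean -> RobustMAD -> feature selection."""
    cfg = cfg or PreprocessConfig()
    log.info(
        "preprocess config: control=%s mad_eps=%g var_thr=%g corr_thr=%g",
        cfg.control_sentinel, cfg.mad_epsilon, cfg.var_threshold, cfg.corr_threshold,
    )
    t = standardize_per_plate(table, cfg.std_epsilon)
    t = drop_nan_rows(t)
    t = remove_controls(t, cfg.control_sentinel)
    prof = average_profiles(t)
    prof = robust_mad_normalize(prof, cfg.mad_epsilon, cfg.mad_statistic)
    return feature_select(prof, cfg.var_threshold, cfg.corr_threshold)


def model_input_table(
    table: SingleCellTable, cfg: PreprocessConfig | None = None
) -> SingleCellTable:
    """Shared head of the chain feeding the learned aggregator."""
    cfg = cfg or PreprocessConfig()
    t = standardize_per_plate(table, cfg.std_epsilon)
    t = drop_nan_rows(t)
    return remove_controls(t, cfg.control_sentinel)
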