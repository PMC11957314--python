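"""Well aggregation, control-based normalization, and feature pruning.

Single-cell tables are reduced to one median profile per well, normalized
per plate against that plate's vehicle-control wells (robust MAD by default,
with the 1.4826 consistency constant so that a kept feature has unit robust
scale in controls), then pruned: features with an excessive standard
deviation are discarded, and of any pair of features correlated beyond a
threshold only the earlier column is kept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import METADATA_COLUMNS, WELL_KEY, CellFeatureTable

log = logging.getLogger(__name__)

MAD_CONSISTENCY = 1.4826
NORMALIZATION_METHODS = ("robust_mad", "zscore", "minmax")

#: Columns that are never features in a profile CSV.
NON_FEATURE_COLUMNS = METADATA_COLUMNS + [
    "cell_count",
    "n_wells",
    "induction_pct",
]


@dataclass
class ProfileMatrix:
    """Profiles (wells or treatments) x features, with row metadata.

    ``well_counts`` keeps one row per well of the full plate layout —
    including wells that yielded zero cells and therefore have no profile
    row — so that cell-count statistics never silently lose dead wells.
    """

    data: pd.DataFrame
    features: list[str]
    level: str = "well"
    normalization: str | None = None
    filtered: bool = False
    control_wells: dict | None = None
    well_counts: pd.DataFrame | None = None

    def matrix(self) -> np.ndarray:
        return self.data[self.features].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def aggregate_wells(cells: CellFeatureTable) -> ProfileMatrix:
    """Median-aggregate single cells into one profile row per well.

    Cells with any missing feature value are dropped first (logged count).
    ``cell_count`` is the number of cells contributing to the median.  Wells
    present in the metadata but yielding zero cells get ``cell_count = 0``
    in ``well_counts`` and no profile row (logged list).
    """
    if len(cells.data) == 0:
        raise ValueError("cannot aggregate an empty cell table")
    df = cells.data
    features = cells.features
    complete = df[features].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("dropped %d cells with missing feature values", n_dropped)
        df = df.loc[complete]

    grouped = df.groupby(WELL_KEY, observed=True, sort=True)
    medians = grouped[features].median().astype(np.float64)
    counts = grouped.size().rename("cell_count")

    meta = cells.wells
    well_counts = meta.merge(
        counts.reset_index(), on=WELL_KEY, how="left"
    )
    well_counts["cell_count"] = (
        well_counts["cell_count"].fillna(0).astype(int)
    )
    empty = well_counts.loc[well_counts["cell_count"] == 0, WELL_KEY]
    if len(empty):
        log.warning(
            "%d wells yielded zero cells and were excluded from profiles: %s",
            len(empty),
            empty.to_records(index=False).tolist()[:10],
        )

    profile = medians.reset_index().merge(meta, on=WELL_KEY, how="left")
    profile = profile.merge(counts.reset_index(), on=WELL_KEY, how="left")
    profile = profile[METADATA_COLUMNS + ["cell_count"] + features]
    return ProfileMatrix(
        data=profile.reset_index(drop=True),
        features=list(features),
        level="well",
        well_counts=well_counts,
    )


def _control_stats(ctrl: np.ndarray, method: str):
    """Per-feature (center, scale) from a plate's vehicle wells."""
    if method == "robust_mad":
        center = np.median(ctrl, axis=0)
        mad = np.median(np.abs(ctrl - center), axis=0)
        scale = MAD_CONSISTENCY * mad
    elif method == "zscore":
        center = ctrl.mean(axis=0)
        scale = ctrl.std(axis=0, ddof=1)
    elif method == "minmax":
        center = ctrl.min(axis=0)
        scale = ctrl.max(axis=0) - center
    else:
        raise ValueError(
            f"unknown normalization method {method!r}; "
            f"expected one of {NORMALIZATION_METHODS}"
        )
    return center, scale


def normalize_profiles(pm: ProfileMatrix, method: str = "robust_mad") -> ProfileMatrix:
    """Normalize each plate's profiles against its own vehicle wells.

    Features whose control scale (MAD, SD or range) is zero on any plate
    carry no calibrated deviation scale and are dropped with a warning.
    """
    if pm.level != "well":
        raise ValueError("normalization operates on well-level profiles")
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization method {method!r}; "
            f"expected one of {NORMALIZATION_METHODS}"
        )
    features = pm.features
    out = pm.data.copy()
    degenerate = np.zeros(len(features), dtype=bool)
    control_wells: dict[str, list[str]] = {}

    for plate_id, plate_df in pm.data.groupby("plate_id", observed=True, sort=True):
        ctrl_mask = plate_df["vehicle"].to_numpy(dtype=bool)
        if ctrl_mask.sum() < 2:
            raise ValueError(
                f"plate {plate_id!r} has fewer than 2 vehicle wells"
            )
        ctrl = plate_df.loc[ctrl_mask, features].to_numpy(dtype=float)
        center, scale = _control_stats(ctrl, method)
        degenerate |= scale == 0
        safe = np.where(scale == 0, 1.0, scale)
        values = plate_df[features].to_numpy(dtype=float)
        out.loc[plate_df.index, features] = (values - center) / safe
        control_wells[str(plate_id)] = plate_df.loc[ctrl_mask, "well"].tolist()

    kept = [f for f, bad in zip(features, degenerate) if not bad]
    dropped = [f for f, bad in zip(features, degenerate) if bad]
    if dropped:
        log.warning(
            "dropped %d features with zero control scale under %s: %s",
            len(dropped),
            method,
            dropped[:10],
        )
    if not kept:
        raise ValueError("all features degenerate under normalization")
    out = out[METADATA_COLUMNS + ["cell_count"] + kept]
    return ProfileMatrix(
        data=out,
        features=kept,
        level="well",
        normalization=method,
        control_wells=control_wells,
        well_counts=pm.well_counts,
    )


def filter_features(
    pm: ProfileMatrix, sd_max: float = 2000.0, corr_max: float = 0.9
) -> tuple[ProfileMatrix, pd.DataFrame]:
    """Drop high-variance then redundant features.

    First discards features with standard deviation above ``sd_max`` (guards
    against features blown up by normalization), then walks the remaining
    features in column order and drops any whose absolute Pearson correlation
    with an already-kept feature exceeds ``corr_max``.  Returns the pruned
    matrix and a drop ledger (feature, reason, detail).  Idempotent.
    """
    if pm.normalization is None:
        raise ValueError("filter_features expects a normalized matrix")
    X = pm.data[pm.features].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    ledger = []
    sd_kept = []
    for j, f in enumerate(pm.features):
        if sd[j] > sd_max:
            ledger.append((f, "sd", f"sd={sd[j]:.6g}"))
        else:
            sd_kept.append(j)

    sub = X[:, sd_kept]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T) if sub.shape[1] > 1 else np.ones((1, 1))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)

    kept_local: list[int] = []
    for j in range(sub.shape[1]):
        partner = next(
            (k for k in kept_local if abs(corr[j, k]) > corr_max), None
        )
        if partner is None:
            kept_local.append(j)
        else:
            ledger.append(
                (
                    pm.features[sd_kept[j]],
                    "correlation",
                    f"r={corr[j, partner]:.4f} with "
                    f"{pm.features[sd_kept[partner]]}",
                )
            )
    kept = [pm.features[sd_kept[j]] for j in kept_local]
    if not kept:
        raise ValueError("all features dropped by filtering")

    ledger_df = pd.DataFrame(ledger, columns=["feature", "reason", "detail"])
    meta_cols = [c for c in NON_FEATURE_COLUMNS if c in pm.data.columns]
    data = pm.data[meta_cols + kept]
    return (
        ProfileMatrix(
            data=data,
            features=kept,
            level=pm.level,
            normalization=pm.normalization,
            filtered=True,
            control_wells=pm.control_wells,
            well_counts=pm.well_counts,
        ),
        ledger_df,
    )


def aggregate_treatments(pm: ProfileMatrix) -> ProfileMatrix:
    """Aggregate well profiles into one row per compound x concentration.

    Feature values are medians across the condition's wells over all plates;
    ``cell_count`` is the median per-well cell count, taken from the full
    well-count table (so wells that yielded zero cells still pull the median
    down).  Vehicle wells aggregate into a single ``VEHICLE x 0`` row.
    """
    if pm.normalization is None:
        raise ValueError("aggregate treatments after normalization")
    if len(pm.data) == 0:
        raise ValueError("no wells to aggregate")
    keys = ["compound", "concentration_m", "vehicle"]
    grouped = pm.data.groupby(keys, observed=True, sort=True)
    med = grouped[pm.features].median()
    n_wells = grouped.size().rename("n_wells")

    counts_src = pm.well_counts if pm.well_counts is not None else pm.data
    count_med = (
        counts_src.groupby(keys, observed=True, sort=True)["cell_count"]
        .median()
        .rename("cell_count")
    )
    out = (
        med.join(n_wells)
        .join(count_med)
        .reset_index()
    )
    out = out[keys + ["cell_count", "n_wells"] + pm.features]
    return ProfileMatrix(
        data=out,
        features=list(pm.features),
        level="treatment",
        normalization=pm.normalization,
        filtered=pm.filtered,
        control_wells=pm.control_wells,
        well_counts=pm.well_counts,
    )


def write_profiles(pm: ProfileMatrix, path) -> None:
    pm.data.to_csv(path, index=False)


def read_profiles(
    path, level: str = "well", normalization: str | None = "robust_mad"
) -> ProfileMatrix:
    """Rebuild a :class:`ProfileMatrix` from a profiles CSV."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "compound": str}, float_precision="round_trip")
    features = [
        c
        for c in df.columns
        if c not in NON_FEATURE_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
    ]
    if "vehicle" in df.columns:
        df["vehicle"] = df["vehicle"].astype(bool)
    return ProfileMatrix(
        data=df, features=features, level=level, normalization=normalization
    )
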