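"""Tabular I/O and plate-layout semantics.

Every artifact in the pipeline is a plain CSV with a header.  Wells are
identified by ``(plate_id, well)`` where ``well`` follows the conventional
row-letter + zero-padded-column pattern (``"B03"``).  Plate metadata maps
each well to its treatment: a compound code, a molar concentration, and a
vehicle flag (DMSO-only control wells).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical plate-metadata schema.  Every tabular artifact carries these.
METADATA_COLUMNS = ["plate_id", "well", "compound", "concentration_m", "vehicle"]
WELL_KEY = ["plate_id", "well"]
VEHICLE_COMPOUND = "VEHICLE"

_WELL_RE = re.compile(r"^[A-Z]\d{2,}$")


@dataclass(frozen=True)
class WellAddress:
    """A single well on a named plate.

    ``site_count`` is the number of microscope fields imaged per well; it is
    carried as layout metadata and does not affect any computation.
    """

    plate_id: str
    well: str
    site_count: int = 5

    def __post_init__(self) -> None:
        if not self.plate_id:
            raise ValueError("plate_id must be non-empty")
        if not _WELL_RE.match(self.well):
            raise ValueError(
                f"well {self.well!r} does not match row-letter + "
                "zero-padded-column pattern (e.g. 'B03')"
            )
        if self.site_count <= 0:
            raise ValueError("site_count must be positive")


@dataclass(frozen=True)
class TreatmentLabel:
    """Compound x concentration label attached to a well."""

    compound: str
    concentration_m: float
    vehicle: bool

    def __post_init__(self) -> None:
        if self.concentration_m < 0:
            raise ValueError("concentration must be non-negative")
        is_vehicle_like = (
            self.compound == VEHICLE_COMPOUND and self.concentration_m == 0.0
        )
        if self.vehicle != is_vehicle_like:
            raise ValueError(
                "vehicle=True requires compound='VEHICLE' and concentration 0 "
                f"(got {self.compound!r} at {self.concentration_m!r})"
            )


@dataclass
class CellFeatureTable:
    """Single-cell morphology table: one row per segmented cell.

    ``data`` holds the metadata columns plus ``features`` numeric columns;
    ``wells`` is the per-well metadata table (one row per well), kept so that
    downstream aggregation can account for wells that yielded zero cells.
    """

    data: pd.DataFrame
    features: list[str]
    wells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return len(self.features)


@dataclass
class ViabilityTable:
    """Per-well luminescence reads from an ATP-based viability assay.

    ``viability_pct`` (percentage of the same plate's vehicle-median
    luminescence) is NaN until populated by
    :func:`myoscreen.doseresponse.normalize_viability`.
    """

    data: pd.DataFrame

    @property
    def normalized(self) -> bool:
        return bool(self.data["viability_pct"].notna().all())


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a plate-metadata CSV (one row per well)."""
    meta = pd.read_csv(path, dtype={"plate_id": str, "well": str, "compound": str}, float_precision="round_trip")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    dup = meta.duplicated(subset=WELL_KEY)
    if dup.any():
        bad = meta.loc[dup, WELL_KEY].to_records(index=False).tolist()
        raise ValueError(f"duplicate wells in metadata: {bad[:5]}")
    meta["vehicle"] = meta["vehicle"].astype(bool)
    meta["concentration_m"] = meta["concentration_m"].astype(float)
    for row in meta.itertuples(index=False):
        WellAddress(row.plate_id, row.well)
        TreatmentLabel(row.compound, row.concentration_m, row.vehicle)
    return meta[METADATA_COLUMNS + [c for c in meta.columns if c not in METADATA_COLUMNS]]


def _detect_feature_columns(cells: pd.DataFrame) -> list[str]:
    """Feature columns are the numeric columns outside the metadata schema."""
    candidates = [c for c in cells.columns if c not in METADATA_COLUMNS]
    features = []
    for col in candidates:
        if pd.api.types.is_numeric_dtype(cells[col]):
            features.append(col)
        else:
            log.warning(
                "column %r is not numeric and was excluded from the feature set",
                col,
            )
    return features


def read_cell_features(path, metadata_path) -> CellFeatureTable:
    """Read a single-cell feature CSV and join it to plate metadata.

    Rows referencing wells absent from the metadata are an error; non-numeric
    columns are excluded from the feature set with a logged warning.
    """
    meta = read_metadata(metadata_path)
    cells = pd.read_csv(path, dtype={"plate_id": str, "well": str}, float_precision="round_trip")
    for col in WELL_KEY:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing the {col!r} column")
    features = _detect_feature_columns(cells)
    if len(features) == 0:
        raise ValueError("zero feature columns detected in cell table")

    known = set(map(tuple, meta[WELL_KEY].itertuples(index=False)))
    seen = set(map(tuple, cells[WELL_KEY].drop_duplicates().itertuples(index=False)))
    orphans = sorted(seen - known)
    if orphans:
        raise ValueError(
            f"cell rows reference wells absent from metadata: {orphans[:5]}"
        )

    joined = cells[WELL_KEY + features].merge(meta, on=WELL_KEY, how="left")
    # keep metadata columns first, as in the canonical layout
    joined = joined[
        METADATA_COLUMNS
        + [c for c in meta.columns if c not in METADATA_COLUMNS]
        + features
    ]
    return CellFeatureTable(data=joined, features=features, wells=meta)


def read_viability(path, metadata_path) -> ViabilityTable:
    """Read a per-well luminescence CSV and join it to plate metadata.

    Luminescence of 0 is allowed (a dead well); negative reads and duplicate
    wells are errors.  ``viability_pct`` is left unset.
    """
    meta = read_metadata(metadata_path)
    lum = pd.read_csv(path, dtype={"plate_id": str, "well": str}, float_precision="round_trip")
    if "luminescence" not in lum.columns:
        raise ValueError("viability table is missing the 'luminescence' column")
    dup = lum.duplicated(subset=WELL_KEY)
    if dup.any():
        bad = lum.loc[dup, WELL_KEY].to_records(index=False).tolist()
        raise ValueError(f"duplicate wells in viability table: {bad[:5]}")
    if (lum["luminescence"] < 0).any():
        bad = lum.loc[lum["luminescence"] < 0, WELL_KEY].to_records(index=False)
        raise ValueError(f"negative luminescence reads at {bad.tolist()[:5]}")
    known = set(map(tuple, meta[WELL_KEY].itertuples(index=False)))
    seen = set(map(tuple, lum[WELL_KEY].itertuples(index=False)))
    orphans = sorted(seen - known)
    if orphans:
        raise ValueError(
            f"viability rows reference wells absent from metadata: {orphans[:5]}"
        )
    joined = lum[WELL_KEY + ["luminescence"]].merge(meta, on=WELL_KEY, how="left")
    joined["viability_pct"] = np.nan
    joined = joined[METADATA_COLUMNS + ["luminescence", "viability_pct"]]
    return ViabilityTable(data=joined)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV with round-trip float precision (shortest repr)."""
    df.to_csv(path, index=False)
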