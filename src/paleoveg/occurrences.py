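"""Ingestion and curation of taxon occurrence records.

Occurrences (fossil and current) are carried as pandas DataFrames with
the columns ``taxon, group, lon, lat, age_ma, source`` (and, after
discretization, ``stage_index``). Fossil and current records are merged
and treated jointly; current records sit at age 0 in the youngest
stage. Tables are expected to be pre-curated upstream (species-level
identification, name reconciliation, removal of aquatic families): this
module validates schema, crops, deduplicates and filters, it does not
reconcile taxonomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chrono import StageTable, discretize_age

__all__ = [
    "CropWindow",
    "DEFAULT_WINDOW",
    "read_occurrences",
    "read_vegetation_points",
    "assign_stages",
    "crop_to_window",
    "deduplicate",
    "filter_informative_taxa",
    "merge_sources",
]

OCCURRENCE_COLUMNS = ["taxon", "group", "lon", "lat", "age_ma", "source"]
VEGETATION_COLUMNS = ["lon", "lat", "age_ma", "label", "source"]

VALID_GROUPS = {"mammal", "plant"}
VALID_OCC_SOURCES = {"fossil", "current"}
VALID_LABELS = {"open", "closed"}
VALID_VEG_SOURCES = {"paleo", "current"}


@dataclass(frozen=True)
class CropWindow:
    """Rectangular lon/lat study window (decimal degrees)."""

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("window bounds must satisfy min < max")

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )


#: North America study window, corner points P1 and P2.
DEFAULT_WINDOW = CropWindow(lon_min=-180.0, lat_min=25.0, lon_max=-52.0, lat_max=80.0)


def _check_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def _check_coords(frame: pd.DataFrame, what: str) -> None:
    if ((frame["lon"].abs() > 180) | (frame["lat"].abs() > 90)).any():
        raise ValueError(f"{what} table has coordinates outside WGS84 bounds")
    if (frame["age_ma"] < 0).any():
        raise ValueError(f"{what} table has negative ages")


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV with strict header validation."""
    frame = pd.read_csv(path)
    _check_columns(frame, OCCURRENCE_COLUMNS, "occurrence")
    _check_coords(frame, "occurrence")
    bad_groups = set(frame["group"]) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown taxon groups: {sorted(bad_groups)}")
    bad_sources = set(frame["source"]) - VALID_OCC_SOURCES
    if bad_sources:
        raise ValueError(f"unknown occurrence sources: {sorted(bad_sources)}")
    return frame


def read_vegetation_points(path) -> pd.DataFrame:
    """Read a labeled vegetation-point CSV (training instances)."""
    frame = pd.read_csv(path)
    _check_columns(frame, VEGETATION_COLUMNS, "vegetation point")
    _check_coords(frame, "vegetation point")
    bad_labels = set(frame["label"]) - VALID_LABELS
    if bad_labels:
        raise ValueError(f"unknown vegetation labels: {sorted(bad_labels)}")
    bad_sources = set(frame["source"]) - VALID_VEG_SOURCES
    if bad_sources:
        raise ValueError(f"unknown vegetation sources: {sorted(bad_sources)}")
    return frame


def assign_stages(records: pd.DataFrame, table: StageTable) -> pd.DataFrame:
    """Attach ``stage_index`` and stage-midpoint age to each record."""
    out = records.copy()
    idx = np.empty(len(out), dtype=int)
    mid = np.empty(len(out), dtype=float)
    for pos, age in enumerate(out["age_ma"].to_numpy(dtype=float)):
        idx[pos], mid[pos] = discretize_age(age, table)
    out["stage_index"] = idx
    out["stage_midpoint_ma"] = mid
    return out


def crop_to_window(
    records: pd.DataFrame, window: CropWindow = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Keep records inside the study window; input order preserved."""
    keep = window.contains(records["lon"].to_numpy(), records["lat"].to_numpy())
    return records.loc[keep].copy()


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop spatiotemporal duplicates, keeping the first record.

    A duplicate shares taxon, coordinates, and geological stage; records
    of the same taxon and location in different stages are distinct.
    """
    if "stage_index" not in records.columns:
        raise ValueError("records must be stage-discretized (assign_stages) first")
    return records.drop_duplicates(
        subset=["taxon", "lon", "lat", "stage_index"], keep="first"
    ).copy()


def filter_informative_taxa(
    records: pd.DataFrame, table: StageTable, min_stages: int = 9
) -> set[str]:
    """Taxa whose range-through stage span covers at least ``min_stages``.

    Presence is range-through: a taxon is assumed present in every stage
    between its first and last occurrence, so the criterion is the
    inclusive span of stage indices from the youngest to the oldest
    occurrence, not the number of stages with observed records.
    """
    if records.empty:
        return set()
    if "stage_index" not in records.columns:
        raise ValueError("records must be stage-discretized (assign_stages) first")
    spans = records.groupby("taxon")["stage_index"].agg(["min", "max"])
    span = spans["max"] - spans["min"] + 1
    return set(span.index[span >= min_stages])


def merge_sources(
    fossil: pd.DataFrame, current: pd.DataFrame, table: StageTable | None = None
) -> pd.DataFrame:
    """Concatenate fossil and current occurrences into one table.

    Current records are forced to age 0 (youngest stage if ``table`` is
    given). A taxon appearing in both tables must carry the same group
    label in each.
    """
    fossil = fossil.copy()
    current = current.copy()
    if not current.empty:
        if "age_ma" in current.columns and (current["age_ma"] != 0).any():
            warnings.warn("current occurrences had nonzero ages; reset to 0")
        current["age_ma"] = 0.0
        current["source"] = "current"
    frames = [f for f in (fossil, current) if not f.empty]
    merged = (
        pd.concat(frames, ignore_index=True) if frames else fossil.copy()
    )
    groups = merged.groupby("taxon")["group"].nunique()
    conflicted = list(groups.index[groups > 1])
    if conflicted:
        raise ValueError(
            f"conflicting group assignments for taxa: {conflicted}"
        )
    if table is not None:
        merged = assign_stages(merged, table)
    return merged
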