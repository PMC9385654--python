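"""Feature generation: biotic distance tensors and abiotic predictors.

Each instance (a point in space-time) is described by

* a *biotic* block: for every selected taxon and every geological
  stage, the pair (spatial distance to the taxon's nearest occurrence
  in that stage, temporal distance to the stage midpoint). Spatial
  distances are Euclidean in the Albers equal-area plane and use
  present-day coordinates; temporal distance is the absolute
  difference between the instance age and the stage midpoint.
* an *abiotic* block of 8 predictors: paleo-temperature,
  paleo-precipitation and elevation sampled from time-interpolated
  rasters at the instance's paleocoordinates; global mean temperature
  and CO2 interpolated from scalar curves at the instance age; and the
  paleocoordinates and age themselves.

All features (distances included) are min-max scaled to [0, 1] jointly
across every instance that will ever be seen by a model (training and
prediction alike), and the bounds are kept for reuse. Stages in which a
taxon has no occurrence receive a sentinel spatial distance equal to
the projected diagonal of the crop window — an upper bound on any real
distance, mapping to ~1 after scaling ("maximally far").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chrono import StageTable
from .occurrences import CropWindow
from .projection import AlbersEqualArea
from .rasters import Curve, RasterStack

__all__ = [
    "ABIOTIC_FEATURE_NAMES",
    "BioticDistanceTensor",
    "FeatureMatrix",
    "ModelData",
    "ScalingBounds",
    "sentinel_distance",
    "nearest_distance_per_stage",
    "build_distance_tensor",
    "extract_abiotic",
    "build_abiotic_matrix",
    "scale_features",
    "apply_scaling",
    "apply_joint_scaling",
    "perturb_features",
    "assemble_features",
    "prepare_datasets",
]

ABIOTIC_FEATURE_NAMES = [
    "paleo_temperature",
    "paleo_precipitation",
    "elevation",
    "global_temperature",
    "co2",
    "paleolon",
    "paleolat",
    "age_ma",
]

CLASS_NAMES = ["closed", "open"]  # fixed class order; pp reported for "open"


@dataclass
class BioticDistanceTensor:
    """Per-instance, per-taxon, per-stage (spatial, temporal) distances."""

    delta_s: np.ndarray  # [N, I, J], km (or unitless once scaled)
    delta_t: np.ndarray  # [N, I, J], Myr (or unitless once scaled)
    taxa: list[str]
    groups: list[str]  # 'mammal' | 'plant', aligned with taxa

    def __post_init__(self) -> None:
        if self.delta_s.shape != self.delta_t.shape:
            raise ValueError("delta_s and delta_t shapes differ")
        if self.delta_s.ndim != 3 or self.delta_s.shape[1] != len(self.taxa):
            raise ValueError("tensor shape inconsistent with the taxon list")
        if len(self.groups) != len(self.taxa):
            raise ValueError("groups must align with taxa")

    @property
    def n_instances(self) -> int:
        return self.delta_s.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.delta_s.shape[1]

    @property
    def n_stages(self) -> int:
        return self.delta_s.shape[2]

    def subset(self, idx) -> "BioticDistanceTensor":
        return BioticDistanceTensor(
            delta_s=self.delta_s[idx],
            delta_t=self.delta_t[idx],
            taxa=self.taxa,
            groups=self.groups,
        )


@dataclass
class FeatureMatrix:
    """A plain [instances x features] block with named columns."""

    values: np.ndarray
    feature_names: list[str]
    scaling_bounds: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape inconsistent with feature_names")


@dataclass(frozen=True)
class ScalingBounds:
    """Joint min-max bounds for the biotic tensor and abiotic columns.

    Persisted with a trained model so later prediction batches reuse the
    identical 0-1 mapping.
    """

    s_min: float
    s_max: float
    t_min: float
    t_max: float
    abiotic: tuple[tuple[float, float], ...]  # per abiotic column

    def to_dict(self) -> dict:
        return {
            "s_min": self.s_min,
            "s_max": self.s_max,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "abiotic": [list(b) for b in self.abiotic],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScalingBounds":
        return cls(
            s_min=float(payload["s_min"]),
            s_max=float(payload["s_max"]),
            t_min=float(payload["t_min"]),
            t_max=float(payload["t_max"]),
            abiotic=tuple(tuple(float(x) for x in b) for b in payload["abiotic"]),
        )


def sentinel_distance(
    window: CropWindow, projection: AlbersEqualArea | None = None
) -> float:
    """Projected diagonal of the crop window, km.

    Used as the spatial distance for (taxon, stage) cells with no
    occurrence: an upper bound on any within-window distance.
    """
    proj = projection if projection is not None else AlbersEqualArea()
    x0, y0 = proj(window.lon_min, window.lat_min)
    x1, y1 = proj(window.lon_max, window.lat_max)
    return float(np.hypot(x1 - x0, y1 - y0))


def nearest_distance_per_stage(
    instance,
    occurrences: pd.DataFrame,
    taxon: str,
    table: StageTable,
    projection: AlbersEqualArea | None = None,
    sentinel_km: float | None = None,
    window: CropWindow | None = None,
) -> list[tuple[float, float]]:
    """(delta_s, delta_t) pairs for one instance and taxon, one per stage.

    ``instance`` is any mapping with ``lon``, ``lat`` and ``age_ma``.
    Occurrences must be deduplicated and stage-discretized. Stages with
    no occurrence of the taxon get the sentinel spatial distance and the
    ordinary temporal distance.
    """
    proj = projection if projection is not None else AlbersEqualArea()
    if sentinel_km is None:
        if window is None:
            raise ValueError("provide either sentinel_km or a crop window")
        sentinel_km = sentinel_distance(window, proj)
    recs = occurrences[occurrences["taxon"] == taxon]
    if recs.empty:
        warnings.warn(f"taxon {taxon!r} has no occurrences; all-sentinel row")
    xi, yi = proj(float(instance["lon"]), float(instance["lat"]))
    age = float(instance["age_ma"])
    out = []
    for j, stage in enumerate(table.stages):
        dt = abs(age - stage.midpoint_ma)
        in_stage = recs[recs["stage_index"] == j]
        if in_stage.empty:
            out.append((sentinel_km, dt))
            continue
        xo, yo = proj(in_stage["lon"].to_numpy(), in_stage["lat"].to_numpy())
        ds = float(np.min(np.hypot(xo - xi, yo - yi)))
        out.append((ds, dt))
    return out


def build_distance_tensor(
    instances: pd.DataFrame,
    occurrences: pd.DataFrame,
    table: StageTable,
    taxa: list[str] | None = None,
    projection: AlbersEqualArea | None = None,
    window: CropWindow | None = None,
    sentinel_km: float | None = None,
) -> BioticDistanceTensor:
    """Vectorized distance tensor for a whole instance table.

    Distances use present-day coordinates (columns ``lon``/``lat``);
    continental drift over the study window is assumed to change
    relative within-region distances only negligibly.
    """
    proj = projection if projection is not None else AlbersEqualArea()
    if "stage_index" not in occurrences.columns:
        raise ValueError("occurrences must be stage-discretized first")
    if taxa is None:
        taxa = sorted(occurrences["taxon"].unique())
    group_of = (
        occurrences.drop_duplicates("taxon").set_index("taxon")["group"].to_dict()
    )
    groups = [group_of.get(t, "mammal") for t in taxa]
    if sentinel_km is None:
        if window is None:
            # fall back to the bounding box of everything we can see
            lon_all = np.concatenate(
                [instances["lon"].to_numpy(), occurrences["lon"].to_numpy()]
            )
            lat_all = np.concatenate(
                [instances["lat"].to_numpy(), occurrences["lat"].to_numpy()]
            )
            window = CropWindow(
                lon_min=float(lon_all.min()) - 1e-9,
                lat_min=float(lat_all.min()) - 1e-9,
                lon_max=float(lon_all.max()) + 1e-9,
                lat_max=float(lat_all.max()) + 1e-9,
            )
        sentinel_km = sentinel_distance(window, proj)

    n, n_taxa, n_stages = len(instances), len(taxa), len(table)
    xi, yi = proj(instances["lon"].to_numpy(float), instances["lat"].to_numpy(float))
    ages = instances["age_ma"].to_numpy(float)
    midpoints = np.asarray(table.midpoints_ma)

    delta_s = np.full((n, n_taxa, n_stages), sentinel_km, dtype=float)
    delta_t = np.abs(ages[:, None] - midpoints[None, :])  # [N, J]
    delta_t = np.broadcast_to(delta_t[:, None, :], (n, n_taxa, n_stages)).copy()

    taxon_pos = {t: i for i, t in enumerate(taxa)}
    occ = occurrences[occurrences["taxon"].isin(taxon_pos)]
    xo, yo = proj(occ["lon"].to_numpy(float), occ["lat"].to_numpy(float))
    occ_taxon = occ["taxon"].map(taxon_pos).to_numpy()
    occ_stage = occ["stage_index"].to_numpy()
    for i in range(n_taxa):
        for j in range(n_stages):
            mask = (occ_taxon == i) & (occ_stage == j)
            if not mask.any():
                continue
            dx = xi[:, None] - xo[mask][None, :]
            dy = yi[:, None] - yo[mask][None, :]
            delta_s[:, i, j] = np.hypot(dx, dy).min(axis=1)
    return BioticDistanceTensor(delta_s=delta_s, delta_t=delta_t, taxa=list(taxa), groups=groups)


def extract_abiotic(
    instance,
    raster_stacks: dict[str, RasterStack],
    curves: dict[str, Curve],
) -> np.ndarray:
    """The 8 abiotic predictors for one instance.

    ``raster_stacks`` must hold 'temperature', 'precipitation' and
    'elevation'; ``curves`` must hold 'global_temperature' and 'co2'.
    Paleocoordinates are taken from ``paleolon``/``paleolat`` when
    present, otherwise present-day coordinates are used (identity
    rotation) with a warning.
    """
    age = float(instance["age_ma"])
    try:
        plon = float(instance["paleolon"])
        plat = float(instance["paleolat"])
        if not (np.isfinite(plon) and np.isfinite(plat)):
            raise KeyError
    except (KeyError, TypeError):
        warnings.warn(
            "no paleocoordinates supplied; using present-day coordinates"
        )
        plon, plat = float(instance["lon"]), float(instance["lat"])
    values = np.empty(8, dtype=float)
    for pos, var in enumerate(("temperature", "precipitation", "elevation")):
        values[pos] = raster_stacks[var].at_age(age).sample(plon, plat)
    values[3] = curves["global_temperature"].at(age)
    values[4] = curves["co2"].at(age)
    values[5] = plon
    values[6] = plat
    values[7] = age
    return values


def build_abiotic_matrix(
    instances: pd.DataFrame,
    raster_stacks: dict[str, RasterStack],
    curves: dict[str, Curve],
) -> FeatureMatrix:
    """Abiotic feature matrix for a whole instance table.

    Rasters are interpolated once per distinct age, then sampled per
    instance.
    """
    n = len(instances)
    values = np.empty((n, 8), dtype=float)
    has_paleo = {"paleolon", "paleolat"}.issubset(instances.columns)
    if not has_paleo:
        warnings.warn(
            "instance table has no paleocoordinate columns; "
            "treating present-day coordinates as paleocoordinates"
        )
    ages = instances["age_ma"].to_numpy(float)
    plon = (
        instances["paleolon"].to_numpy(float)
        if has_paleo
        else instances["lon"].to_numpy(float)
    )
    plat = (
        instances["paleolat"].to_numpy(float)
        if has_paleo
        else instances["lat"].to_numpy(float)
    )
    for age in np.unique(ages):
        sel = np.flatnonzero(ages == age)
        slices = {
            var: raster_stacks[var].at_age(float(age))
            for var in ("temperature", "precipitation", "elevation")
        }
        for row in sel:
            for pos, var in enumerate(("temperature", "precipitation", "elevation")):
                values[row, pos] = slices[var].sample(plon[row], plat[row])
    values[:, 3] = curves["global_temperature"].at(ages)
    values[:, 4] = curves["co2"].at(ages)
    values[:, 5] = plon
    values[:, 6] = plat
    values[:, 7] = ages
    if not np.all(np.isfinite(values)):
        bad = [
            ABIOTIC_FEATURE_NAMES[k]
            for k in range(8)
            if not np.all(np.isfinite(values[:, k]))
        ]
        raise ValueError(f"non-finite abiotic features in columns {bad}")
    return FeatureMatrix(values=values, feature_names=list(ABIOTIC_FEATURE_NAMES))


def _minmax(column: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi > lo:
        return (column - lo) / (hi - lo)
    return np.zeros_like(column)  # constant column -> 0 by convention


def scale_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale every column to [0, 1], recording the bounds.

    The caller is responsible for concatenating *all* instances that
    share a model (training, test and prediction) before scaling, so
    the bounds are joint. Constant columns map to 0.
    """
    if not np.all(np.isfinite(matrix.values)):
        bad = [
            name
            for k, name in enumerate(matrix.feature_names)
            if not np.all(np.isfinite(matrix.values[:, k]))
        ]
        raise ValueError(f"non-finite values in columns {bad}")
    bounds = [
        (float(matrix.values[:, k].min()), float(matrix.values[:, k].max()))
        for k in range(matrix.values.shape[1])
    ]
    scaled = np.column_stack(
        [
            _minmax(matrix.values[:, k], lo, hi)
            for k, (lo, hi) in enumerate(bounds)
        ]
    )
    return FeatureMatrix(
        values=scaled,
        feature_names=list(matrix.feature_names),
        scaling_bounds=bounds,
    )


def apply_scaling(
    matrix: FeatureMatrix, bounds: list[tuple[float, float]]
) -> FeatureMatrix:
    """Re-apply previously fitted bounds (e.g. to a later prediction batch)."""
    if len(bounds) != matrix.values.shape[1]:
        raise ValueError("bounds length does not match the number of columns")
    scaled = np.column_stack(
        [
            _minmax(matrix.values[:, k], lo, hi)
            for k, (lo, hi) in enumerate(bounds)
        ]
    )
    return FeatureMatrix(
        values=scaled,
        feature_names=list(matrix.feature_names),
        scaling_bounds=list(bounds),
    )


def perturb_features(
    values: np.ndarray,
    columns,
    level: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Uniform multiplicative noise, the raster sensitivity test.

    Each selected value v is replaced by a draw from
    Uniform(v*(1-level), v*(1+level)); level 0 returns the input
    unchanged. Seeded and reproducible.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    out = np.array(values, dtype=float, copy=True)
    if level == 0:
        return out
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = list(columns)
    block = out[:, cols] if out.ndim == 2 else out[cols]
    lo = block * (1.0 - level)
    hi = block * (1.0 + level)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)  # negative values flip
    drawn = rng.uniform(lo, hi)
    if out.ndim == 2:
        out[:, cols] = drawn
    else:
        out[cols] = drawn
    return out


@dataclass
class ModelData:
    """Everything the classifier consumes for a set of instances."""

    tensor: BioticDistanceTensor
    abiotic: FeatureMatrix
    labels: np.ndarray | None = None  # 0 = closed, 1 = open
    source: np.ndarray | None = None  # 'paleo' | 'current' per instance
    scaling: ScalingBounds | None = None

    def __post_init__(self) -> None:
        if self.tensor.n_instances != self.abiotic.values.shape[0]:
            raise ValueError("tensor and abiotic matrix disagree on N")
        if self.labels is not None and len(self.labels) != self.n_instances:
            raise ValueError("labels length mismatch")

    @property
    def n_instances(self) -> int:
        return self.tensor.n_instances

    @property
    def feature_names(self) -> list[str]:
        return list(self.tensor.taxa) + list(self.abiotic.feature_names)

    @property
    def n_features(self) -> int:
        """Reported feature count: one per taxon plus the abiotic block."""
        return self.tensor.n_taxa + len(self.abiotic.feature_names)

    def subset(self, idx) -> "ModelData":
        return ModelData(
            tensor=self.tensor.subset(idx),
            abiotic=FeatureMatrix(
                values=self.abiotic.values[idx],
                feature_names=list(self.abiotic.feature_names),
                scaling_bounds=self.abiotic.scaling_bounds,
            ),
            labels=None if self.labels is None else np.asarray(self.labels)[idx],
            source=None if self.source is None else np.asarray(self.source)[idx],
            scaling=self.scaling,
        )


def assemble_features(
    tensor: BioticDistanceTensor,
    abiotic: FeatureMatrix,
    labels=None,
    source=None,
) -> ModelData:
    """Bundle the biotic tensor and abiotic matrix for one instance set.

    The biotic block stays a tensor (it is consumed by the network's
    sparse first layers); the reported feature count is
    ``n_taxa + n_abiotic``.
    """
    lab = None
    if labels is not None:
        lab = np.asarray(
            [CLASS_NAMES.index(l) if isinstance(l, str) else int(l) for l in labels]
        )
    src = None if source is None else np.asarray(source)
    return ModelData(tensor=tensor, abiotic=abiotic, labels=lab, source=src)


def _fit_joint_scaling(datasets: list[ModelData]) -> ScalingBounds:
    s_all = np.concatenate([d.tensor.delta_s.ravel() for d in datasets])
    t_all = np.concatenate([d.tensor.delta_t.ravel() for d in datasets])
    ab_all = np.vstack([d.abiotic.values for d in datasets])
    ab_bounds = tuple(
        (float(ab_all[:, k].min()), float(ab_all[:, k].max()))
        for k in range(ab_all.shape[1])
    )
    return ScalingBounds(
        s_min=float(s_all.min()),
        s_max=float(s_all.max()),
        t_min=float(t_all.min()),
        t_max=float(t_all.max()),
        abiotic=ab_bounds,
    )


def _apply_joint_scaling(data: ModelData, bounds: ScalingBounds) -> ModelData:
    def mm(a, lo, hi):
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    tensor = BioticDistanceTensor(
        delta_s=mm(data.tensor.delta_s, bounds.s_min, bounds.s_max),
        delta_t=mm(data.tensor.delta_t, bounds.t_min, bounds.t_max),
        taxa=data.tensor.taxa,
        groups=data.tensor.groups,
    )
    ab = apply_scaling(data.abiotic, [list(b) for b in bounds.abiotic])
    return ModelData(
        tensor=tensor,
        abiotic=ab,
        labels=data.labels,
        source=data.source,
        scaling=bounds,
    )


def apply_joint_scaling(data: ModelData, bounds: ScalingBounds) -> ModelData:
    """Scale a dataset with previously fitted joint bounds."""
    return _apply_joint_scaling(data, bounds)


def prepare_datasets(
    instance_tables: dict[str, pd.DataFrame],
    occurrences: pd.DataFrame,
    table: StageTable,
    raster_stacks: dict[str, RasterStack],
    curves: dict[str, Curve],
    taxa: list[str] | None = None,
    window: CropWindow | None = None,
    projection: AlbersEqualArea | None = None,
    bounds: ScalingBounds | None = None,
) -> dict[str, ModelData]:
    """Build jointly scaled model inputs for several instance tables.

    ``instance_tables`` maps a name (e.g. 'train', 'grid') to a table
    with columns ``lon, lat, age_ma`` plus optional ``paleolon,
    paleolat, label, source``. Feature scaling bounds are fitted on the
    concatenation of *all* tables so every dataset shares the same
    0-1 mapping, and are stored on each returned ``ModelData``; passing
    previously persisted ``bounds`` reuses that mapping instead.
    """
    if taxa is None:
        taxa = sorted(occurrences["taxon"].unique())
    raw: dict[str, ModelData] = {}
    for name, inst in instance_tables.items():
        tensor = build_distance_tensor(
            inst,
            occurrences,
            table,
            taxa=taxa,
            projection=projection,
            window=window,
        )
        abiotic = build_abiotic_matrix(inst, raster_stacks, curves)
        labels = inst["label"] if "label" in inst.columns else None
        source = inst["source"] if "source" in inst.columns else None
        raw[name] = assemble_features(tensor, abiotic, labels=labels, source=source)
    if bounds is None:
        bounds = _fit_joint_scaling(list(raw.values()))
    return {name: _apply_joint_scaling(d, bounds) for name, d in raw.items()}
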