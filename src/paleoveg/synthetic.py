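"""Synthetic landscapes for end-to-end testing without any downloads.

The generator emulates the structure of the real study inputs: a 2-D
land grid evolving over tens of Myr with a latent open/closed
vegetation field, taxa whose occurrences are biased toward one
vegetation type with controllable strength, smooth abiotic surfaces
correlated with the field, and labeled vegetation points drawn from it.

The latent field is a latitudinal frontier that drifts with age:
a cell is open iff its center latitude exceeds
``frontier_lat0 + frontier_shift_per_myr * age``, so open habitat
expands toward the present and the true open fraction at any age has a
closed form — which makes open-fraction and expansion-rate outputs
exactly checkable. Taxon occurrences land in open cells with
probability equal to the taxon's ``habitat_affinity`` (1 = strict
open-habitat specialist, 0 = strict forest specialist, 0.5 =
uninformative generalist). Abiotic surfaces are a smooth baseline
gradient plus an additive effect of the open/closed state plus Gaussian
noise. Everything is driven by a single seeded RNG, so all outputs are
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import Curve, Raster, RasterStack

__all__ = [
    "SyntheticTaxon",
    "SyntheticScenario",
    "TruthField",
    "default_taxa",
    "generate_truth_field",
    "generate_occurrences",
    "generate_abiotic_surfaces",
    "generate_training_points",
    "generate_bundle",
    "scenario_inputs",
]


@dataclass(frozen=True)
class SyntheticTaxon:
    name: str
    group: str  # 'mammal' | 'plant'
    habitat_affinity: float  # P(occurrence falls in an open cell)
    sampling_intensity: float  # mean occurrences per time slice

    def __post_init__(self) -> None:
        if not 0.0 <= self.habitat_affinity <= 1.0:
            raise ValueError("habitat_affinity must be in [0, 1]")
        if self.sampling_intensity < 0:
            raise ValueError("sampling_intensity must be >= 0")


def default_taxa(
    affinity_strong: float = 0.9, sampling_intensity: float = 8.0
) -> list[SyntheticTaxon]:
    """Twelve taxa: open specialists, forest specialists, generalists.

    ``affinity_strong`` sets the specialists' bias (open specialists get
    ``affinity_strong``, forest specialists ``1 - affinity_strong``).
    """
    taxa = []
    affinities = [
        affinity_strong,
        affinity_strong,
        1.0 - affinity_strong,
        1.0 - affinity_strong,
        0.5,
        0.5,
    ]
    kinds = ["open", "open", "forest", "forest", "generalist", "generalist"]
    for group in ("mammal", "plant"):
        for pos, (aff, kind) in enumerate(zip(affinities, kinds)):
            taxa.append(
                SyntheticTaxon(
                    name=f"{group}_{kind}_{pos % 2 + 1}",
                    group=group,
                    habitat_affinity=aff,
                    sampling_intensity=sampling_intensity,
                )
            )
    return taxa


@dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of one synthetic world.

    Defaults are sized for fast tests: a 20 x 20 one-degree grid, 10
    time slices over the last 27 Myr, 12 taxa, and roughly a thousand
    occurrences.
    """

    lon_min: float = -120.0
    lat_min: float = 30.0
    n_cols: int = 20
    n_rows: int = 20
    cellsize: float = 1.0
    time_span_ma: float = 27.0
    n_slices: int = 10
    # latent open/closed frontier: open iff lat > lat0 + shift * age
    frontier_lat0: float = 40.0
    frontier_shift_per_myr: float = 0.5
    taxa: tuple[SyntheticTaxon, ...] = field(
        default_factory=lambda: tuple(default_taxa())
    )
    # abiotic links: additive effect of the open state on each surface
    temperature_effect: float = 8.0  # deg C added in open cells
    precipitation_effect: float = -400.0  # mm/yr in open cells
    elevation_effect: float = 0.0  # m
    noise_sd: float = 0.5  # Gaussian noise on the temperature surface
    label_noise: float = 0.0  # P(training label flipped)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("need at least two time slices")
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be in [0, 1]")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cellsize

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cellsize

    @property
    def slice_ages(self) -> np.ndarray:
        return np.linspace(0.0, self.time_span_ma, self.n_slices)

    def frontier_lat(self, age_ma: float) -> float:
        return self.frontier_lat0 + self.frontier_shift_per_myr * age_ma


@dataclass
class TruthField:
    """The latent open/closed field on the scenario grid, per time slice."""

    scenario: SyntheticScenario
    slice_ages: np.ndarray
    open_field: np.ndarray  # [n_slices, n_rows, n_cols] bool, row 0 = north
    lon_centers: np.ndarray  # [n_cols]
    lat_centers: np.ndarray  # [n_rows], aligned with rows (row 0 = north)

    def slice_index(self, age_ma: float) -> int:
        return int(np.argmin(np.abs(self.slice_ages - age_ma)))

    def is_open(self, lon: float, lat: float, age_ma: float) -> bool:
        t = self.slice_index(age_ma)
        col = int((lon - self.scenario.lon_min) // self.scenario.cellsize)
        row_from_bottom = int(
            (lat - self.scenario.lat_min) // self.scenario.cellsize
        )
        row = self.scenario.n_rows - 1 - row_from_bottom
        return bool(self.open_field[t, row, col])

    def open_fraction(self, age_ma: float) -> float:
        """Realized open fraction of the grid at the nearest slice."""
        return float(self.open_field[self.slice_index(age_ma)].mean())

    def analytic_open_fraction(self, age_ma: float) -> float:
        """Closed-form open area fraction from the frontier parameters."""
        frontier = self.scenario.frontier_lat(age_ma)
        frac = (self.scenario.lat_max - frontier) / (
            self.scenario.lat_max - self.scenario.lat_min
        )
        return float(np.clip(frac, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, age in enumerate(self.slice_ages):
            for r, lat in enumerate(self.lat_centers):
                for c, lon in enumerate(self.lon_centers):
                    rows.append(
                        (float(age), float(lon), float(lat),
                         int(self.open_field[t, r, c]))
                    )
        return pd.DataFrame(rows, columns=["age_ma", "lon", "lat", "open"])


def generate_truth_field(scenario: SyntheticScenario) -> TruthField:
    """The deterministic latent open/closed grid per time slice."""
    lon_centers = scenario.lon_min + (np.arange(scenario.n_cols) + 0.5) * scenario.cellsize
    lat_bottom_up = scenario.lat_min + (np.arange(scenario.n_rows) + 0.5) * scenario.cellsize
    lat_centers = lat_bottom_up[::-1]  # row 0 = northernmost, matching Raster
    ages = scenario.slice_ages
    open_field = np.empty(
        (scenario.n_slices, scenario.n_rows, scenario.n_cols), dtype=bool
    )
    for t, age in enumerate(ages):
        frontier = scenario.frontier_lat(float(age))
        open_field[t] = (lat_centers > frontier)[:, None]
    return TruthField(
        scenario=scenario,
        slice_ages=ages,
        open_field=open_field,
        lon_centers=lon_centers,
        lat_centers=lat_centers,
    )


def _jitter_position(
    rng: np.random.Generator, lon_c: float, lat_c: float, cellsize: float
) -> tuple[float, float]:
    return (
        lon_c + rng.uniform(-0.5, 0.5) * cellsize * 0.98,
        lat_c + rng.uniform(-0.5, 0.5) * cellsize * 0.98,
    )


def generate_occurrences(
    scenario: SyntheticScenario,
    truth: TruthField,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Taxon occurrence table biased by habitat affinity.

    Per taxon and time slice the occurrence count is Poisson with the
    taxon's sampling intensity; each occurrence lands in a uniformly
    chosen open cell with probability ``habitat_affinity`` (falling back
    to the other category when the preferred one is absent from the
    slice), jittered within the cell and within the slice's age bin.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    spacing = (
        scenario.time_span_ma / (scenario.n_slices - 1)
        if scenario.n_slices > 1
        else 1.0
    )
    rows = []
    for taxon in scenario.taxa:
        for t, age in enumerate(truth.slice_ages):
            count = rng.poisson(taxon.sampling_intensity)
            if count == 0:
                continue
            open_cells = np.argwhere(truth.open_field[t])
            closed_cells = np.argwhere(~truth.open_field[t])
            for _ in range(count):
                want_open = rng.uniform() < taxon.habitat_affinity
                pool = open_cells if want_open else closed_cells
                if len(pool) == 0:
                    pool = closed_cells if want_open else open_cells
                r, c = pool[rng.integers(len(pool))]
                lon, lat = _jitter_position(
                    rng, truth.lon_centers[c], truth.lat_centers[r],
                    scenario.cellsize,
                )
                if age == 0:
                    age_j, source = 0.0, "current"
                else:
                    age_j = float(
                        np.clip(
                            age + rng.uniform(-0.5, 0.5) * spacing,
                            1e-6,
                            scenario.time_span_ma,
                        )
                    )
                    source = "fossil"
                rows.append(
                    (taxon.name, taxon.group, lon, lat, age_j, source)
                )
    return pd.DataFrame(
        rows, columns=["taxon", "group", "lon", "lat", "age_ma", "source"]
    )


def generate_abiotic_surfaces(
    scenario: SyntheticScenario,
    truth: TruthField,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, RasterStack], dict[str, Curve]]:
    """Raster stacks (temperature, precipitation, elevation) and curves.

    Each surface is a smooth baseline gradient plus the scenario's
    additive open-state effect plus Gaussian noise; the global curves
    are smooth functions of age. With zero effects and zero noise the
    surfaces equal the baselines exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    lat_grid = np.broadcast_to(
        truth.lat_centers[:, None], (scenario.n_rows, scenario.n_cols)
    )
    lon_grid = np.broadcast_to(
        truth.lon_centers[None, :], (scenario.n_rows, scenario.n_cols)
    )
    base_temperature = 25.0 - 0.6 * (lat_grid - scenario.lat_min)
    base_precipitation = 600.0 + 15.0 * (lon_grid - scenario.lon_min)
    base_elevation = 300.0 + 12.0 * (lat_grid - scenario.lat_min)
    stacks: dict[str, dict[float, Raster]] = {
        "temperature": {},
        "precipitation": {},
        "elevation": {},
    }
    for t, age in enumerate(truth.slice_ages):
        is_open = truth.open_field[t].astype(float)
        surfaces = {
            "temperature": base_temperature
            + scenario.temperature_effect * is_open
            + rng.normal(0.0, scenario.noise_sd, is_open.shape),
            "precipitation": base_precipitation
            + scenario.precipitation_effect * is_open
            + rng.normal(0.0, scenario.noise_sd * 50.0, is_open.shape),
            "elevation": base_elevation
            + scenario.elevation_effect * is_open
            + rng.normal(0.0, scenario.noise_sd * 20.0, is_open.shape),
        }
        for var, values in surfaces.items():
            stacks[var][float(age)] = Raster(
                values=values,
                xll=scenario.lon_min,
                yll=scenario.lat_min,
                cellsize=scenario.cellsize,
            )
    raster_stacks = {var: RasterStack(s) for var, s in stacks.items()}
    curve_ages = np.arange(0.0, scenario.time_span_ma + 1e-9, 1.0)
    curves = {
        "global_temperature": Curve(curve_ages, 14.0 + 0.25 * curve_ages),
        "co2": Curve(curve_ages, 280.0 + 8.0 * curve_ages),
    }
    return raster_stacks, curves


def generate_training_points(
    scenario: SyntheticScenario,
    truth: TruthField,
    n_paleo: int = 331,
    n_current: int = 331,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Labeled vegetation points sampled from the truth field.

    Paleo points are drawn uniformly over (land cell, past slice)
    combinations without replacement where possible (with replacement
    plus a warning otherwise); current points over land cells at age 0.
    Points sit at cell centers so labels read directly off the truth
    field, apart from the scenario's optional label noise.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 2)
    n_cells = scenario.n_rows * scenario.n_cols
    past = np.flatnonzero(truth.slice_ages > 0)
    rows = []

    def draw(pool_size: int, n: int) -> np.ndarray:
        if n > pool_size:
            warnings.warn(
                f"requested {n} points from {pool_size} cells; "
                "sampling with replacement"
            )
            return rng.integers(pool_size, size=n)
        return rng.choice(pool_size, size=n, replace=False)

    for combo in draw(len(past) * n_cells, n_paleo):
        t = past[combo // n_cells]
        cell = combo % n_cells
        r, c = divmod(cell, scenario.n_cols)
        rows.append((t, r, c, "paleo"))
    for cell in draw(n_cells, n_current):
        r, c = divmod(cell, scenario.n_cols)
        rows.append((0, r, c, "current"))

    records = []
    for t, r, c, source in rows:
        truth_open = bool(truth.open_field[t, r, c])
        if scenario.label_noise > 0 and rng.uniform() < scenario.label_noise:
            truth_open = not truth_open
        records.append(
            {
                "lon": float(truth.lon_centers[c]),
                "lat": float(truth.lat_centers[r]),
                # the synthetic world has no plate motion: paleo == modern
                "paleolon": float(truth.lon_centers[c]),
                "paleolat": float(truth.lat_centers[r]),
                "age_ma": float(truth.slice_ages[t]),
                "label": "open" if truth_open else "closed",
                "source": source,
            }
        )
    return pd.DataFrame(records)


def grid_instances(truth: TruthField, ages) -> pd.DataFrame:
    """Prediction instances at every cell center for each requested age."""
    rows = []
    for age in np.atleast_1d(np.asarray(ages, dtype=float)):
        for lat in truth.lat_centers:
            for lon in truth.lon_centers:
                rows.append(
                    (float(lon), float(lat), float(lon), float(lat), float(age))
                )
    return pd.DataFrame(
        rows, columns=["lon", "lat", "paleolon", "paleolat", "age_ma"]
    )


def scenario_inputs(
    scenario: SyntheticScenario,
    n_paleo: int = 331,
    n_current: int = 331,
):
    """Generate the full in-memory input bundle for one scenario.

    Returns ``(truth, occurrences, vegetation_points, raster_stacks,
    curves)``, all derived from the scenario's seed.
    """
    truth = generate_truth_field(scenario)
    rng = np.random.default_rng(scenario.seed)
    occurrences = generate_occurrences(scenario, truth, rng)
    raster_stacks, curves = generate_abiotic_surfaces(scenario, truth, rng)
    points = generate_training_points(scenario, truth, n_paleo, n_current, rng)
    return truth, occurrences, points, raster_stacks, curves


def generate_bundle(
    scenario: SyntheticScenario,
    outdir,
    n_paleo: int = 331,
    n_current: int = 331,
) -> dict[str, str]:
    """Write the full synthetic input bundle to a directory.

    Emits ``occurrences.csv``, ``vegetation_points.csv``,
    ``truth_field.csv``, ``global_temperature.csv`` and ``co2.csv``,
    plus a ``rasters/`` subdirectory of plain-text grids
    (``<variable>_<age>ma.asc``). Returns the paths written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, occurrences, points, raster_stacks, curves = scenario_inputs(
        scenario, n_paleo, n_current
    )
    paths = {}
    occurrences.to_csv(outdir / "occurrences.csv", index=False)
    paths["occurrences"] = str(outdir / "occurrences.csv")
    points.to_csv(outdir / "vegetation_points.csv", index=False)
    paths["vegetation_points"] = str(outdir / "vegetation_points.csv")
    truth.to_frame().to_csv(outdir / "truth_field.csv", index=False)
    paths["truth_field"] = str(outdir / "truth_field.csv")
    for name, curve in curves.items():
        curve.to_csv(outdir / f"{name}.csv")
        paths[name] = str(outdir / f"{name}.csv")
    raster_dir = outdir / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for var, stack in raster_stacks.items():
        for age in stack.ages:
            fname = raster_dir / f"{var}_{age:g}ma.asc"
            stack.slices[age].to_ascii(fname)
    paths["rasters"] = str(raster_dir)
    return paths
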