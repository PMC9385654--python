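"""Chronostratigraphic stage table and age discretization.

Fossil occurrences and vegetation points are binned into geological
stages, the finest formal divisions of the International
Chronostratigraphic Chart (ICS, v2020/03). Ages are discretized to the
midpoint of the containing stage. The chart boundaries for the last
33.9 Myr are embedded below so no download is needed; a user-supplied
CSV (columns ``name,top_ma,base_ma``) can override them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GeoStage", "StageTable", "load_stage_table", "discretize_age"]

# ICS v2020/03 stage boundaries (Ma), young -> old, covering 0-33.9 Ma.
# "Upper Pleistocene" is the chart's unnamed Upper Pleistocene stage.
_ICS_2020_03 = [
    ("Meghalayan", 0.0, 0.0042),
    ("Northgrippian", 0.0042, 0.0082),
    ("Greenlandian", 0.0082, 0.0117),
    ("Upper Pleistocene", 0.0117, 0.129),
    ("Chibanian", 0.129, 0.774),
    ("Calabrian", 0.774, 1.80),
    ("Gelasian", 1.80, 2.58),
    ("Piacenzian", 2.58, 3.600),
    ("Zanclean", 3.600, 5.333),
    ("Messinian", 5.333, 7.246),
    ("Tortonian", 7.246, 11.63),
    ("Serravallian", 11.63, 13.82),
    ("Langhian", 13.82, 15.97),
    ("Burdigalian", 15.97, 20.44),
    ("Aquitanian", 20.44, 23.03),
    ("Chattian", 23.03, 27.82),
    ("Rupelian", 27.82, 33.9),
]


@dataclass(frozen=True)
class GeoStage:
    """A geological stage with its age bounds (Ma) and midpoint."""

    name: str
    top_ma: float
    base_ma: float

    def __post_init__(self) -> None:
        if not self.top_ma < self.base_ma:
            raise ValueError(
                f"stage {self.name!r}: top_ma ({self.top_ma}) must be "
                f"younger than base_ma ({self.base_ma})"
            )
        if self.top_ma < 0:
            raise ValueError(f"stage {self.name!r}: top_ma must be >= 0")

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.top_ma + self.base_ma)

    def contains(self, age_ma: float) -> bool:
        """Half-open convention: ``top_ma <= age < base_ma``.

        A boundary age belongs to the older of the two adjacent stages.
        """
        return self.top_ma <= age_ma < self.base_ma


@dataclass(frozen=True)
class StageTable:
    """Ordered (young -> old), contiguous, non-overlapping stages."""

    stages: tuple[GeoStage, ...]
    window_max_ma: float = 30.0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("StageTable needs at least one stage")
        for younger, older in zip(self.stages, self.stages[1:]):
            if younger.base_ma != older.top_ma:
                raise ValueError(
                    f"stages {younger.name!r} and {older.name!r} are not "
                    "contiguous"
                )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def midpoints_ma(self) -> tuple[float, ...]:
        return tuple(s.midpoint_ma for s in self.stages)

    @property
    def span_ma(self) -> float:
        """Total covered age span (sum of stage durations)."""
        return self.stages[-1].base_ma - self.stages[0].top_ma

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.stages],
                "top_ma": [s.top_ma for s in self.stages],
                "base_ma": [s.base_ma for s in self.stages],
                "midpoint_ma": [s.midpoint_ma for s in self.stages],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame()[["name", "top_ma", "base_ma"]].to_csv(path, index=False)


def load_stage_table(window_max_ma: float = 30.0, csv_path=None) -> StageTable:
    """Stages whose interval intersects ``[0, window_max_ma]``, young -> old.

    Parameters
    ----------
    window_max_ma
        Oldest age of interest, Ma. The default 30 Ma window retains 17
        stages of the embedded ICS v2020/03 chart.
    csv_path
        Optional CSV override with columns ``name, top_ma, base_ma``.
    """
    if window_max_ma <= 0:
        raise ValueError("window_max_ma must be positive")
    if csv_path is not None:
        frame = pd.read_csv(csv_path)
        rows = [
            (str(r["name"]), float(r["top_ma"]), float(r["base_ma"]))
            for _, r in frame.iterrows()
        ]
        rows.sort(key=lambda r: r[1])
    else:
        rows = _ICS_2020_03
    coverage = max(r[2] for r in rows)
    if window_max_ma > coverage:
        raise ValueError(
            f"window_max_ma={window_max_ma} exceeds the stage table "
            f"coverage ({coverage} Ma); supply a longer table via csv_path"
        )
    kept = tuple(
        GeoStage(name, top, base)
        for name, top, base in rows
        if top < window_max_ma  # interval [top, base) intersects [0, window]
    )
    return StageTable(stages=kept, window_max_ma=window_max_ma)


def discretize_age(age_ma: float, table: StageTable) -> tuple[int, float]:
    """Map an age to its stage index and stage midpoint.

    Stage intervals are half-open ``[top_ma, base_ma)``; an age exactly on
    a shared boundary is assigned to the older stage. Returns
    ``(stage_index, midpoint_ma)``.
    """
    if age_ma < 0 or age_ma > table.window_max_ma:
        raise ValueError(
            f"age {age_ma} Ma outside the window [0, {table.window_max_ma}]"
        )
    for k, stage in enumerate(table.stages):
        if stage.contains(age_ma):
            return k, stage.midpoint_ma
    # age == base of the oldest stage (only possible when the window
    # extends exactly to the table's oldest boundary)
    last = len(table.stages) - 1
    return last, table.stages[last].midpoint_ma
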