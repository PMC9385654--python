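"""Posterior prediction and downstream summaries.

Class probabilities for new instances are averaged over the post-burn-in
weight samples (the posterior probability, PP). Predictions can be
thresholded: an instance whose winning-class PP falls below the
threshold is labeled ``unknown``. The threshold itself is calibrated on
labeled data as the smallest value on a 0.01 grid over [0.5, 1.0] whose
retained predictions reach a target accuracy (default 90%).

Gridded predictions feed time series of the open-habitat fraction with
95% highest-posterior-density (HPD) bands and per-Myr expansion rates,
and per-taxon habitat associations (the share of a taxon's occurrences
falling in open-classified cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .features import CLASS_NAMES, ModelData
from .bnn import WeightSample, forward
from .mcmc import PosteriorTrace

__all__ = [
    "PredictionResult",
    "OpenFractionSeries",
    "posterior_probs",
    "calibrate_threshold",
    "predict_grid",
    "hpd_interval",
    "open_fraction_series",
    "expansion_rate",
    "habitat_association",
]

OPEN, CLOSED = 1, 0  # indices into CLASS_NAMES


@dataclass
class PredictionResult:
    """Posterior class probabilities and per-sample classifications."""

    pp: np.ndarray  # [N, n_classes], mean probabilities across samples
    per_sample_class: np.ndarray  # [N, S] argmax class per posterior sample
    threshold_used: float | None = None

    @property
    def pp_open(self) -> np.ndarray:
        return self.pp[:, OPEN]

    @property
    def winning_pp(self) -> np.ndarray:
        return self.pp.max(axis=1)

    def classify(self, threshold: float | None = None) -> np.ndarray:
        """Class labels at a PP threshold: open / closed / unknown.

        ``unknown`` wherever the winning class's PP is below the
        threshold. ``threshold=None`` (or 0.5) retains everything.
        """
        if threshold is None:
            threshold = self.threshold_used if self.threshold_used is not None else 0.5
        winners = self.pp.argmax(axis=1)
        labels = np.array([CLASS_NAMES[w] for w in winners], dtype=object)
        labels[self.winning_pp < threshold] = "unknown"
        return labels


def posterior_probs(
    trace: PosteriorTrace,
    data: ModelData,
    max_samples: int | None = None,
    seed: int = 0,
) -> PredictionResult:
    """Forward pass per retained posterior sample, averaged into PPs.

    ``max_samples`` randomly subsamples the post-burn-in trace (seeded)
    to bound prediction cost.
    """
    block = trace.post_burnin
    if block.shape[0] == 0:
        raise ValueError("trace has no post-burn-in samples")
    if max_samples is not None and max_samples < block.shape[0]:
        rng = np.random.default_rng(seed)
        keep = rng.choice(block.shape[0], size=max_samples, replace=False)
        block = block[np.sort(keep)]
    n = data.n_instances
    pp_sum = np.zeros((n, trace.config.n_classes))
    per_sample = np.empty((n, block.shape[0]), dtype=np.int8)
    for s, vec in enumerate(block):
        probs = forward(WeightSample(trace.config, vec), data)
        pp_sum += probs
        per_sample[:, s] = probs.argmax(axis=1)
    return PredictionResult(pp=pp_sum / block.shape[0], per_sample_class=per_sample)


def calibrate_threshold(
    pp_open: np.ndarray,
    true_labels: np.ndarray,
    target_accuracy: float = 0.9,
    grid_step: float = 0.01,
) -> tuple[float, float]:
    """Smallest PP threshold reaching the target accuracy on retained points.

    The threshold applies to the winning class's PP
    (``max(pp_open, 1 - pp_open)``), scanned over the grid
    [0.5, 1.0] in ``grid_step`` increments. Returns
    ``(threshold, fraction_retained)``; if no threshold attains the
    target the threshold is set to 1.0 with nothing retained (every
    prediction labeled unknown).
    """
    pp_open = np.asarray(pp_open, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    if pp_open.size == 0:
        raise ValueError("empty calibration set")
    predicted = (pp_open >= 0.5).astype(int)
    winning = np.maximum(pp_open, 1.0 - pp_open)
    correct = predicted == true_labels
    n_grid = int(round(0.5 / grid_step))
    for k in range(n_grid + 1):
        threshold = round(0.5 + k * grid_step, 10)
        retained = winning >= threshold
        n_ret = int(retained.sum())
        if n_ret == 0:
            continue
        if correct[retained].mean() >= target_accuracy:
            return float(threshold), n_ret / pp_open.size
    return 1.0, 0.0


def predict_grid(
    trace: PosteriorTrace,
    grid_data: ModelData,
    grid_table: pd.DataFrame,
    threshold: float = 0.5,
    max_samples: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, PredictionResult]:
    """Thresholded class map for a grid of instances.

    Returns a table (lon, lat, age_ma, pp_open, class) alongside the
    raw ``PredictionResult``. Raising the threshold can only grow the
    set of unknown cells.
    """
    if grid_data.scaling is None:
        raise ValueError(
            "grid features are unscaled; build them through prepare_datasets"
        )
    result = posterior_probs(trace, grid_data, max_samples=max_samples, seed=seed)
    result.threshold_used = threshold
    out = pd.DataFrame(
        {
            "lon": grid_table["lon"].to_numpy(),
            "lat": grid_table["lat"].to_numpy(),
            "age_ma": grid_table["age_ma"].to_numpy(),
            "pp_open": result.pp_open,
            "class": result.classify(threshold),
        }
    )
    return out, result


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if n < 2:
        return float(x[0]), float(x[0])
    m = int(np.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    start = int(np.argmin(widths))
    return float(x[start]), float(x[start + m - 1])


@dataclass
class OpenFractionSeries:
    """Open-habitat fraction through time with 95% HPD bands."""

    ages: np.ndarray  # Ma, ascending
    mean_fraction: np.ndarray
    hpd_low: np.ndarray
    hpd_high: np.ndarray
    fractions: np.ndarray  # [n_ages, n_samples] per-sample fractions
    rate: np.ndarray | None = None  # change per Myr toward the present

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "age_ma": self.ages,
                "mean_fraction": self.mean_fraction,
                "hpd_low": self.hpd_low,
                "hpd_high": self.hpd_high,
            }
        )
        if self.rate is not None:
            frame["rate_per_myr"] = self.rate
        return frame


def open_fraction_series(
    per_sample_class_by_age: dict[float, np.ndarray],
    land_mask_by_age: dict[float, np.ndarray] | None = None,
    mass: float = 0.95,
) -> OpenFractionSeries:
    """Fraction of land cells classified open, per age and posterior sample.

    ``per_sample_class_by_age`` maps an age to an [n_cells, n_samples]
    array of per-sample argmax classes (1 = open). The mean and the HPD
    band are taken across posterior samples at each age; the expansion
    rate is the change of the mean fraction over each preceding 1-Myr
    bin (computed whenever the next-older age is present).
    """
    ages = np.array(sorted(per_sample_class_by_age), dtype=float)
    means, lows, highs, all_fracs = [], [], [], []
    for age in ages:
        classes = np.asarray(per_sample_class_by_age[age])
        if land_mask_by_age is not None:
            mask = np.asarray(land_mask_by_age[age], dtype=bool)
            if not mask.any():
                raise ValueError(f"empty land mask at age {age}")
            classes = classes[mask]
        if classes.size == 0:
            raise ValueError(f"no cells at age {age}")
        fracs = (classes == OPEN).mean(axis=0)  # one fraction per sample
        lo, hi = hpd_interval(fracs, mass) if fracs.size > 1 else (fracs[0], fracs[0])
        means.append(fracs.mean())
        lows.append(lo)
        highs.append(hi)
        all_fracs.append(fracs)
    series = OpenFractionSeries(
        ages=ages,
        mean_fraction=np.array(means),
        hpd_low=np.array(lows),
        hpd_high=np.array(highs),
        fractions=np.array(all_fracs),
    )
    series.rate = expansion_rate(series)
    return series


def expansion_rate(series: OpenFractionSeries) -> np.ndarray:
    """Mean open-fraction change per Myr across each preceding time bin.

    The rate at age t is ``mean(t) - mean(t_next_older)`` divided by the
    bin width, i.e. positive while open habitat expands toward the
    present. The oldest age has no preceding bin and gets NaN; a
    single-age series yields an all-NaN (empty) rate.
    """
    rate = np.full(series.ages.size, np.nan)
    for k in range(series.ages.size - 1):
        dt = series.ages[k + 1] - series.ages[k]
        rate[k] = (series.mean_fraction[k] - series.mean_fraction[k + 1]) / dt
    return rate


def habitat_association(
    occurrences: pd.DataFrame,
    class_maps_by_age: dict[float, pd.DataFrame],
    max_cell_distance_deg: float | None = None,
) -> pd.DataFrame:
    """Per-taxon fraction of occurrences falling in open-classified cells.

    Each occurrence is matched to the class map at the nearest available
    age, then to its nearest grid cell (optionally bounded by
    ``max_cell_distance_deg``). Cells classified ``unknown`` are
    excluded from both numerator and denominator. Returns one row per
    taxon with counts and ``fraction_open`` (NaN when no occurrence
    resolves to a known cell).
    """
    if not class_maps_by_age:
        raise ValueError("no class maps supplied")
    map_ages = np.array(sorted(class_maps_by_age), dtype=float)
    trees = {}
    for age in map_ages:
        cmap = class_maps_by_age[age]
        trees[float(age)] = (
            cKDTree(np.column_stack([cmap["lon"], cmap["lat"]])),
            cmap["class"].to_numpy(),
        )
    rows = []
    for taxon, recs in occurrences.groupby("taxon"):
        n_open = n_closed = n_unknown = n_unresolved = 0
        for _, rec in recs.iterrows():
            age = map_ages[np.argmin(np.abs(map_ages - float(rec["age_ma"])))]
            tree, classes = trees[float(age)]
            dist, cell = tree.query([float(rec["lon"]), float(rec["lat"])])
            if max_cell_distance_deg is not None and dist > max_cell_distance_deg:
                n_unresolved += 1
                continue
            cls = classes[cell]
            if cls == "open":
                n_open += 1
            elif cls == "closed":
                n_closed += 1
            else:
                n_unknown += 1
        known = n_open + n_closed
        rows.append(
            {
                "taxon": taxon,
                "n_open": n_open,
                "n_closed": n_closed,
                "n_unknown": n_unknown,
                "n_unresolved": n_unresolved,
                "fraction_open": n_open / known if known else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")
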