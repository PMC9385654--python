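"""Model evaluation: cross-validation, weighted accuracy, importance.

Models are scored by five-fold cross-validation stratified by the
instance source, so each fold holds the same proportion of
paleovegetation and current-vegetation points. The headline score is
the weighted mean of the paleo and current test accuracies with the
paleo component weighted ten times higher (it spans many geological
stages, the current data only one). Feature relevance is measured by
permutation importance: the drop in prediction accuracy (delta-acc)
after shuffling one feature across instances, averaged over randomly
selected posterior weight samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .bnn import BNNConfig, WeightSample, forward
from .features import ModelData
from .inference import calibrate_threshold, posterior_probs
from .mcmc import MCMCSettings, PosteriorTrace, run_chain

__all__ = [
    "CVFold",
    "make_cv_folds",
    "weighted_accuracy",
    "permutation_importance",
    "evaluate_model",
    "EvaluationReport",
]


@dataclass(frozen=True)
class CVFold:
    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def make_cv_folds(source: np.ndarray, k: int = 5, seed: int = 0) -> list[CVFold]:
    """Stratified k-fold split on the instance source labels.

    The folds partition the instances; each preserves the global
    paleo:current ratio to within one instance per source.
    """
    source = np.asarray(source)
    counts = pd.Series(source).value_counts()
    if (counts < k).any():
        raise ValueError(f"need at least {k} instances per source class")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros(len(source))
    return [
        CVFold(fold_id=i, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(splitter.split(dummy, source))
    ]


def weighted_accuracy(
    acc_paleo: float, acc_current: float, weight: float = 10.0
) -> float:
    """Paleo-weighted mean accuracy: (w * paleo + current) / (w + 1)."""
    if not (0 <= acc_paleo <= 1 and 0 <= acc_current <= 1):
        raise ValueError("accuracies must be in [0, 1]")
    return (weight * acc_paleo + acc_current) / (weight + 1.0)


def _sample_accuracy(vec: np.ndarray, config: BNNConfig, data: ModelData) -> float:
    probs = forward(WeightSample(config, vec), data)
    return float((probs.argmax(axis=1) == data.labels).mean())


@dataclass
class ImportanceReport:
    """Per-feature delta-accuracy across posterior samples."""

    feature_names: list[str]
    delta_accuracy: np.ndarray  # [n_features, n_posterior] per-sample values
    n_posterior_samples: int

    @property
    def mean_delta_accuracy(self) -> np.ndarray:
        return self.delta_accuracy.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "feature": self.feature_names,
                "delta_accuracy": self.mean_delta_accuracy,
            }
        )
        return frame.sort_values(
            "delta_accuracy", ascending=False, ignore_index=True
        )

    def rank_of(self, feature: str) -> int:
        """1-based importance rank (1 = largest mean delta-accuracy)."""
        ordered = self.to_frame()["feature"].tolist()
        return ordered.index(feature) + 1


def permutation_importance(
    trace: PosteriorTrace,
    data: ModelData,
    n_posterior: int = 100,
    n_shuffles: int = 1,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation feature importance over posterior weight samples.

    For each selected post-burn-in sample and each feature, the feature
    is shuffled across instances and delta-acc = baseline accuracy
    minus shuffled accuracy. A biotic (taxon) feature is shuffled as a
    unit: the taxon's whole per-stage distance block moves between
    instances, spatial and temporal distances together. Permutations
    are drawn once per (feature, shuffle) and reused across posterior
    samples. The baseline is computed per sample, not on the
    posterior-mean prediction.
    """
    if data.labels is None:
        raise ValueError("permutation importance needs labeled data")
    block = trace.post_burnin
    if block.shape[0] == 0:
        raise ValueError("trace has no post-burn-in samples")
    rng = np.random.default_rng(seed)
    if n_posterior > block.shape[0]:
        import warnings

        warnings.warn(
            f"n_posterior={n_posterior} exceeds the {block.shape[0]} retained "
            "samples; using all of them"
        )
        n_posterior = block.shape[0]
    keep = np.sort(rng.choice(block.shape[0], size=n_posterior, replace=False))
    block = block[keep]

    cfg = trace.config
    n = data.n_instances
    taxa = data.tensor.taxa if cfg.use_biotic else []
    abiotic_names = data.abiotic.feature_names if cfg.use_abiotic else []
    feature_names = list(taxa) + list(abiotic_names)
    perms = [
        [rng.permutation(n) for _ in range(n_shuffles)] for _ in feature_names
    ]

    baseline = np.array(
        [_sample_accuracy(vec, cfg, data) for vec in block]
    )
    delta = np.zeros((len(feature_names), n_posterior))
    for f, name in enumerate(feature_names):
        for perm in perms[f]:
            shuffled = _shuffle_feature(data, f, len(taxa), perm)
            accs = np.array(
                [_sample_accuracy(vec, cfg, shuffled) for vec in block]
            )
            delta[f] += baseline - accs
        delta[f] /= n_shuffles
    return ImportanceReport(
        feature_names=feature_names,
        delta_accuracy=delta,
        n_posterior_samples=n_posterior,
    )


def _shuffle_feature(
    data: ModelData, feature_pos: int, n_taxa: int, perm: np.ndarray
) -> ModelData:
    from .features import BioticDistanceTensor, FeatureMatrix

    if feature_pos < n_taxa:
        ds = data.tensor.delta_s.copy()
        dt = data.tensor.delta_t.copy()
        ds[:, feature_pos, :] = ds[perm, feature_pos, :]
        dt[:, feature_pos, :] = dt[perm, feature_pos, :]
        tensor = BioticDistanceTensor(
            delta_s=ds, delta_t=dt, taxa=data.tensor.taxa, groups=data.tensor.groups
        )
        abiotic = data.abiotic
    else:
        col = feature_pos - n_taxa
        values = data.abiotic.values.copy()
        values[:, col] = values[perm, col]
        abiotic = FeatureMatrix(
            values=values,
            feature_names=data.abiotic.feature_names,
            scaling_bounds=data.abiotic.scaling_bounds,
        )
        tensor = data.tensor
    return ModelData(
        tensor=tensor,
        abiotic=abiotic,
        labels=data.labels,
        source=data.source,
        scaling=data.scaling,
    )


@dataclass
class FoldResult:
    fold_id: int
    n_train: int
    n_test: int
    acc_paleo: float
    acc_current: float
    acc_weighted: float


@dataclass
class EvaluationReport:
    """Cross-validation accuracy report for one model configuration."""

    config: BNNConfig
    folds: list[FoldResult]
    acc_paleo: float  # pooled over all test instances
    acc_current: float
    acc_weighted: float
    acc_overall: float  # plain pooled fraction correct, all sources
    pp_threshold: float
    fraction_retained: float
    traces: list[PosteriorTrace] = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        return {
            "architecture": "-".join(str(n) for n in self.config.hidden_layout),
            "pooling": self.config.pooling,
            "features": (
                "all"
                if self.config.use_biotic and self.config.use_abiotic
                else ("biotic" if self.config.use_biotic else "abiotic")
            ),
            "accuracy": self.acc_weighted,
            "accuracy_overall": self.acc_overall,
            "accuracy_paleo": self.acc_paleo,
            "accuracy_current": self.acc_current,
            "pp_threshold": self.pp_threshold,
            "fraction_above_threshold": self.fraction_retained,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()])


def _accuracy_by_source(
    pp_open: np.ndarray, labels: np.ndarray, source: np.ndarray
) -> tuple[float, float]:
    predicted = (pp_open >= 0.5).astype(int)
    correct = predicted == labels
    paleo = source == "paleo"
    current = source == "current"
    acc_p = float(correct[paleo].mean()) if paleo.any() else np.nan
    acc_c = float(correct[current].mean()) if current.any() else np.nan
    return acc_p, acc_c


def evaluate_model(
    data: ModelData,
    config: BNNConfig,
    settings: MCMCSettings,
    k: int = 5,
    target_accuracy: float = 0.9,
    seed: int = 0,
    max_prediction_samples: int | None = None,
    keep_traces: bool = False,
) -> EvaluationReport:
    """Train and score one configuration by stratified k-fold CV.

    Each fold trains its own chain (seeded deterministically from
    ``seed`` and the fold id); test predictions are pooled across folds
    before computing the headline accuracies, the 10:1 weighted
    accuracy, and the calibrated PP threshold (calibrated on the pooled
    paleovegetation test predictions when any are present).
    """
    if data.labels is None or data.source is None:
        raise ValueError("evaluation needs labeled instances with sources")
    folds = make_cv_folds(data.source, k=k, seed=seed)
    fold_results: list[FoldResult] = []
    traces = []
    pooled_pp = np.empty(data.n_instances)
    for fold in folds:
        fold_seed = (seed * 1009 + fold.fold_id + 1) % (2**31)
        fold_settings = replace(settings, seed=fold_seed)
        train = data.subset(fold.train_indices)
        test = data.subset(fold.test_indices)
        trace = run_chain(train, config, fold_settings)
        result = posterior_probs(
            trace, test, max_samples=max_prediction_samples, seed=fold_seed
        )
        pooled_pp[fold.test_indices] = result.pp_open
        acc_p, acc_c = _accuracy_by_source(
            result.pp_open, test.labels, test.source
        )
        fold_results.append(
            FoldResult(
                fold_id=fold.fold_id,
                n_train=len(fold.train_indices),
                n_test=len(fold.test_indices),
                acc_paleo=acc_p,
                acc_current=acc_c,
                acc_weighted=(
                    weighted_accuracy(acc_p, acc_c)
                    if np.isfinite(acc_p) and np.isfinite(acc_c)
                    else np.nan
                ),
            )
        )
        if keep_traces:
            traces.append(trace)
    acc_p, acc_c = _accuracy_by_source(pooled_pp, data.labels, data.source)
    acc_overall = float(((pooled_pp >= 0.5).astype(int) == data.labels).mean())
    if np.isfinite(acc_p) and np.isfinite(acc_c):
        acc_w = weighted_accuracy(acc_p, acc_c)
    else:
        acc_w = acc_p if np.isfinite(acc_p) else acc_c
    paleo_mask = data.source == "paleo"
    calib_mask = paleo_mask if paleo_mask.any() else np.ones(len(pooled_pp), bool)
    threshold, retained = calibrate_threshold(
        pooled_pp[calib_mask], data.labels[calib_mask], target_accuracy
    )
    return EvaluationReport(
        config=config,
        folds=fold_results,
        acc_paleo=acc_p,
        acc_current=acc_c,
        acc_weighted=acc_w,
        acc_overall=acc_overall,
        pp_threshold=threshold,
        fraction_retained=retained,
        traces=traces,
    )
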