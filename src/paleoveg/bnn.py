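"""The Bayesian neural network: architecture, forward pass, priors.

The classifier maps, for each instance, the biotic distance tensor and
the abiotic predictors to probabilities of the two vegetation classes
(fixed order: ``closed``, ``open``):

1. a sparse layer with two shared scalar weights combines each
   (spatial, temporal) distance pair into one node per taxon and stage,
   ``h1[i, j] = swish(w_s * ds[i, j] + w_t * dt[i, j])``;
2. a per-taxon contraction over stages with a taxon-by-stage weight
   matrix yields one "proximity" node per taxon,
   ``h2[i] = swish(sum_j h1[i, j] * W2[i, j])``;
3. optional pooling collapses the taxon nodes to one faunal and one
   floral feature (max- or sum-pooling), or leaves them untouched;
4. fully connected hidden layers (no bias terms, swish activations)
   followed by a softmax output layer give the class probabilities.

All weights carry independent standard-normal priors; the likelihood is
categorical. Weights live in a single flat vector (``WeightSample``)
whose layout is fixed by the architecture, which keeps the MCMC sampler
a plain random-walk over one array.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .features import ModelData

__all__ = [
    "BNNConfig",
    "WeightSample",
    "swish",
    "layer1_forward",
    "layer2_forward",
    "pool_taxa",
    "dense_forward",
    "output_probs",
    "forward",
    "log_prior",
    "log_likelihood",
]

LIKELIHOOD_EPS = 1e-12
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class BNNConfig:
    """Architecture and input-block switches for one model."""

    n_taxa: int
    n_stages: int
    n_abiotic: int = 8
    hidden_layout: tuple[int, ...] = (8,)
    pooling: str = "none"  # 'none' | 'max' | 'sum'
    use_biotic: bool = True
    use_abiotic: bool = True
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.use_biotic or self.use_abiotic):
            raise ValueError("at least one of use_biotic/use_abiotic must be set")
        if not self.hidden_layout:
            raise ValueError("hidden_layout must be nonempty")
        if self.pooling not in ("none", "max", "sum"):
            raise ValueError(f"unknown pooling strategy {self.pooling!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        object.__setattr__(self, "hidden_layout", tuple(self.hidden_layout))

    @property
    def biotic_dim(self) -> int:
        if not self.use_biotic:
            return 0
        return 2 if self.pooling in ("max", "sum") else self.n_taxa

    @property
    def input_dim(self) -> int:
        return self.biotic_dim + (self.n_abiotic if self.use_abiotic else 0)

    @property
    def dense_shapes(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_layout]
        shapes = [(a, b) for a, b in zip(dims, dims[1:])]
        shapes.append((dims[-1], self.n_classes))
        return shapes

    @property
    def n_weights(self) -> int:
        n = 0
        if self.use_biotic:
            n += 2 + self.n_taxa * self.n_stages
        n += sum(a * b for a, b in self.dense_shapes)
        return n

    def hash(self) -> str:
        payload = json.dumps(
            {
                "n_taxa": self.n_taxa,
                "n_stages": self.n_stages,
                "n_abiotic": self.n_abiotic,
                "hidden_layout": list(self.hidden_layout),
                "pooling": self.pooling,
                "use_biotic": self.use_biotic,
                "use_abiotic": self.use_abiotic,
                "n_classes": self.n_classes,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class WeightSample:
    """One full set of network weights, stored as a flat vector.

    Views (``w_s``, ``w_t``, ``W2``, ``W_hidden``, ``W_out``) share
    memory with the vector, so the sampler can perturb the vector
    directly.
    """

    def __init__(self, config: BNNConfig, vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (config.n_weights,):
            raise ValueError(
                f"expected {config.n_weights} weights, got {vector.shape}"
            )
        if not np.all(np.isfinite(vector)):
            raise ValueError("weights must be finite")
        self.config = config
        self.vector = vector

    @property
    def w_s(self) -> float:
        return float(self.vector[0]) if self.config.use_biotic else 0.0

    @property
    def w_t(self) -> float:
        return float(self.vector[1]) if self.config.use_biotic else 0.0

    @property
    def W2(self) -> np.ndarray | None:
        if not self.config.use_biotic:
            return None
        size = self.config.n_taxa * self.config.n_stages
        return self.vector[2 : 2 + size].reshape(
            self.config.n_taxa, self.config.n_stages
        )

    def _dense_blocks(self) -> list[np.ndarray]:
        offset = 2 + self.config.n_taxa * self.config.n_stages if self.config.use_biotic else 0
        blocks = []
        for a, b in self.config.dense_shapes:
            blocks.append(self.vector[offset : offset + a * b].reshape(a, b))
            offset += a * b
        return blocks

    @property
    def W_hidden(self) -> list[np.ndarray]:
        return self._dense_blocks()[:-1]

    @property
    def W_out(self) -> np.ndarray:
        return self._dense_blocks()[-1]

    def copy(self) -> "WeightSample":
        return WeightSample(self.config, self.vector.copy())


def swish(x):
    """The swish activation, x * sigmoid(x)."""
    x = np.asarray(x, dtype=float)
    out = x * expit(x)
    return out if out.ndim else float(out)


def layer1_forward(delta_s, delta_t, w_s: float, w_t: float) -> np.ndarray:
    """Shared-weight combination of each (spatial, temporal) pair.

    One node per (taxon, stage); the two scalar weights are shared
    across all taxa and stages.
    """
    delta_s = np.asarray(delta_s, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    if delta_s.shape != delta_t.shape:
        raise ValueError("delta_s and delta_t shapes differ")
    return swish(w_s * delta_s + w_t * delta_t)


def layer2_forward(h1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Per-taxon contraction over stages: one proximity node per taxon."""
    h1 = np.asarray(h1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if h1.shape[-2:] != W2.shape:
        raise ValueError(
            f"h1 trailing shape {h1.shape[-2:]} does not match W2 {W2.shape}"
        )
    return swish(np.einsum("...ij,ij->...i", h1, W2))


def pool_taxa(h2: np.ndarray, groups: list[str], strategy: str) -> np.ndarray:
    """Collapse taxon nodes to one faunal + one floral feature, or not.

    ``none`` is the identity; ``max``/``sum`` reduce over the mammal and
    plant taxa separately, in that output order.
    """
    if strategy == "none":
        return np.asarray(h2, dtype=float)
    if strategy not in ("max", "sum"):
        raise ValueError(f"unknown pooling strategy {strategy!r}")
    unknown = set(groups) - {"mammal", "plant"}
    if unknown:
        raise ValueError(f"unknown taxon groups: {sorted(unknown)}")
    h2 = np.asarray(h2, dtype=float)
    groups_arr = np.asarray(groups)
    cols = []
    for grp in ("mammal", "plant"):
        mask = groups_arr == grp
        if not mask.any():
            cols.append(np.zeros(h2.shape[:-1]))
            continue
        block = h2[..., mask]
        cols.append(block.max(axis=-1) if strategy == "max" else block.sum(axis=-1))
    return np.stack(cols, axis=-1)


def dense_forward(x: np.ndarray, W_hidden: list[np.ndarray]) -> np.ndarray:
    """Bias-free fully connected layers with swish after each."""
    out = np.asarray(x, dtype=float)
    for W in W_hidden:
        if out.shape[-1] != W.shape[0]:
            raise ValueError(
                f"input width {out.shape[-1]} does not match weight {W.shape}"
            )
        out = swish(out @ W)
    return out


def output_probs(h_last: np.ndarray, W_out: np.ndarray) -> np.ndarray:
    """Softmax output layer, stabilized by max-subtraction."""
    logits = np.asarray(h_last, dtype=float) @ np.asarray(W_out, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    logits = logits - logits.max(axis=-1, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=-1, keepdims=True)


def forward(weights: WeightSample, data: ModelData) -> np.ndarray:
    """Full forward pass: per-instance class probabilities [N, n_classes]."""
    cfg = weights.config
    parts = []
    if cfg.use_biotic:
        if data.tensor.n_taxa != cfg.n_taxa or data.tensor.n_stages != cfg.n_stages:
            raise ValueError("distance tensor shape does not match the config")
        h1 = layer1_forward(
            data.tensor.delta_s, data.tensor.delta_t, weights.w_s, weights.w_t
        )
        h2 = layer2_forward(h1, weights.W2)
        parts.append(pool_taxa(h2, data.tensor.groups, cfg.pooling))
    if cfg.use_abiotic:
        if data.abiotic.values.shape[1] != cfg.n_abiotic:
            raise ValueError("abiotic block width does not match the config")
        parts.append(data.abiotic.values)
    x = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=-1)
    h = dense_forward(x, weights.W_hidden)
    return output_probs(h, weights.W_out)


def log_prior(weights: WeightSample) -> float:
    """Sum of independent standard-normal log-densities over all weights."""
    v = weights.vector
    return float(-v.size * _LOG_SQRT_2PI - 0.5 * np.dot(v, v))


def log_likelihood(y: np.ndarray, labels: np.ndarray, eps: float = LIKELIHOOD_EPS) -> float:
    """Categorical log-likelihood of integer labels under probabilities y."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if y.ndim != 2 or len(labels) != y.shape[0]:
        raise ValueError("y must be [N, n_classes] with one label per row")
    p = y[np.arange(len(labels)), labels]
    if np.any(p < eps):
        warnings.warn("zero-probability true labels floored at eps")
        p = np.maximum(p, eps)
    return float(np.log(p).sum())
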