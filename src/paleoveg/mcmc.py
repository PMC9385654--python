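"""Metropolis-Hastings sampling of the network weights.

All weights are updated with a symmetric Gaussian random-walk proposal
applied to a random subset of the weight vector each iteration (default
5% of the weights, proposal sd 0.1), accepted with probability
``min(1, exp(delta log posterior))``. The posterior combines the
categorical likelihood with independent standard-normal priors on every
weight. Weights are initialized from ``Normal(0, init_sd)``. Chains are
thinned on the fly (default: keep one sample every 200 iterations) and
the first fraction of iterations (default 10%) is flagged as burn-in
but retained in the trace. Everything is driven by one seeded RNG per
chain, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bnn import BNNConfig, WeightSample, forward, log_likelihood, log_prior
from .features import ModelData

__all__ = [
    "MCMCSettings",
    "PosteriorTrace",
    "init_weights",
    "log_posterior",
    "mh_step",
    "run_chain",
    "resume_chain",
    "save_trace",
    "load_trace",
]


@dataclass(frozen=True)
class MCMCSettings:
    n_iterations: int = 200_000
    sample_every: int = 200
    burnin_fraction: float = 0.1
    proposal_sd: float = 0.1
    update_fraction: float = 0.05
    init_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= self.sample_every:
            raise ValueError("n_iterations must exceed sample_every")
        if not 0 < self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in (0, 1)")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")
        if not 0 < self.update_fraction <= 1:
            raise ValueError("update_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "sample_every": self.sample_every,
            "burnin_fraction": self.burnin_fraction,
            "proposal_sd": self.proposal_sd,
            "update_fraction": self.update_fraction,
            "init_sd": self.init_sd,
            "seed": self.seed,
        }


@dataclass
class PosteriorTrace:
    """Thinned weight samples from one chain (burn-in retained, flagged)."""

    samples: np.ndarray  # [n_samples, n_weights]
    log_posteriors: np.ndarray  # [n_samples]
    iterations: np.ndarray  # [n_samples] global iteration index
    post_resume: np.ndarray  # [n_samples] bool, True for resumed segments
    acceptance_rate: float
    settings: MCMCSettings
    config: BNNConfig
    final_vector: np.ndarray
    final_log_posterior: float
    burnin_cutoff: int  # iterations <= cutoff are burn-in
    n_resumes: int = 0

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def is_burnin(self) -> np.ndarray:
        return self.iterations <= self.burnin_cutoff

    @property
    def post_burnin(self) -> np.ndarray:
        """Weight vectors after burn-in, [n_kept, n_weights]."""
        return self.samples[~self.is_burnin]

    def weight_samples(self, post_burnin_only: bool = True) -> list[WeightSample]:
        block = self.post_burnin if post_burnin_only else self.samples
        return [WeightSample(self.config, row.copy()) for row in block]


def init_weights(
    config: BNNConfig, seed: int | np.random.Generator = 0, init_sd: float = 0.1
) -> WeightSample:
    """Draw every weight from Normal(0, init_sd); seeded and reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return WeightSample(config, rng.normal(0.0, init_sd, config.n_weights))


def log_posterior(weights: WeightSample, data: ModelData | None) -> float:
    """Log prior plus categorical log likelihood (prior only if no data)."""
    lp = log_prior(weights)
    if data is not None and data.n_instances > 0:
        if data.labels is None:
            raise ValueError("training data must carry labels")
        lp += log_likelihood(forward(weights, data), data.labels)
    return lp


def _raw_log_posterior(
    vector: np.ndarray, config: BNNConfig, data: ModelData | None
) -> float:
    try:
        return log_posterior(WeightSample(config, vector), data)
    except (ValueError, FloatingPointError):
        return -np.inf


def mh_step(
    current: WeightSample,
    data: ModelData | None,
    settings: MCMCSettings,
    rng: np.random.Generator,
    current_log_post: float | None = None,
) -> tuple[WeightSample, bool, float]:
    """One Metropolis-Hastings update of a random weight subset.

    The proposal is a symmetric Gaussian random walk, so the acceptance
    ratio reduces to the posterior ratio. Non-finite proposal
    posteriors are auto-rejected.
    """
    cfg = current.config
    if current_log_post is None:
        current_log_post = _raw_log_posterior(current.vector, cfg, data)
    k = current.vector.size
    n_update = max(1, int(round(settings.update_fraction * k)))
    idx = rng.choice(k, size=n_update, replace=False)
    proposal = current.vector.copy()
    proposal[idx] += rng.normal(0.0, settings.proposal_sd, n_update)
    prop_lp = _raw_log_posterior(proposal, cfg, data)
    log_u = np.log(rng.uniform())
    if np.isfinite(prop_lp) and log_u < prop_lp - current_log_post:
        return WeightSample(cfg, proposal), True, prop_lp
    return current, False, current_log_post


def _run(
    data: ModelData | None,
    config: BNNConfig,
    settings: MCMCSettings,
    rng: np.random.Generator,
    start_vector: np.ndarray,
    n_iterations: int,
    iteration_offset: int,
    log_csv=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, float]:
    k = start_vector.size
    n_samples = n_iterations // settings.sample_every
    samples = np.empty((n_samples, k))
    lps = np.empty(n_samples)
    iters = np.empty(n_samples, dtype=int)
    vec = start_vector.copy()
    lp = _raw_log_posterior(vec, config, data)
    n_accept = 0
    n_update = max(1, int(round(settings.update_fraction * k)))
    pos = 0
    log_rows = []
    for it in range(1, n_iterations + 1):
        idx = rng.choice(k, size=n_update, replace=False)
        proposal = vec.copy()
        proposal[idx] += rng.normal(0.0, settings.proposal_sd, n_update)
        prop_lp = _raw_log_posterior(proposal, config, data)
        log_u = np.log(rng.uniform())
        accepted = bool(np.isfinite(prop_lp) and log_u < prop_lp - lp)
        if accepted:
            vec, lp = proposal, prop_lp
            n_accept += 1
        if it % settings.sample_every == 0:
            samples[pos] = vec
            lps[pos] = lp
            iters[pos] = iteration_offset + it
            pos += 1
            if log_csv is not None:
                log_rows.append((iteration_offset + it, lp, int(accepted)))
    if log_csv is not None:
        import pandas as pd

        pd.DataFrame(
            log_rows, columns=["iteration", "log_posterior", "accepted"]
        ).to_csv(log_csv, index=False)
    acc_rate = n_accept / n_iterations if n_iterations else 0.0
    return samples, lps, iters, acc_rate, vec, lp


def run_chain(
    data: ModelData | None,
    config: BNNConfig,
    settings: MCMCSettings,
    log_csv=None,
) -> PosteriorTrace:
    """Run one MCMC chain; the trace holds ``n_iterations // sample_every``
    thinned samples with the burn-in portion flagged.

    With ``data=None`` (or an empty dataset) the likelihood is constant
    and the chain samples the standard-normal prior — the sampler's
    built-in correctness check.
    """
    rng = np.random.default_rng(settings.seed)
    start = rng.normal(0.0, settings.init_sd, config.n_weights)
    samples, lps, iters, acc, final_vec, final_lp = _run(
        data, config, settings, rng, start, settings.n_iterations, 0, log_csv
    )
    if acc == 0.0:
        warnings.warn(
            "no proposals were accepted; consider lowering proposal_sd "
            "or update_fraction"
        )
    return PosteriorTrace(
        samples=samples,
        log_posteriors=lps,
        iterations=iters,
        post_resume=np.zeros(len(samples), dtype=bool),
        acceptance_rate=acc,
        settings=settings,
        config=config,
        final_vector=final_vec,
        final_log_posterior=final_lp,
        burnin_cutoff=int(settings.burnin_fraction * settings.n_iterations),
        n_resumes=0,
    )


def resume_chain(
    trace: PosteriorTrace,
    data: ModelData | None,
    extra_iterations: int,
    config: BNNConfig | None = None,
) -> PosteriorTrace:
    """Continue a chain from its last state for ``extra_iterations`` more.

    Appended samples are flagged ``post_resume`` and are never treated
    as burn-in. A config mismatch is refused.
    """
    if len(trace) < 1:
        raise ValueError("cannot resume an empty trace")
    if config is not None and config.hash() != trace.config.hash():
        raise ValueError("architecture mismatch between trace and config")
    if extra_iterations <= 0:
        return trace
    rng = np.random.default_rng([trace.settings.seed, trace.n_resumes + 1])
    offset = int(trace.iterations[-1])
    samples, lps, iters, acc, final_vec, final_lp = _run(
        data,
        trace.config,
        trace.settings,
        rng,
        trace.final_vector,
        extra_iterations,
        offset,
    )
    n_new = len(samples)
    # overall acceptance: weighted by iteration counts of each segment
    prev_iters = int(trace.iterations[-1])
    combined_acc = (
        trace.acceptance_rate * prev_iters + acc * extra_iterations
    ) / (prev_iters + extra_iterations)
    return PosteriorTrace(
        samples=np.vstack([trace.samples, samples]),
        log_posteriors=np.concatenate([trace.log_posteriors, lps]),
        iterations=np.concatenate([trace.iterations, iters]),
        post_resume=np.concatenate(
            [trace.post_resume, np.ones(n_new, dtype=bool)]
        ),
        acceptance_rate=combined_acc,
        settings=trace.settings,
        config=trace.config,
        final_vector=final_vec,
        final_log_posterior=final_lp,
        burnin_cutoff=trace.burnin_cutoff,
        n_resumes=trace.n_resumes + 1,
    )


def save_trace(trace: PosteriorTrace, path) -> None:
    """Persist a trace as ``<path>.npz`` plus a JSON sidecar ``<path>.json``."""
    path = str(path)
    np.savez_compressed(
        path + ".npz",
        samples=trace.samples,
        log_posteriors=trace.log_posteriors,
        iterations=trace.iterations,
        post_resume=trace.post_resume,
        final_vector=trace.final_vector,
    )
    sidecar = {
        "acceptance_rate": trace.acceptance_rate,
        "final_log_posterior": trace.final_log_posterior,
        "burnin_cutoff": trace.burnin_cutoff,
        "n_resumes": trace.n_resumes,
        "settings": trace.settings.to_dict(),
        "config": {
            "n_taxa": trace.config.n_taxa,
            "n_stages": trace.config.n_stages,
            "n_abiotic": trace.config.n_abiotic,
            "hidden_layout": list(trace.config.hidden_layout),
            "pooling": trace.config.pooling,
            "use_biotic": trace.config.use_biotic,
            "use_abiotic": trace.config.use_abiotic,
            "n_classes": trace.config.n_classes,
            "seed": trace.config.seed,
        },
        "config_hash": trace.config.hash(),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_trace(path, expected_config: BNNConfig | None = None) -> PosteriorTrace:
    path = str(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    cfg_dict = dict(sidecar["config"])
    cfg_dict["hidden_layout"] = tuple(cfg_dict["hidden_layout"])
    config = BNNConfig(**cfg_dict)
    if expected_config is not None and expected_config.hash() != config.hash():
        raise ValueError("trace was produced by a different architecture")
    arrays = np.load(path + ".npz")
    return PosteriorTrace(
        samples=arrays["samples"],
        log_posteriors=arrays["log_posteriors"],
        iterations=arrays["iterations"],
        post_resume=arrays["post_resume"].astype(bool),
        acceptance_rate=float(sidecar["acceptance_rate"]),
        settings=MCMCSettings(**sidecar["settings"]),
        config=config,
        final_vector=arrays["final_vector"],
        final_log_posterior=float(sidecar["final_log_posterior"]),
        burnin_cutoff=int(sidecar["burnin_cutoff"]),
        n_resumes=int(sidecar["n_resumes"]),
    )
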