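"""Shared fixtures: the stage table and a small synthetic world.

The session-scoped fixtures build one strong-signal synthetic dataset
and train a single chain on it, shared by every test that needs a
realistic trained model so the suite trains as few chains as possible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import paleoveg as pv

#: scenario conditions shared by tests and worked examples
STRONG_SEED = 11
N_PALEO = 100
N_CURRENT = 100


@pytest.fixture(scope="session")
def stage_table() -> pv.StageTable:
    return pv.load_stage_table(30.0)


def build_training_data(scenario: pv.SyntheticScenario, table, n_paleo=N_PALEO,
                        n_current=N_CURRENT) -> pv.ModelData:
    """Full pipeline from scenario to a scaled, labeled ModelData."""
    truth, occ, points, stacks, curves = pv.scenario_inputs(
        scenario, n_paleo=n_paleo, n_current=n_current
    )
    occ = pv.deduplicate(pv.assign_stages(occ, table))
    return pv.prepare_datasets({"train": points}, occ, table, stacks, curves)[
        "train"
    ]


@pytest.fixture(scope="session")
def strong_scenario() -> pv.SyntheticScenario:
    return pv.SyntheticScenario(seed=STRONG_SEED)


@pytest.fixture(scope="session")
def strong_data(strong_scenario, stage_table) -> pv.ModelData:
    return build_training_data(strong_scenario, stage_table)


@pytest.fixture(scope="session")
def strong_config(strong_data) -> pv.BNNConfig:
    return pv.BNNConfig(
        n_taxa=strong_data.tensor.n_taxa,
        n_stages=strong_data.tensor.n_stages,
    )


@pytest.fixture(scope="session")
def strong_trace(strong_data, strong_config) -> pv.PosteriorTrace:
    settings = pv.MCMCSettings(n_iterations=50_000, sample_every=200, seed=5)
    return pv.run_chain(strong_data, strong_config, settings)


def make_trace(config, vectors, settings=None):
    """A hand-built trace whose post-burn-in samples are exactly ``vectors``."""
    vectors = np.asarray(vectors, dtype=float)
    settings = settings or pv.MCMCSettings(
        n_iterations=1000, sample_every=100, seed=0
    )
    n = vectors.shape[0]
    return pv.PosteriorTrace(
        samples=vectors,
        log_posteriors=np.zeros(n),
        iterations=np.arange(1, n + 1) * 10_000,  # all past burn-in
        post_resume=np.zeros(n, dtype=bool),
        acceptance_rate=0.5,
        settings=settings,
        config=config,
        final_vector=vectors[-1],
        final_log_posterior=0.0,
        burnin_cutoff=100,
    )


@pytest.fixture(scope="session")
def tiny_trace() -> tuple[pv.PosteriorTrace, pv.ModelData]:
    """A very small trained model on trivially structured data.

    One abiotic column fully determines the label; everything else is
    noise. Cheap enough for structural tests of prediction plumbing.
    """
    rng = np.random.default_rng(42)
    n = 60
    signal = rng.uniform(0, 1, n)
    labels = (signal > 0.5).astype(int)
    abiotic = rng.uniform(0, 1, (n, 8))
    abiotic[:, 0] = signal
    abiotic[:, 7] = 1.0  # constant column doubles as a bias carrier
    tensor = pv.BioticDistanceTensor(
        delta_s=rng.uniform(0, 1, (n, 3, 4)),
        delta_t=rng.uniform(0, 1, (n, 3, 4)),
        taxa=["taxon_a", "taxon_b", "taxon_c"],
        groups=["mammal", "mammal", "plant"],
    )
    data = pv.ModelData(
        tensor=tensor,
        abiotic=pv.FeatureMatrix(
            values=abiotic, feature_names=list(pv.ABIOTIC_FEATURE_NAMES)
        ),
        labels=labels,
        source=np.where(rng.uniform(size=n) < 0.5, "paleo", "current"),
    )
    config = pv.BNNConfig(n_taxa=3, n_stages=4, hidden_layout=(6,))
    settings = pv.MCMCSettings(n_iterations=8_000, sample_every=100, seed=3)
    return pv.run_chain(data, config, settings), data
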