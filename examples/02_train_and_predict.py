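"""Train a model by MCMC and predict vegetation with uncertainty.

Builds features (per-taxon nearest-occurrence distances per geological
stage plus 8 abiotic predictors, jointly scaled to [0, 1]), samples the
network weights with Metropolis-Hastings, and reports posterior class
probabilities for held-back points.
"""

import numpy as np

import paleoveg as pv

table = pv.load_stage_table(30.0)
scenario = pv.SyntheticScenario(seed=42)
truth, occurrences, points, stacks, curves = pv.scenario_inputs(
    scenario, n_paleo=100, n_current=100
)
occurrences = pv.deduplicate(pv.assign_stages(occurrences, table))

# hold back 40 points to show out-of-sample prediction
train_points, test_points = points.iloc[:-40], points.iloc[-40:]
datasets = pv.prepare_datasets(
    {"train": train_points, "test": test_points},
    occurrences, table, stacks, curves,
)

config = pv.BNNConfig(
    n_taxa=datasets["train"].tensor.n_taxa,
    n_stages=len(table),
    hidden_layout=(8,),  # one hidden layer, eight nodes
)
settings = pv.MCMCSettings(n_iterations=20_000, sample_every=200, seed=1)
trace = pv.run_chain(datasets["train"], config, settings)
print(f"sampled {len(trace)} weight vectors, "
      f"acceptance rate {trace.acceptance_rate:.2f}")

result = pv.posterior_probs(trace, datasets["test"])
accuracy = ((result.pp_open >= 0.5).astype(int) == datasets["test"].labels).mean()
print(f"held-out accuracy: {accuracy:.2f} on {len(test_points)} points")

# posterior probabilities quantify confidence per point: values near 0
# or 1 are confident closed/open calls, values near 0.5 are uncertain
print("first five held-out points (pp_open, truth):")
for pp, label in zip(result.pp_open[:5], datasets["test"].labels[:5]):
    print(f"  {pp:.3f}  {'open' if label == 1 else 'closed'}")
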