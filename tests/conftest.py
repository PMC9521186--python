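"""Shared fixtures: one moderately sized simulated study, built once.

The session bundle uses the generator's default study conditions (organ
mix, regimen mixtures, outcome hazards, 5% planted negatives per
eligibility rule) at n=600 so every downstream stage has realistic input
without re-simulating per test.
"""

from __future__ import annotations

import pytest

import txclaims as tx

SESSION_SEED = 11
SESSION_N = 600


@pytest.fixture(scope="session")
def schema():
    return tx.CDMSchema.load()


@pytest.fixture(scope="session")
def dictionary():
    return tx.default_dictionary()


@pytest.fixture(scope="session")
def sim(schema):
    cfg = tx.SimulationConfig(n_persons=SESSION_N, seed=SESSION_SEED)
    bundles, truth = tx.generate_regional_claims(cfg)
    datasets = [tx.build_analytical_dataset(b, schema)
                for b in bundles.values()]
    pooled = tx.pool_regions(datasets)
    cohort, attrition = tx.build_cohort(pooled)
    return {"cfg": cfg, "bundles": bundles, "truth": truth,
            "datasets": datasets, "pooled": pooled, "cohort": cohort,
            "attrition": attrition}


@pytest.fixture(scope="session")
def classifications(sim, dictionary):
    return tx.classify_cohort(sim["cohort"], sim["pooled"].dispensings,
                              dictionary)
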