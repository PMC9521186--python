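"""Shared driver plumbing: build the synthetic study once per invocation.

Every numbered script regenerates the study deterministically from the
same (seed, n) pair rather than parsing a previous script's output files;
the generator is fast enough that reproducibility beats caching.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import txclaims as tx

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=600,
                        help="number of synthetic transplant recipients")
    return parser.parse_args()


def build_study(seed: int, n: int) -> dict:
    cfg = tx.SimulationConfig(n_persons=n, seed=seed)
    schema = tx.CDMSchema.load()
    bundles, truth = tx.generate_regional_claims(cfg)
    reports = {r: tx.validate_bundle(b, schema) for r, b in bundles.items()}
    datasets = [tx.build_analytical_dataset(b, schema)
                for b in bundles.values()]
    pooled = tx.pool_regions(datasets)
    cohort, attrition = tx.build_cohort(pooled)
    return {"cfg": cfg, "schema": schema, "bundles": bundles, "truth": truth,
            "validation": reports, "datasets": datasets, "pooled": pooled,
            "cohort": cohort, "attrition": attrition}


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
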