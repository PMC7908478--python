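#!/usr/bin/env python
"""Generate the synthetic study: a tract demographic table with known
5-factor oblique structure, its variable catalog, and a prevalence outcome
driven by the factors plus state/county random intercepts and confounders.

Writes tracts.csv, catalog.csv, outcome.csv and truth.json under
scratch/study/ (regenerable intermediates; summary tables land in
results/ in later steps).
"""

import json
from pathlib import Path

from neighborfactor import generate_outcome, generate_tract_table, generate_truth
from neighborfactor.synth import truth_to_dict

K, P_CORE = 5, 39
N_TRACTS, N_STATES, COUNTIES = 5000, 20, 4
SEED = 42

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "study"     # large intermediate tables


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(K, P_CORE, seed=SEED)
    data = generate_tract_table(truth, N_TRACTS, N_STATES, COUNTIES, seed=SEED + 1)
    outcome = generate_outcome(truth, data.factors, data.geography, seed=SEED + 2)

    data.table.to_csv(OUT / "tracts.csv", index=False)
    data.catalog.to_csv(OUT / "catalog.csv", index=False)
    outcome.to_csv(OUT / "outcome.csv", index=False)
    (OUT / "truth.json").write_text(json.dumps(truth_to_dict(truth), indent=2))

    n_missing = int(data.table.drop(columns="GEOID").isna().to_numpy().sum())
    print(f"simulated {N_TRACTS} tracts x {data.table.shape[1] - 1} variables "
          f"({N_STATES} states, {COUNTIES} counties each)")
    print(f"planted artifacts: "
          f"{(data.catalog['role'] == 'complement').sum()} complements, "
          f"{(data.catalog['role'] == 'low_cv').sum()} low-CV columns, "
          f"{(data.catalog['role'] == 'stratum').sum()} stratum subgroups; "
          f"{n_missing} missing cells")
    print(f"prevalence range: {outcome['prevalence'].min():.4f}"
          f"-{outcome['prevalence'].max():.4f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
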