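#!/usr/bin/env python
"""Reduce the simulated tract table to the analysis variable set and
Gaussianize it: drop declared-redundant complements, filter coefficient of
variation < 0.06, combine strata subgroups, fit per-column symmetrizing
transforms, standardize, and fill missing cells by weighted 10-NN.

Reads scratch/study/, writes selected.csv, transformed.csv and
transforms.json there and selection_log.csv under results/.
"""

from pathlib import Path

import pandas as pd

from neighborfactor import apply_transforms, fit_transforms, knn_impute, select_features
from neighborfactor.pipeline import read_tract_table
from neighborfactor.transform import specs_to_json

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "scratch" / "study"   # large intermediate tables
RESULTS = ROOT / "results"           # small summary tables


def main() -> None:
    table = read_tract_table(STUDY / "tracts.csv")
    catalog = pd.read_csv(STUDY / "catalog.csv").fillna("")

    selected, log = select_features(table, catalog)
    selected.to_csv(STUDY / "selected.csv", index=False)
    RESULTS.mkdir(parents=True, exist_ok=True)
    log.to_csv(RESULTS / "selection_log.csv", index=False)
    by_action = log["action"].value_counts().to_dict()
    print(f"selection: {table.shape[1] - 1} -> {selected.shape[1] - 1} variables "
          f"({by_action})")

    specs = fit_transforms(selected)
    families = pd.Series({c: s.family for c, s in specs.items()})
    print("transform families chosen:", families.value_counts().to_dict())

    transformed = apply_transforms(selected, specs)
    cols = [c for c in transformed.columns if c != "GEOID"]
    n_missing = int(transformed[cols].isna().to_numpy().sum())
    transformed[cols] = knn_impute(transformed[cols], k=10)
    print(f"imputed {n_missing} missing cells "
          f"({100 * n_missing / (len(transformed) * len(cols)):.3f}% of the table)")

    transformed.to_csv(STUDY / "transformed.csv", index=False)
    (STUDY / "transforms.json").write_text(specs_to_json(specs))
    print(f"wrote {STUDY}/transformed.csv")


if __name__ == "__main__":
    main()
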