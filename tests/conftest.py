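"""Shared fixtures: one default synthetic study, built once per session.

The default study conditions — 5 factors, 39 core variables, 5000 tracts in
20 states with 4 counties each, 0.16% missingness — exercise every pipeline
stage with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from neighborfactor import (
    apply_transforms,
    compute_scores,
    fit_efa,
    fit_transforms,
    generate_outcome,
    generate_tract_table,
    generate_truth,
    knn_impute,
    select_features,
)
from neighborfactor.efa import align_factors, congruence_matrix

K, P_CORE = 5, 39
N_TRACTS, N_STATES, COUNTIES = 5000, 20, 4
SEED_TRUTH, SEED_TABLE, SEED_OUTCOME = 7, 8, 9

CORE_NAMES = [f"core_{i + 1:02d}" for i in range(P_CORE)]


@dataclass
class Study:
    truth: object
    table: pd.DataFrame
    catalog: pd.DataFrame
    geography: pd.DataFrame
    factors: np.ndarray
    outcome: pd.DataFrame
    selected: pd.DataFrame
    selection_log: pd.DataFrame
    specs: dict
    imputed: pd.DataFrame          # transformed + imputed, with GEOID
    model: object
    scores: pd.DataFrame
    aligned_loadings: np.ndarray   # model loadings (core rows) matched to truth
    perm: np.ndarray               # model factor j corresponds to truth factor perm^-1 order
    signs: np.ndarray
    congruence: np.ndarray         # per-truth-factor |Tucker congruence|


@pytest.fixture(scope="session")
def study() -> Study:
    truth = generate_truth(K, P_CORE, seed=SEED_TRUTH)
    data = generate_tract_table(truth, N_TRACTS, N_STATES, COUNTIES, seed=SEED_TABLE)
    outcome = generate_outcome(truth, data.factors, data.geography, seed=SEED_OUTCOME)

    selected, sel_log = select_features(data.table, data.catalog)
    specs = fit_transforms(selected)
    transformed = apply_transforms(selected, specs)
    cols = [c for c in transformed.columns if c != "GEOID"]
    imputed = transformed.copy()
    imputed[cols] = knn_impute(transformed[cols], k=10)

    model = fit_efa(imputed, K)
    scores = compute_scores(model, imputed)

    idx = [model.variables.index(n) for n in CORE_NAMES]
    aligned, perm, signs = align_factors(truth.loadings, model.loadings[idx])
    cong = np.abs(np.diag(congruence_matrix(truth.loadings, aligned)))

    return Study(
        truth=truth,
        table=data.table,
        catalog=data.catalog,
        geography=data.geography,
        factors=data.factors,
        outcome=outcome,
        selected=selected,
        selection_log=sel_log,
        specs=specs,
        imputed=imputed,
        model=model,
        scores=scores,
        aligned_loadings=aligned,
        perm=perm,
        signs=signs,
        congruence=cong,
    )


@pytest.fixture(scope="session")
def aligned_scores(study) -> np.ndarray:
    """Score matrix with columns matched (and sign-flipped) to truth factors."""
    S = study.scores[[c for c in study.scores.columns if c != "GEOID"]].to_numpy()
    return S[:, study.perm] * study.signs
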