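"""End-to-end pipeline orchestration, tabular I/O and configuration.

Ties the stages together: feature selection -> transform/impute -> factor
model -> scores -> association, writing every intermediate artifact plus a
manifest that fully determines reproduction (config, seed, row/column
counts per stage). Tract keys are always 11-character GEOID strings —
numeric parsing would corrupt the leading zero of low-numbered state codes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from neighborfactor import association, efa, selection, transform


@dataclass
class PipelineConfig:
    cv_threshold: float = 0.06
    knn_k: int = 10
    n_factors: int = 5
    n_boot: int = 2000
    seed: int = 0
    effect_thresholds: tuple[float, float, float] = (0.02, 0.15, 0.35)
    spline_min_tracts: int = 20
    confounders: tuple[str, ...] = ("age_conf", "sex_ratio", "minority_share", "poverty")
    run_bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.cv_threshold <= 0 or self.knn_k <= 0 or self.n_boot <= 0:
            raise ValueError("thresholds and counts must be positive")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_tract_table(path: str | Path) -> pd.DataFrame:
    """Read a tract CSV with a validated string GEOID key.

    GEOIDs are parsed as 11-character zero-padded strings, empty cells
    become missing values, and duplicate keys are rejected.
    """
    df = pd.read_csv(path, dtype={"GEOID": str})
    if "GEOID" not in df.columns:
        raise ValueError(f"{path}: no GEOID column")
    geoid = df["GEOID"].astype(str)
    bad = geoid[(geoid.str.len() != 11) | ~geoid.str.isdigit()]
    if len(bad):
        raise ValueError(
            f"{path}: malformed GEOID at row {bad.index[0]}: {bad.iloc[0]!r} "
            "(expected 11 digits)"
        )
    dup = geoid[geoid.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate GEOID {dup.iloc[0]!r}")
    for c in df.columns:
        if c in ("GEOID", "state", "county"):
            continue
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def read_outcome_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"GEOID": str, "state": str, "county": str})
    for col in ("GEOID", "state", "county", "prevalence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    prev = df["prevalence"].to_numpy(dtype=float)
    if ((prev < 0) | (prev > 1)).any():
        raise ValueError(f"{path}: prevalence outside [0, 1]")
    return df


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(
    config: PipelineConfig,
    tract_table_path: str | Path,
    catalog_path: str | Path,
    outcome_path: str | Path,
    out_dir: str | Path,
) -> dict:
    """Execute select -> transform/impute -> factor -> score -> associate.

    Writes every intermediate artifact into ``out_dir`` plus a
    ``manifest.json``; identical config + inputs + seed produce identical
    outputs. Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "stages": {},
    }

    def _stage(name: str, t0: float, **counts) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}

    t0 = time.time()
    tracts = read_tract_table(tract_table_path)
    catalog = pd.read_csv(catalog_path).fillna("")
    outcome = read_outcome_table(outcome_path)
    _stage("read", t0, n_tracts=len(tracts), n_columns=tracts.shape[1] - 1)

    t0 = time.time()
    selected, sel_log = selection.select_features(tracts, catalog, config.cv_threshold)
    _write_csv(selected, out / "selected.csv")
    _write_csv(sel_log, out / "selection_log.csv")
    _stage("select", t0, n_columns=selected.shape[1] - 1, n_removed=len(sel_log))

    t0 = time.time()
    specs = transform.fit_transforms(selected)
    transformed = transform.apply_transforms(selected, specs)
    data_cols = [c for c in transformed.columns if c != "GEOID"]
    imputed = transformed.copy()
    imputed[data_cols] = transform.knn_impute(transformed[data_cols], k=config.knn_k)
    (out / "transforms.json").write_text(transform.specs_to_json(specs))
    _write_csv(imputed, out / "transformed.csv")
    _stage(
        "transform",
        t0,
        n_columns=len(data_cols),
        n_imputed=int(transformed[data_cols].isna().to_numpy().sum()),
        n_missing_after=int(imputed[data_cols].isna().to_numpy().sum()),
    )

    t0 = time.time()
    model = efa.fit_efa(imputed, config.n_factors)
    loadings = pd.DataFrame(
        model.loadings,
        index=pd.Index(model.variables, name="variable"),
        columns=[f"factor_{j + 1}" for j in range(model.k)],
    )
    loadings.reset_index().to_csv(out / "loadings.csv", index=False)
    pd.DataFrame(model.factor_corr).to_csv(out / "phi.csv", index=False)
    (out / "fit.json").write_text(
        json.dumps(
            {
                "eigenvalues": model.eigenvalues.tolist(),
                "variance_explained": model.variance_explained.tolist(),
                "cumulative_variance": model.cumulative_variance,
                "rms_residual": model.rms_residual,
                "offdiag_fit": model.offdiag_fit,
                "kaiser_count": int(np.sum(model.eigenvalues >= 1.0)),
            },
            indent=2,
        )
    )
    scores = efa.compute_scores(model, imputed)
    _write_csv(scores, out / "scores.csv")
    _stage("factor", t0, k=model.k)

    if config.run_bootstrap:
        t0 = time.time()
        boot = efa.bootstrap_loading_se(
            imputed, config.n_factors, n_boot=config.n_boot, seed=config.seed
        )
        pd.DataFrame(
            boot.loading_se, index=loadings.index, columns=loadings.columns
        ).reset_index().to_csv(out / "bootstrap_se.csv", index=False)
        _stage("bootstrap", t0, n_boot=boot.n_boot, n_dropped=boot.n_dropped)

    t0 = time.time()
    confounders = [c for c in config.confounders if c in outcome.columns]
    splines = association.state_spline_r2(
        scores, outcome, min_tracts_per_state=config.spline_min_tracts
    )
    _write_csv(splines.table, out / "spline_summary.csv")
    decomp = association.decomposition_report(outcome, scores, confounders)
    _write_csv(decomp.table, out / "decomposition.csv")
    (out / "association_report.json").write_text(
        json.dumps(
            {
                "v_null": decomp.v_null,
                "confounders": decomp.confounders,
                "spline_medians": dict(
                    zip(splines.summary["factor"], splines.summary["median_r2"])
                ),
            },
            indent=2,
        )
    )
    _stage("associate", t0, n_states=int(splines.summary["n_states"].max()))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
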