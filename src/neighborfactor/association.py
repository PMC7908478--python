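"""Factor-outcome association: per-state smoothing splines and the
mixed-model variance decomposition.

Two complementary views of how each latent neighborhood factor relates to
the tract-level poor-mental-health prevalence:

* **Bivariate**: a cubic smoothing spline of prevalence on each factor
  score, fitted separately per state (regional differences), summarized by
  the median and IQR of R^2 across states.

* **Multivariable**: linear mixed models with random state and
  county-within-state intercepts. R^2 of a model is
  ``(V_null - V_model) / V_null`` where V is the total estimated variance
  (state + county + residual components) of the model versus the
  random-effects-only null. The unique variance of factor i is
  ``R^2_{a,i} - R^2_a`` (the increment over the confounders-only model) and
  its local effect size is Cohen's ``f^2 = (R^2_{a,i} - R^2_a) /
  (1 - R^2_{a,i})``, with the conventional small/medium/large thresholds
  0.02 / 0.15 / 0.35.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.interpolate import make_smoothing_spline

EFFECT_THRESHOLDS = {"small": 0.02, "medium": 0.15, "large": 0.35}

#: published variance decomposition this methodology produced on the full
#: national tract data (confounder set: age, sex, race, ethnicity, poverty).
#: ``r2`` columns are inputs; ``unique`` and ``f2`` are re-derivable from
#: them via unique_variance / cohens_f2.
PUBLISHED_DECOMPOSITION = pd.DataFrame(
    [
        ("Ma", "ACS only", 0.8376, None, None),
        ("Ma,1", "ACS + Affluence", 0.9037, 0.0661, 0.6861),
        ("Ma,2", "ACS + Singletons in Tract", 0.8376, 0.0, 0.0),
        ("Ma,3", "ACS + Seniors in Tract", 0.86, 0.0224, 0.1597),
        ("Ma,4", "ACS + African Americans in Tract", 0.8587, 0.0211, 0.149),
        ("Ma,5", "ACS + Hispanics or Latinos in Tract", 0.8768, 0.0392, 0.3177),
        ("Ma,1:5", "ACS + All Neighborhood Factors", 0.9177, 0.0801, 0.9728),
    ],
    columns=["notation", "model", "r2", "unique_variance", "f2"],
)


# ---------------------------------------------------------------------------
# elementary effect-size arithmetic


def r2_from_variances(v_null: float, v_model: float) -> float:
    """R^2 of a model against the null: (V_null - V_model) / V_null."""
    if v_null <= 0:
        raise ValueError("V_null must be positive")
    if v_model < 0:
        raise ValueError("V_model must be non-negative")
    return (v_null - v_model) / v_null


def unique_variance(r2_with: float, r2_without: float) -> float:
    """Unique variance explained by a covariate: R^2_with - R^2_without."""
    return r2_with - r2_without


def cohens_f2(r2_with: float, r2_without: float) -> float:
    """Cohen's local effect size f^2 = (R^2_with - R^2_without) / (1 - R^2_with)."""
    if r2_with >= 1:
        raise ValueError("r2_with must be < 1")
    return (r2_with - r2_without) / (1.0 - r2_with)


def classify_effect(f2: float) -> str:
    """Map f^2 to {none, small, medium, large} by the >= 0.02/0.15/0.35 rule."""
    if f2 < 0:
        raise ValueError("f2 must be non-negative")
    if f2 >= EFFECT_THRESHOLDS["large"]:
        return "large"
    if f2 >= EFFECT_THRESHOLDS["medium"]:
        return "medium"
    if f2 >= EFFECT_THRESHOLDS["small"]:
        return "small"
    return "none"


# ---------------------------------------------------------------------------
# per-state smoothing splines


@dataclass
class SplineSummary:
    """Per-state spline R^2 per factor with across-state summaries."""

    table: pd.DataFrame    # columns: factor, state, r2, n_tracts
    summary: pd.DataFrame  # columns: factor, median_r2, q25_r2, q75_r2, n_states
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["factor", "state", "reason"])
    )


def _spline_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of a GCV cubic smoothing spline of y on x.

    Duplicate abscissae are averaged (with multiplicity weights) before the
    fit, since the spline routine needs strictly increasing knots.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xu, inverse, counts = np.unique(xs, return_inverse=True, return_counts=True)
    yu = np.bincount(inverse, weights=ys) / counts
    spl = make_smoothing_spline(xu, yu, w=counts.astype(float))
    pred = spl(x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def state_spline_r2(
    scores: pd.DataFrame,
    outcome: pd.DataFrame,
    min_tracts_per_state: int = 20,
) -> SplineSummary:
    """Fit per-state cubic smoothing splines of prevalence on each factor
    score and summarize R^2 across states (median and IQR).

    States with fewer than ``min_tracts_per_state`` tracts, or with a
    degenerate outcome (zero variance), are excluded and logged.
    """
    merged = scores.merge(outcome, on="GEOID", how="inner")
    factor_cols = [c for c in scores.columns if c != "GEOID"]
    rows, excluded = [], []
    for state, grp in merged.groupby("state", sort=True):
        if len(grp) < min_tracts_per_state:
            excluded.extend(
                {"factor": f, "state": state, "reason": "too few tracts"}
                for f in factor_cols
            )
            continue
        y = grp["prevalence"].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            excluded.extend(
                {"factor": f, "state": state, "reason": "constant outcome"}
                for f in factor_cols
            )
            continue
        for f in factor_cols:
            x = grp[f].to_numpy(dtype=float)
            if len(np.unique(x)) < 5:
                excluded.append(
                    {"factor": f, "state": state, "reason": "too few distinct scores"}
                )
                continue
            rows.append(
                {"factor": f, "state": state, "r2": _spline_r2(x, y), "n_tracts": len(grp)}
            )
    if not rows:
        raise ValueError("no state passed the size filter")
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("factor")["r2"]
        .agg(
            median_r2="median",
            q25_r2=lambda s: s.quantile(0.25),
            q75_r2=lambda s: s.quantile(0.75),
            n_states="count",
        )
        .reset_index()
    )
    return SplineSummary(
        table=table,
        summary=summary,
        excluded=pd.DataFrame(excluded, columns=["factor", "state", "reason"]),
    )


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class LmeFit:
    """Variance components of a fitted linear mixed model."""

    fixed_terms: list[str]
    var_state: float
    var_county: float
    var_resid: float
    fixed_effects: dict
    converged: bool

    @property
    def v_total(self) -> float:
        return self.var_state + self.var_county + self.var_resid


def fit_lme(data: pd.DataFrame, fixed_terms: list[str]) -> LmeFit:
    """Fit prevalence ~ fixed_terms + (1|state) + (1|county:state) by ML.

    ``data`` must carry ``prevalence``, ``state`` and ``county`` columns plus
    every requested fixed-effect column, with no missing values. The county
    intercept is a variance component nested inside the state grouping, so
    county codes only need to be unique within a state. Maximum likelihood
    (not REML) is used so variance comparisons across models with different
    fixed effects are coherent.
    """
    required = {"prevalence", "state", "county", *fixed_terms}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns: {sorted(missing)}")
    if data[sorted(required)].isna().any().any():
        raise ValueError("data contains missing values")
    if data["state"].nunique() < 2:
        raise ValueError("need at least 2 states")

    rhs = " + ".join(f"Q('{t}')" for t in fixed_terms) if fixed_terms else "1"
    model = smf.mixedlm(
        f"prevalence ~ {rhs}",
        data,
        groups="state",
        re_formula="1",
        vc_formula={"county": "0 + C(county)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
    var_state = float(np.asarray(result.cov_re)[0, 0])
    var_county = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    if var_state < 0 or var_county < 0:
        warnings.warn("singular fit: clamping a negative variance component to 0",
                      stacklevel=2)
    fe = {name.replace("Q('", "").replace("')", ""): float(v)
          for name, v in result.fe_params.items()}
    return LmeFit(
        fixed_terms=list(fixed_terms),
        var_state=max(var_state, 0.0),
        var_county=max(var_county, 0.0),
        var_resid=float(result.scale),
        fixed_effects=fe,
        converged=bool(result.converged),
    )


@dataclass
class VarianceDecomposition:
    """Variance decomposition across the confounder-adjusted model family."""

    table: pd.DataFrame  # notation, model, v_model, r2, unique_variance, f2, effect_label
    v_null: float
    confounders: list[str]
    factors: list[str]


def decomposition_report(
    outcome: pd.DataFrame,
    scores: pd.DataFrame,
    confounder_names: list[str],
) -> VarianceDecomposition:
    """Fit the full model family and decompose variance per factor.

    Models: the random-effects-only null; the confounders-only model Ma;
    one model per factor Ma,i adding that factor to Ma; and Ma,1:k with all
    factors. Each model's R^2 is computed against the null's total variance;
    unique variance and Cohen's f^2 for the factor models are computed
    against Ma.
    """
    data = scores.merge(outcome, on="GEOID", how="inner")
    factor_cols = [c for c in scores.columns if c != "GEOID"]

    null = fit_lme(data, [])
    v_null = null.v_total
    ma = fit_lme(data, confounder_names)
    r2_a = r2_from_variances(v_null, ma.v_total)

    rows = [
        {"notation": "Ma", "model": "confounders only", "v_model": ma.v_total,
         "r2": r2_a, "unique_variance": np.nan, "f2": np.nan, "effect_label": ""}
    ]
    for i, f in enumerate(factor_cols, start=1):
        fit = fit_lme(data, confounder_names + [f])
        r2 = r2_from_variances(v_null, fit.v_total)
        f2 = cohens_f2(r2, r2_a)
        f2 = max(f2, 0.0)  # ML increments can be -epsilon numerically
        rows.append(
            {"notation": f"Ma,{i}", "model": f"confounders + {f}",
             "v_model": fit.v_total, "r2": r2,
             "unique_variance": unique_variance(r2, r2_a), "f2": f2,
             "effect_label": classify_effect(f2)}
        )
    full = fit_lme(data, confounder_names + factor_cols)
    r2_full = r2_from_variances(v_null, full.v_total)
    f2_full = max(cohens_f2(r2_full, r2_a), 0.0)
    rows.append(
        {"notation": f"Ma,1:{len(factor_cols)}", "model": "confounders + all factors",
         "v_model": full.v_total, "r2": r2_full,
         "unique_variance": unique_variance(r2_full, r2_a), "f2": f2_full,
         "effect_label": classify_effect(f2_full)}
    )
    return VarianceDecomposition(
        table=pd.DataFrame(rows),
        v_null=v_null,
        confounders=list(confounder_names),
        factors=factor_cols,
    )
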