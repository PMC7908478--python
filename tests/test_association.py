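"""Effect-size arithmetic, per-state splines, and mixed-model machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neighborfactor import (
    PUBLISHED_DECOMPOSITION,
    classify_effect,
    cohens_f2,
    fit_lme,
    r2_from_variances,
    state_spline_r2,
    unique_variance,
)
from neighborfactor.association import _spline_r2


class TestEffectArithmetic:
    @pytest.mark.parametrize(
        "v_null,v_model,expected", [(10.0, 10.0, 0.0), (10.0, 2.0, 0.8), (3.7, 0.0, 1.0)]
    )
    def test_r2_from_variances(self, v_null, v_model, expected):
        assert r2_from_variances(v_null, v_model) == pytest.approx(expected)

    def test_r2_rejects_nonpositive_null(self):
        with pytest.raises(ValueError):
            r2_from_variances(0.0, 1.0)

    @pytest.mark.parametrize(
        "with_,without,expected",
        [(0.9037, 0.8376, 0.0661), (0.8376, 0.8376, 0.0), (0.5, 0.25, 0.25)],
    )
    def test_unique_variance(self, with_, without, expected):
        assert unique_variance(with_, without) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "with_,without,expected",
        [(0.8587, 0.8376, 0.1493), (0.8376, 0.8376, 0.0), (0.5, 0.0, 1.0)],
    )
    def test_cohens_f2(self, with_, without, expected):
        assert cohens_f2(with_, without) == pytest.approx(expected, abs=5e-5)

    def test_cohens_f2_rejects_saturated_model(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)

    @pytest.mark.parametrize(
        "f2,label",
        [
            (0.0, "none"),
            (0.019999, "none"),
            (0.02, "small"),
            (0.1, "small"),
            (0.15, "medium"),
            (0.1597, "medium"),
            (0.35, "large"),
            (0.6861, "large"),
        ],
    )
    def test_classify_effect_step_function(self, f2, label):
        assert classify_effect(f2) == label

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.0, 0.99),
        st.floats(0.0, 0.99),
    )
    def test_f2_sign_matches_r2_increment(self, r2_with, r2_without):
        f2 = cohens_f2(r2_with, r2_without)
        assert (f2 >= 0) == (r2_with >= r2_without)
        assert unique_variance(r2_with, r2_without) == pytest.approx(
            f2 * (1 - r2_with), abs=1e-12
        )


class TestPublishedTableIdentities:
    """The variance-decomposition table's internal arithmetic: unique
    variance and f^2 re-derived from the R^2 columns reproduce the printed
    values (f^2 to the precision the 4-decimal R^2 inputs support)."""

    def test_unique_variance_identities(self):
        tab = PUBLISHED_DECOMPOSITION
        r2_a = float(tab.loc[tab["notation"] == "Ma", "r2"].iloc[0])
        for _, row in tab[tab["notation"] != "Ma"].iterrows():
            assert unique_variance(row["r2"], r2_a) == pytest.approx(
                row["unique_variance"], abs=5e-5
            )

    def test_f2_identities(self):
        tab = PUBLISHED_DECOMPOSITION
        r2_a = float(tab.loc[tab["notation"] == "Ma", "r2"].iloc[0])
        for _, row in tab[tab["notation"] != "Ma"].iterrows():
            assert cohens_f2(row["r2"], r2_a) == pytest.approx(row["f2"], abs=1e-3)

    def test_effect_labels_match_published_narrative(self):
        # at the two-decimal precision of the prose thresholds: the affluence
        # factor is large; seniors, racial and ethnic composition factors are
        # medium; the singleton factor explains nothing
        tab = PUBLISHED_DECOMPOSITION.set_index("notation")
        labels = {n: classify_effect(round(tab.loc[n, "f2"], 2))
                  for n in ("Ma,1", "Ma,2", "Ma,3", "Ma,4", "Ma,5")}
        assert labels["Ma,1"] == "large"
        assert labels["Ma,2"] == "none"
        assert labels["Ma,3"] == "medium"
        assert labels["Ma,4"] == "medium"
        assert labels["Ma,5"] == "medium"


def _score_outcome_frames(x, y, states):
    n = len(x)
    geoid = [f"{s:>02}{1:03d}{i:06d}" for i, s in enumerate(states)]
    scores = pd.DataFrame({"GEOID": geoid, "factor_1": x})
    outcome = pd.DataFrame(
        {"GEOID": geoid, "state": [f"{s:>02}" for s in states],
         "county": ["001"] * n, "prevalence": y}
    )
    return scores, outcome


class TestStateSplines:
    def test_exact_cubic_signal_fits_perfectly(self):
        rng = np.random.default_rng(0)
        states = np.repeat([1, 2, 3], 80)
        x = rng.uniform(-2, 2, len(states))
        y = 0.3 + 0.05 * x + 0.02 * x**2 - 0.01 * x**3
        scores, outcome = _score_outcome_frames(x, y, states)
        res = state_spline_r2(scores, outcome)
        assert (res.table["r2"] >= 1 - 1e-6).all()

    def test_pure_noise_has_negligible_r2(self):
        rng = np.random.default_rng(1)
        states = np.repeat(np.arange(1, 6), 200)
        x = rng.standard_normal(len(states))
        y = rng.uniform(0.1, 0.3, len(states))
        scores, outcome = _score_outcome_frames(x, y, states)
        res = state_spline_r2(scores, outcome)
        assert res.summary["median_r2"].iloc[0] < 0.05

    def test_spline_nests_linear_fit(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, 150)
        y = 0.2 + 0.1 * x + 0.01 * rng.standard_normal(150)
        lin_r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert _spline_r2(x, y) >= lin_r2 - 1e-6

    def test_small_states_excluded(self):
        rng = np.random.default_rng(3)
        states = np.r_[np.repeat(1, 50), np.repeat(2, 5)]
        x = rng.standard_normal(len(states))
        y = rng.uniform(0.1, 0.3, len(states))
        scores, outcome = _score_outcome_frames(x, y, states)
        res = state_spline_r2(scores, outcome, min_tracts_per_state=20)
        assert set(res.table["state"]) == {"01"}
        assert (res.excluded["state"] == "02").all()

    def test_all_states_too_small_raises(self):
        rng = np.random.default_rng(4)
        states = np.repeat([1, 2], 5)
        x = rng.standard_normal(10)
        scores, outcome = _score_outcome_frames(x, np.full(10, 0.2), states)
        with pytest.raises(ValueError):
            state_spline_r2(scores, outcome)

    def test_fixture_effect_ordering(self, study, aligned_scores):
        """The strongly weighted factor out-fits the weakly weighted one in
        the bivariate spline summaries (|beta| 0.5 vs 0.1 in the truth)."""
        cols = [c for c in study.scores.columns if c != "GEOID"]
        res = state_spline_r2(study.scores, study.outcome)
        med = res.summary.set_index("factor")["median_r2"]
        # model factor matched to truth factor j sits at position perm[j]
        strong = cols[int(np.argmax(study.perm == 0))]
        weak = cols[int(np.argmax(study.perm == 1))]
        assert med[strong] > med[weak]


def _hierarchical_outcome(rng, n_states=50, n_counties=4, n_tracts=50,
                          state_sd=0.5, county_sd=0.2, resid_sd=0.3):
    rows = []
    for s in range(n_states):
        us = rng.normal(0, state_sd)
        for c in range(n_counties):
            uc = rng.normal(0, county_sd)
            for t in range(n_tracts):
                rows.append((f"{s:02d}", f"{c:03d}", us + uc))
    df = pd.DataFrame(rows, columns=["state", "county", "mu"])
    df["prevalence"] = df["mu"] + rng.normal(0, resid_sd, len(df))
    return df.drop(columns="mu")


class TestMixedModels:
    def test_null_model_variance_components_recovered(self):
        rng = np.random.default_rng(5)
        df = _hierarchical_outcome(rng)
        fit = fit_lme(df, [])
        assert fit.var_state == pytest.approx(0.25, rel=0.3)
        assert fit.var_county == pytest.approx(0.04, rel=0.3)
        assert fit.var_resid == pytest.approx(0.09, rel=0.3)

    def test_null_fixed_effects_reproduce_null_variance(self):
        rng = np.random.default_rng(6)
        df = _hierarchical_outcome(rng, n_states=10, n_counties=2, n_tracts=30)
        null = fit_lme(df, [])
        assert r2_from_variances(null.v_total, null.v_total) == 0.0

    def test_noise_covariate_barely_changes_variance(self):
        rng = np.random.default_rng(7)
        df = _hierarchical_outcome(rng, n_states=20, n_counties=2, n_tracts=40)
        df["noise"] = rng.standard_normal(len(df))
        v0 = fit_lme(df, []).v_total
        v1 = fit_lme(df, ["noise"]).v_total
        assert abs(v1 - v0) / v0 < 0.01

    def test_informative_covariate_reduces_variance(self):
        rng = np.random.default_rng(8)
        df = _hierarchical_outcome(rng, n_states=10, n_counties=2, n_tracts=40)
        df["x"] = rng.standard_normal(len(df))
        df["prevalence"] = df["prevalence"] + 0.5 * df["x"]
        v0 = fit_lme(df, []).v_total
        v1 = fit_lme(df, ["x"]).v_total
        r2 = r2_from_variances(v0, v1)
        assert r2 > 0.2
        assert v1 <= v0 + 1e-9  # ML monotonicity

    def test_missing_column_rejected(self):
        df = pd.DataFrame({"prevalence": [0.1, 0.2], "state": ["01", "02"],
                           "county": ["001", "001"]})
        with pytest.raises(ValueError, match="ghost"):
            fit_lme(df, ["ghost"])

    def test_single_state_rejected(self):
        df = pd.DataFrame({"prevalence": [0.1, 0.2], "state": ["01", "01"],
                           "county": ["001", "002"]})
        with pytest.raises(ValueError, match="states"):
            fit_lme(df, [])
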