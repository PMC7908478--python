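"""Factor extraction, rotation, diagnostics, scores and bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

from neighborfactor import (
    bootstrap_loading_se,
    compute_scores,
    factor_diagnostics,
    fit_efa,
    score_correlations,
    tucker_congruence,
)
from neighborfactor.efa import FactorModel, align_factors, congruence_matrix, scree_elbow


def two_factor_population_R():
    lam = np.zeros((6, 2))
    lam[:3, 0] = [0.8, 0.7, 0.6]
    lam[3:, 1] = [0.75, 0.65, 0.7]
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    psi = 1.0 - np.diag(lam @ phi @ lam.T)
    return lam, phi, psi, lam @ phi @ lam.T + np.diag(psi)


def test_identity_correlation_has_no_common_factor():
    m = fit_efa(np.eye(5), 1)
    assert np.abs(m.loadings).max() < 1e-6
    assert np.allclose(m.uniquenesses, 1.0, atol=1e-6)


def test_recovers_closed_form_two_factor_structure():
    lam, phi, psi, R = two_factor_population_R()
    m = fit_efa(R, 2)
    aligned, _, _ = align_factors(lam, m.loadings)
    cong = np.abs(np.diag(congruence_matrix(lam, aligned)))
    assert np.all(cong >= 0.999)
    assert m.factor_corr[0, 1] == pytest.approx(0.3, abs=1e-4)
    assert np.allclose(m.uniquenesses, psi, atol=1e-6)
    assert m.offdiag_fit == pytest.approx(1.0, abs=1e-9)
    assert m.rms_residual == pytest.approx(0.0, abs=1e-6)


def test_reproduced_diagonal_identity(study):
    m = study.model
    diag = np.diag(m.loadings @ m.factor_corr @ m.loadings.T) + m.uniquenesses
    assert np.allclose(diag, 1.0, atol=1e-6)


def test_sign_and_order_conventions(study):
    m = study.model
    for j in range(m.k):
        assert m.loadings[np.argmax(np.abs(m.loadings[:, j])), j] > 0
    assert np.all(np.diff(m.variance_explained) <= 1e-12)


def test_column_permutation_equivariance():
    rng = np.random.default_rng(5)
    lam, phi, psi, R = two_factor_population_R()
    X = rng.multivariate_normal(np.zeros(6), R, size=2000)
    m1 = fit_efa(X, 2)
    perm = np.array([3, 0, 5, 1, 4, 2])
    m2 = fit_efa(X[:, perm], 2)
    aligned, _, _ = align_factors(m1.loadings[perm], m2.loadings)
    assert np.allclose(aligned, m1.loadings[perm], atol=1e-4)


def test_fixture_recovery(study):
    """End-to-end recovery: selection -> transform -> impute -> EFA matches
    the generating loadings factor-for-factor."""
    assert np.all(study.congruence >= 0.95)


def test_phi_off_diagonals_recovered(study):
    est = study.model.factor_corr[np.ix_(study.perm, study.perm)]
    est = est * np.outer(study.signs, study.signs)
    true = study.truth.factor_corr
    off = ~np.eye(study.truth.k, dtype=bool)
    assert np.abs(est[off] - true[off]).max() < 0.15


def test_invalid_k_rejected(study):
    with pytest.raises(ValueError):
        fit_efa(np.eye(4), 0)
    with pytest.raises(ValueError):
        fit_efa(np.eye(4), 4)


def test_incomplete_matrix_rejected():
    X = np.random.default_rng(0).standard_normal((50, 4))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        fit_efa(X, 1)


class TestDiagnostics:
    def test_identity_spectrum(self):
        d = factor_diagnostics(np.eye(6), 2)
        eig = d.attrs["eigenvalues"]
        assert np.allclose(eig, 1.0, atol=1e-9)
        assert d.attrs["kaiser_count"] == 6  # >= rule counts eigenvalues == 1

    def test_equicorrelation_closed_form(self):
        # all pairwise r = 0.64 (single factor, loadings 0.8), p = 5:
        # leading eigenvalue 1 + (p-1) r = 3.56, perfect off-diagonal fit at k=1
        R = np.full((5, 5), 0.64)
        np.fill_diagonal(R, 1.0)
        d = factor_diagnostics(R, 2)
        assert d.attrs["eigenvalues"][0] == pytest.approx(3.56, abs=1e-9)
        assert d.loc[1, "offdiag_fit"] == pytest.approx(1.0, abs=1e-9)
        assert d.loc[1, "rms_residual"] == pytest.approx(0.0, abs=1e-6)

    def test_eigenvalues_sum_to_p(self, study):
        assert study.model.eigenvalues.sum() == pytest.approx(
            len(study.model.variables), abs=1e-6
        )

    def test_fixture_suggests_at_least_five_factors(self, study):
        d = factor_diagnostics(study.imputed, 6)
        assert d.attrs["kaiser_count"] >= 5
        assert d.attrs["scree_elbow"] >= 5

    def test_offdiag_fit_improves_with_k(self, study):
        d = factor_diagnostics(study.imputed, 6)
        assert d["offdiag_fit"].is_monotonic_increasing


def test_scree_elbow_on_clean_spectrum():
    # spectrum with a sharp break after 3 large eigenvalues
    eig = np.array([5.0, 4.0, 3.0, 0.4, 0.35, 0.3, 0.25])
    assert scree_elbow(eig) == 3


class TestScores:
    def test_single_variable_unit_loading(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        model = FactorModel(
            loadings=np.array([[1.0]]),
            factor_corr=np.eye(1),
            uniquenesses=np.array([1e-3]),
            eigenvalues=np.array([1.0]),
            variance_explained=np.array([1.0]),
            cumulative_variance=1.0,
            rms_residual=0.0,
            offdiag_fit=1.0,
            corr=np.eye(1),
            variables=["x"],
        )
        s = compute_scores(model, x[:, None])
        z = (x - x.mean()) / x.std(ddof=0)
        assert np.allclose(s["factor_1"], z)

    def test_score_truth_correlation(self, study, aligned_scores):
        for j in range(study.truth.k):
            r = np.corrcoef(aligned_scores[:, j], study.factors[:, j])[0, 1]
            assert abs(r) >= 0.9

    def test_score_correlations_consistent_with_phi(self, study):
        emp = score_correlations(study.scores).to_numpy()
        m = study.model
        S = m.loadings @ m.factor_corr
        W = np.linalg.solve(m.corr, S)
        implied_cov = W.T @ m.corr @ W
        d = np.sqrt(np.diag(implied_cov))
        implied = implied_cov / np.outer(d, d)
        off = ~np.eye(m.k, dtype=bool)
        assert np.abs(emp[off] - implied[off]).max() < 0.05


class TestScoreCorrelations:
    def test_duplicated_column_correlates_perfectly(self):
        x = np.random.default_rng(7).standard_normal(100)
        s = pd.DataFrame({"factor_1": x, "factor_2": x})
        assert score_correlations(s).iloc[0, 1] == pytest.approx(1.0)

    def test_constant_column_reported_undefined(self):
        s = pd.DataFrame({"factor_1": [1.0, 2.0, 3.0], "factor_2": [1.0, 1.0, 1.0]})
        c = score_correlations(s)
        assert np.isnan(c.iloc[0, 1])
        assert c.iloc[1, 1] == 1.0

    def test_planted_factor_correlation_recovered(self, study):
        # the true factor draws carry the generating Phi
        f = pd.DataFrame(study.factors, columns=[f"f{j}" for j in range(study.truth.k)])
        est = score_correlations(f).to_numpy()
        off = ~np.eye(study.truth.k, dtype=bool)
        assert np.abs(est[off] - study.truth.factor_corr[off]).max() < 0.05


def test_tucker_congruence_is_scale_invariant():
    v = np.array([0.8, 0.1, -0.3])
    assert tucker_congruence(v, 2.5 * v) == pytest.approx(1.0)
    assert tucker_congruence(v, -v) == pytest.approx(-1.0)


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        lam, phi, psi, R = two_factor_population_R()
        X = rng.multivariate_normal(np.zeros(6), R, size=400)
        b1 = bootstrap_loading_se(X, 2, n_boot=25, seed=11)
        b2 = bootstrap_loading_se(X, 2, n_boot=25, seed=11)
        assert np.array_equal(b1.loading_se, b2.loading_se)

    def test_near_deterministic_data_has_tiny_se(self):
        rng = np.random.default_rng(9)
        lam, phi, psi, R = two_factor_population_R()
        F = rng.multivariate_normal(np.zeros(2), phi, size=3000)
        X = F @ lam.T + 1e-3 * rng.standard_normal((3000, 6))
        b = bootstrap_loading_se(X, 2, n_boot=40, seed=12)
        assert b.loading_se.max() < 0.02
        assert b.congruence_min > 0.999

    def test_se_scales_with_sample_size(self):
        rng = np.random.default_rng(10)
        lam, phi, psi, R = two_factor_population_R()
        X = rng.multivariate_normal(np.zeros(6), R, size=300)
        X2 = np.vstack([X, X])
        b1 = bootstrap_loading_se(X, 2, n_boot=200, seed=13)
        b2 = bootstrap_loading_se(X2, 2, n_boot=200, seed=13)
        ratio = b2.loading_se.mean() / b1.loading_se.mean()
        assert 0.6 <= ratio <= 0.85  # ~ 1/sqrt(2)

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_loading_se(np.eye(4), 1, n_boot=1, seed=0)
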