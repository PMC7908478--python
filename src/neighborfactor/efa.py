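"""Exploratory factor analysis: minres extraction, oblimin rotation,
diagnostics, regression scores and bootstrap loading stability.

Minimum-residual (minres) extraction finds uniquenesses psi minimizing the
sum of squared off-diagonal residuals of R - Lambda Lambda' where Lambda is
the rank-k eigen-approximation of R - diag(psi). Direct oblimin (gamma = 0,
i.e. quartimin) rotation is performed by the oblique gradient-projection
algorithm of Jennrich, yielding a pattern matrix Lambda and factor
correlation matrix Phi. Conventions making the solution unique: each
factor's largest-|loading| entry is positive, and factors are ordered by
descending variance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.optimize import linear_sum_assignment

MAX_COMMUNALITY = 0.995  # Heywood clamp


@dataclass
class FactorModel:
    loadings: np.ndarray        # p x k oblimin pattern matrix
    factor_corr: np.ndarray     # k x k Phi
    uniquenesses: np.ndarray    # length p, in (0, 1]
    eigenvalues: np.ndarray     # of the observed correlation matrix, length p
    variance_explained: np.ndarray  # per-factor proportion of total variance
    cumulative_variance: float
    rms_residual: float
    offdiag_fit: float
    corr: np.ndarray            # the observed correlation matrix R
    variables: list[str] = field(default_factory=list)
    rotation: str = "oblimin"
    extraction: str = "minres"

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses


@dataclass
class BootstrapStability:
    loading_se: np.ndarray      # p x k standard errors
    n_boot: int
    n_dropped: int
    congruence_min: float       # min over resamples/factors of |Tucker congruence|
    congruence_median: float


# ---------------------------------------------------------------------------
# minres extraction


def _loadings_given_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rs = R - np.diag(psi)
    vals, vecs = np.linalg.eigh(Rs)
    vals_k = np.clip(vals[-k:], 0.0, None)
    return vecs[:, -k:] * np.sqrt(vals_k)


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    lam = _loadings_given_psi(R, psi, k)
    resid = R - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float(np.sum(resid**2))


def _ols_objective_grad(
    psi: np.ndarray, R: np.ndarray, k: int
) -> tuple[float, np.ndarray]:
    """Full-residual least-squares objective ||R - diag(psi) - LL'||_F^2.

    Because LL' is the rank-k Frobenius minimizer for the reduced matrix,
    the envelope theorem gives the exact gradient -2 diag(residual). At the
    optimum the diagonal residuals vanish (psi is free), so this objective
    attains the same solution as the off-diagonal-only minres criterion
    while being two orders of magnitude cheaper to differentiate.
    """
    Rs = R - np.diag(psi)
    vals, vecs = np.linalg.eigh(Rs)
    vals_k = np.clip(vals[-k:], 0.0, None)
    lam = vecs[:, -k:] * np.sqrt(vals_k)
    resid = Rs - lam @ lam.T
    return float(np.sum(resid**2)), -2.0 * np.diag(resid).copy()


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (communality start values)."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        smc = np.full(R.shape[0], 0.5)
    return np.clip(smc, 0.0, MAX_COMMUNALITY)


def extract_minres(
    R: np.ndarray, k: int, psi0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated minres loadings and uniquenesses for a correlation matrix.

    ``psi0`` warm-starts the uniquenesses (used by the bootstrap, where each
    resample's solution is close to the full-sample one).
    """
    p = R.shape[0]
    if psi0 is None:
        psi0 = 1.0 - _smc(R)
    psi0 = np.clip(psi0, 1.0 - MAX_COMMUNALITY, 1.0)
    res = optimize.minimize(
        _ols_objective_grad,
        psi0,
        args=(R, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(1.0 - MAX_COMMUNALITY, 1.0)] * p,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
    )
    if not res.success and res.status != 2:  # status 2: precision loss, accept
        raise RuntimeError(
            f"minres extraction failed to converge: {res.message} "
            f"(nit={res.nit}, fun={res.fun:.3e})"
        )
    psi = res.x
    lam = _loadings_given_psi(R, psi, k)
    comm = np.sum(lam**2, axis=1)
    heywood = comm > MAX_COMMUNALITY
    if heywood.any():
        warnings.warn(
            f"Heywood case: clamping {int(heywood.sum())} communalities to "
            f"{MAX_COMMUNALITY}",
            stacklevel=2,
        )
        lam[heywood] *= np.sqrt(MAX_COMMUNALITY / comm[heywood])[:, None]
        psi = np.clip(1.0 - np.sum(lam**2, axis=1), 1.0 - MAX_COMMUNALITY, 1.0)
    return lam, psi


# ---------------------------------------------------------------------------
# direct oblimin (quartimin) rotation by oblique gradient projection


def _quartimin(L: np.ndarray, N: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion value and gradient wrt the rotated loadings.

    ``N`` is the k x k hollow matrix (ones off the diagonal)."""
    L2 = L * L
    X = L2 @ N
    f = float((L2 * X).sum()) / 4.0
    return f, L * X


def rotate_oblimin(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation of unrotated loadings ``A``.

    Returns the pattern matrix ``L = A (T')^-1`` and factor correlation
    ``Phi = T'T`` minimizing the quartimin criterion.
    """
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    N = np.ones((k, k)) - np.eye(k)
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L, N)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X * X).sum(axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _quartimin(Lt, N)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi


def _canonicalize(
    lam: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sign and order conventions; returns (lam, phi, variance_explained).

    Variance explained per factor is diag(Phi Lambda' Lambda) / p, the
    oblique analogue of the sum of squared loadings.
    """
    p, k = lam.shape
    # sign: largest-|loading| entry of each factor positive
    for j in range(k):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
    ss = np.diag(phi @ lam.T @ lam) / p
    order = np.argsort(-ss)
    lam = lam[:, order]
    phi = phi[np.ix_(order, order)]
    ss = ss[order]
    # re-apply sign convention after reordering (phi rows/cols moved intact)
    return lam, phi, ss


def _fit_stats(R: np.ndarray, lam: np.ndarray, phi: np.ndarray) -> tuple[float, float]:
    resid = R - lam @ phi @ lam.T
    np.fill_diagonal(resid, 0.0)
    off = ~np.eye(R.shape[0], dtype=bool)
    ss_resid = float(np.sum(resid[off] ** 2))
    ss_r = float(np.sum(R[off] ** 2))
    rms = float(np.sqrt(np.mean(resid[off] ** 2)))
    fit = 1.0 - ss_resid / ss_r if ss_r > 0 else 1.0
    return rms, fit


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        cols = [c for c in matrix.columns if c != "GEOID"]
        return matrix[cols].to_numpy(dtype=float), cols
    X = np.asarray(matrix, dtype=float)
    return X, [f"v{i + 1}" for i in range(X.shape[1])]


def fit_efa(
    matrix, k: int, rotate: bool = True, psi0: np.ndarray | None = None
) -> FactorModel:
    """Fit a k-factor minres model with oblimin rotation to a data matrix.

    ``matrix`` may be an n x p data matrix (DataFrame or array) or a p x p
    correlation matrix (detected as square symmetric with unit diagonal).
    """
    X, variables = _as_matrix(matrix)
    if np.isnan(X).any():
        raise ValueError("matrix must be complete (impute first)")
    if (
        X.shape[0] == X.shape[1]
        and np.allclose(X, X.T)
        and np.allclose(np.diag(X), 1.0)
    ):
        R = X.copy()
    else:
        R = np.corrcoef(X, rowvar=False)
    p = R.shape[0]
    if not 1 <= k < p:
        raise ValueError("need 1 <= k < number of variables")

    lam, psi = extract_minres(R, k, psi0=psi0)
    if rotate and k > 1:
        lam, phi = rotate_oblimin(lam)
        rotation = "oblimin"
    else:
        phi = np.eye(k)
        rotation = "none" if not rotate else "oblimin"
    lam, phi, ss = _canonicalize(lam, phi)
    rms, fit = _fit_stats(R, lam, phi)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    return FactorModel(
        loadings=lam,
        factor_corr=phi,
        uniquenesses=psi,
        eigenvalues=eigenvalues,
        variance_explained=ss,
        cumulative_variance=float(np.sum(1.0 - psi) / p),
        rms_residual=rms,
        offdiag_fit=fit,
        corr=R,
        variables=variables,
        rotation=rotation,
    )


# ---------------------------------------------------------------------------
# diagnostics


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Suggested factor count from the acceleration (second difference) of
    the scree curve: the count of eigenvalues preceding the point of maximum
    acceleration.

    The second difference is taken on the log scale — the elbow of a scree
    plot is where the *relative* decay collapses into the flat noise tail,
    and on the raw scale the widely spaced leading eigenvalues of a strong
    multi-factor structure would mask that break."""
    e = np.log(np.clip(np.asarray(eigenvalues, dtype=float), 1e-12, None))
    if len(e) < 3:
        return 1
    accel = e[:-2] - 2.0 * e[1:-1] + e[2:]  # second difference at i = 1..p-2
    return int(np.argmax(accel)) + 1


def factor_diagnostics(matrix, k_max: int) -> pd.DataFrame:
    """Factor-number diagnostics: eigenvalues, Kaiser count, scree elbow and
    per-k fit statistics.

    Returns a DataFrame with one row per k in 1..k_max (columns
    ``cumulative_variance``, ``rms_residual``, ``offdiag_fit``) carrying
    ``eigenvalues``, ``kaiser_count`` and ``scree_elbow`` in ``attrs``.
    """
    X, _ = _as_matrix(matrix)
    probe = fit_efa(matrix, 1)
    eig = probe.eigenvalues
    if k_max >= len(eig):
        raise ValueError("k_max must be smaller than the number of variables")
    rows = []
    for k in range(1, k_max + 1):
        m = fit_efa(matrix, k)
        rows.append(
            {
                "k": k,
                "cumulative_variance": m.cumulative_variance,
                "rms_residual": m.rms_residual,
                "offdiag_fit": m.offdiag_fit,
            }
        )
    out = pd.DataFrame(rows).set_index("k")
    out.attrs["eigenvalues"] = eig
    out.attrs["kaiser_count"] = int(np.sum(eig >= 1.0))
    out.attrs["scree_elbow"] = scree_elbow(eig)
    return out


# ---------------------------------------------------------------------------
# scores


def compute_scores(model: FactorModel, matrix) -> pd.DataFrame:
    """Regression (Thurstone) factor scores: W = R^-1 Lambda Phi.

    Scores are computed on the standardized data; the result is keyed by
    GEOID when the input carries one.
    """
    X, variables = _as_matrix(matrix)
    if np.isnan(X).any():
        raise ValueError("matrix must be complete")
    if variables != model.variables and len(variables) != len(model.variables):
        raise ValueError("matrix columns do not match the model's variables")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    R = model.corr
    S = model.loadings @ model.factor_corr  # structure matrix
    try:
        W = np.linalg.solve(R, S)
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; ridge-regularizing", stacklevel=2)
        W = np.linalg.solve(R + 1e-8 * np.eye(R.shape[0]), S)
    scores = Z @ W
    out = pd.DataFrame(
        scores, columns=[f"factor_{j + 1}" for j in range(model.k)]
    )
    if isinstance(matrix, pd.DataFrame) and "GEOID" in matrix.columns:
        out.insert(0, "GEOID", matrix["GEOID"].to_numpy())
    return out


def score_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the factor scores (unit diagonal;
    constant columns yield NaN entries)."""
    cols = [c for c in scores.columns if c != "GEOID"]
    if len(scores) < 3:
        raise ValueError("need at least 3 rows")
    X = scores[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C[np.ix_(sd == 0, np.arange(len(cols)))] = np.nan
    C[np.ix_(np.arange(len(cols)), np.flatnonzero(sd == 0))] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# bootstrap stability


def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    if denom == 0:
        return 0.0
    return float(np.sum(x * y) / denom)


def congruence_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """k x k matrix of Tucker congruences between columns of A and B."""
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn


def align_factors(reference: np.ndarray, candidate: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match candidate factors to reference columns (Hungarian assignment on
    |Tucker congruence|, with sign flips). Returns (aligned loadings,
    permutation, signs)."""
    C = congruence_matrix(reference, candidate)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(len(cols), dtype=int)
    perm[rows] = cols
    signs = np.sign(C[rows, cols][np.argsort(rows)])
    signs[signs == 0] = 1.0
    aligned = candidate[:, perm] * signs
    return aligned, perm, signs


def bootstrap_loading_se(
    matrix, k: int, n_boot: int = 2000, seed: int = 0
) -> BootstrapStability:
    """Bootstrap standard errors of the oblimin pattern loadings.

    Rows are resampled with replacement; each resample is refitted and its
    factors aligned to the full-sample reference solution before pooling.
    Resamples that fail to converge are dropped (an error is raised if more
    than 5% are).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X, _ = _as_matrix(matrix)
    reference = fit_efa(X, k)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots, congruences = [], []
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_efa(X[idx], k, psi0=reference.uniquenesses)
        except (RuntimeError, np.linalg.LinAlgError):
            dropped += 1
            continue
        aligned, perm, signs = align_factors(reference.loadings, m.loadings)
        C = congruence_matrix(reference.loadings, aligned)
        congruences.extend(np.abs(np.diag(C)))
        boots.append(aligned)
    if dropped > 0.05 * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap resamples failed to converge")
    stack = np.stack(boots)
    return BootstrapStability(
        loading_se=stack.std(axis=0, ddof=1),
        n_boot=n_boot,
        n_dropped=dropped,
        congruence_min=float(np.min(congruences)),
        congruence_median=float(np.median(congruences)),
    )
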