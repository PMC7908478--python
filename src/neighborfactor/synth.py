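"""Synthetic tract tables with known oblique latent structure.

Real inputs for this kind of analysis are five-year census demographic
estimates (hundreds of tract-level proportions and means) merged with a
small-area-estimated health prevalence. The generator here emulates the
properties that stress each pipeline stage: skewed non-Gaussian marginals
produced by known monotone maps of latent-normal columns, redundant
complement variables, near-constant columns, strata subgroups that sum to a
parent statistic, sparse missingness, a state -> county -> tract hierarchy,
and an outcome driven by the latent factors plus random intercepts and
confounders. Every generated artifact carries its ground truth so recovery
can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

# the 13 variable groups a demographic table of this kind covers
VARIABLE_GROUPS = [
    "age",
    "race/ethnicity",
    "nativity/citizenship",
    "mobility",
    "transportation",
    "household type",
    "marital status",
    "education",
    "disability",
    "income",
    "employment",
    "residential conditions",
    "tenure",
]

#: monotone skew maps applied round-robin to latent-normal core columns.
#: "square" is a shifted square (z+5)^2 so the map stays monotone on the
#: support of z and a square-root transform can undo it.
SKEW_MAPS = ("exp", "square", "logistic", "identity")


def _apply_skew(z: np.ndarray, name: str) -> np.ndarray:
    if name == "exp":
        return np.exp(z / 2.0)
    if name == "square":
        return (z + 5.0) ** 2
    if name == "logistic":
        # shifted so the proportion is right-skewed (small shares with a
        # tail), as demographic shares typically are; a symmetric proportion
        # would need no transform at all
        return expit(z - 1.5)
    if name == "identity":
        return z.copy()
    raise ValueError(f"unknown skew map {name!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth generating parameters for one synthetic study.

    ``loadings`` (p_core x k), ``factor_corr`` (k x k) and ``uniquenesses``
    define the latent structure of the core demographic columns on the
    standardized scale: each core column is ``F @ loadings[i] + e_i`` with
    ``Var(e_i) = uniquenesses[i]`` so its variance is exactly 1 before the
    marginal skew map is applied. The outcome side holds logit-scale fixed
    effects per factor standard deviation, confounder coefficients and the
    random-intercept SDs of the state/county hierarchy.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    outcome_betas: np.ndarray
    confounder_betas: np.ndarray
    intercept: float
    state_sd: float
    county_sd: float
    noise_sd: float
    marginal_transforms: list[str]
    missing_rate: float
    seed: int

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def p_core(self) -> int:
        return self.loadings.shape[0]

    def validate(self) -> None:
        phi = self.factor_corr
        if not np.allclose(phi, phi.T):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("factor_corr must be positive-definite")
        comm = np.diag(self.loadings @ phi @ self.loadings.T)
        if not np.allclose(comm + self.uniquenesses, 1.0, atol=1e-9):
            raise ValueError("communality + uniqueness must equal 1 per variable")
        if not (0 <= self.missing_rate < 0.05):
            raise ValueError("missing_rate must lie in [0, 0.05)")


class TractData(NamedTuple):
    """Output bundle of :func:`generate_tract_table`."""

    table: pd.DataFrame  # GEOID + all variable columns (with planted artifacts)
    catalog: pd.DataFrame  # per-variable metadata (group, role, parent, ...)
    geography: pd.DataFrame  # GEOID, state, county
    factors: np.ndarray  # n_tracts x k latent draws used for the core columns


DEFAULT_OUTCOME_BETAS = np.array([-0.5, 0.1, 0.3, 0.15, 0.25])
DEFAULT_CONFOUNDER_BETAS = np.array([0.25, -0.15, 0.35, 0.45])
CONFOUNDER_NAMES = ["age_conf", "sex_ratio", "minority_share", "poverty"]


def _draw_factor_corr(k: int, rng: np.random.Generator, max_retries: int = 100) -> np.ndarray:
    if k == 1:
        return np.ones((1, 1))
    for _ in range(max_retries):
        phi = np.eye(k)
        off = rng.uniform(-0.4, 0.4, size=(k, k))
        iu = np.triu_indices(k, 1)
        phi[iu] = off[iu]
        phi.T[iu] = off[iu]
        if np.linalg.eigvalsh(phi).min() > 0.05:
            return phi
    raise RuntimeError(
        f"could not draw a positive-definite factor correlation in {max_retries} tries"
    )


def generate_truth(
    k: int,
    p_core: int,
    seed: int,
    *,
    missing_rate: float = 0.0016,
    state_sd: float = 0.2,
    county_sd: float = 0.1,
    noise_sd: float = 0.15,
    baseline_prevalence: float = 0.12,
    outcome_betas: np.ndarray | None = None,
) -> SyntheticTruth:
    """Draw a ground-truth factor structure with simple structure.

    Variables are assigned to factors round-robin; each variable gets a
    primary loading in [0.55, 0.8] and small cross-loadings in [-0.1, 0.1],
    so every variable loads >= 0.5 on exactly one factor. Factor
    correlations are drawn uniformly in [-0.4, 0.4] (resampled until
    positive-definite). Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if p_core < 3 * k:
        raise ValueError("p_core must be at least 3k so every factor is identified")
    rng = np.random.default_rng(seed)
    phi = _draw_factor_corr(k, rng)

    lam = rng.uniform(-0.1, 0.1, size=(p_core, k))
    primary = np.arange(p_core) % k
    lam[np.arange(p_core), primary] = rng.uniform(0.55, 0.8, size=p_core)

    # keep communalities comfortably below 1 so uniquenesses stay in (0, 1]
    comm = np.diag(lam @ phi @ lam.T)
    scale = np.sqrt(np.minimum(1.0, 0.9 / comm))
    lam = lam * scale[:, None]
    comm = np.diag(lam @ phi @ lam.T)
    psi = 1.0 - comm

    if outcome_betas is None:
        betas = np.resize(DEFAULT_OUTCOME_BETAS, k).astype(float)
    else:
        betas = np.asarray(outcome_betas, dtype=float)
        if betas.shape != (k,):
            raise ValueError("outcome_betas must have length k")

    truth = SyntheticTruth(
        loadings=lam,
        factor_corr=phi,
        uniquenesses=psi,
        outcome_betas=betas,
        confounder_betas=DEFAULT_CONFOUNDER_BETAS.copy(),
        intercept=float(logit(baseline_prevalence)),
        state_sd=state_sd,
        county_sd=county_sd,
        noise_sd=noise_sd,
        marginal_transforms=[SKEW_MAPS[i % len(SKEW_MAPS)] for i in range(p_core)],
        missing_rate=missing_rate,
        seed=seed,
    )
    truth.validate()
    return truth


def _make_geography(
    n_tracts: int, n_states: int, counties_per_state: int
) -> pd.DataFrame:
    """Round-robin assignment of tracts to counties within states.

    GEOIDs are synthesized 11-digit strings (2-digit state + 3-digit county
    + 6-digit tract); no real FIPS codes are implied.
    """
    slots = n_states * counties_per_state
    if n_tracts < slots:
        raise ValueError("n_tracts must be >= n_states * counties_per_state")
    idx = np.arange(n_tracts)
    state = idx % n_states + 1
    county = (idx // n_states) % counties_per_state + 1
    state_s = np.char.zfill(state.astype(str), 2)
    county_s = np.char.zfill(county.astype(str), 3)
    tract_s = np.char.zfill(idx.astype(str), 6)
    geoid = np.char.add(np.char.add(state_s, county_s), tract_s)
    return pd.DataFrame({"GEOID": geoid, "state": state_s, "county": county_s})


def generate_tract_table(
    truth: SyntheticTruth,
    n_tracts: int,
    n_states: int,
    counties_per_state: int,
    seed: int,
    *,
    n_complements: int = 3,
    n_low_cv: int = 1,
    n_strata_subgroups: int = 3,
    skew: bool = True,
) -> TractData:
    """Generate a tract table, its variable catalog and geography.

    Core columns are monotone skew maps of ``F @ loadings.T + noise`` with
    ``F ~ MVN(0, factor_corr)``. Planted artifacts exercise the selection
    stage: complement columns ``1 - x`` of proportion cores, near-constant
    columns with coefficient of variation far below 0.06, and one stratum
    group (a proportion core split into subgroup columns that sum to the
    parent exactly). Missing entries are planted completely at random at
    ``truth.missing_rate``. ``skew=False`` leaves core columns latent-normal,
    which is useful for checking generative consistency.
    """
    rng = np.random.default_rng(seed)
    geo = _make_geography(n_tracts, n_states, counties_per_state)
    p, k = truth.p_core, truth.k

    chol = np.linalg.cholesky(truth.factor_corr)
    factors = rng.standard_normal((n_tracts, k)) @ chol.T
    noise = rng.standard_normal((n_tracts, p)) * np.sqrt(truth.uniquenesses)
    latent = factors @ truth.loadings.T + noise  # each column ~ N(0, 1)

    names = [f"core_{i + 1:02d}" for i in range(p)]
    groups = [VARIABLE_GROUPS[i % len(VARIABLE_GROUPS)] for i in range(p)]
    cols: dict[str, np.ndarray] = {}
    catalog_rows: list[dict] = []
    for i, name in enumerate(names):
        mapped = (
            _apply_skew(latent[:, i], truth.marginal_transforms[i])
            if skew
            else latent[:, i].copy()
        )
        if np.ptp(mapped) == 0:
            raise RuntimeError(f"degenerate skew map produced constant column {name}")
        cols[name] = mapped
        catalog_rows.append(
            {"variable": name, "group": groups[i], "role": "core",
             "parent": "", "complement_of": "", "combine_rule": ""}
        )

    # complements of proportion-valued (logistic-mapped) cores
    logistic_idx = [
        i for i, t in enumerate(truth.marginal_transforms) if t == "logistic"
    ] if skew else []
    comp_idx = logistic_idx[:n_complements]
    for i in comp_idx:
        name = f"{names[i]}_comp"
        cols[name] = 1.0 - cols[names[i]]
        catalog_rows.append(
            {"variable": name, "group": groups[i], "role": "complement",
             "parent": "", "complement_of": names[i], "combine_rule": ""}
        )

    for j in range(n_low_cv):
        name = f"low_cv_{j + 1:02d}"
        cols[name] = rng.normal(1.0, 0.002, size=n_tracts)
        catalog_rows.append(
            {"variable": name, "group": VARIABLE_GROUPS[j % len(VARIABLE_GROUPS)],
             "role": "low_cv", "parent": "", "complement_of": "", "combine_rule": ""}
        )

    # one stratum group: split the last unused logistic core into additive
    # subgroups; the parent column itself is withheld from the table and is
    # reconstructed by the strata-combination stage.
    stratum_parent = None
    if skew and n_strata_subgroups >= 2:
        candidates = [i for i in logistic_idx if i not in comp_idx]
        if candidates:
            pi = candidates[-1]
            stratum_parent = names[pi]
            weights = rng.dirichlet(np.full(n_strata_subgroups, 5.0), size=n_tracts)
            parent_vals = cols.pop(stratum_parent)
            catalog_rows = [r for r in catalog_rows if r["variable"] != stratum_parent]
            for s in range(n_strata_subgroups):
                name = f"{stratum_parent}_s{s + 1}"
                cols[name] = parent_vals * weights[:, s]
                catalog_rows.append(
                    {"variable": name, "group": groups[pi], "role": "stratum",
                     "parent": stratum_parent, "complement_of": "",
                     "combine_rule": "sum"}
                )

    table = pd.DataFrame(cols)
    if truth.missing_rate > 0:
        mask = rng.random(table.shape) < truth.missing_rate
        # keep at least one observed value per row so imputation is defined
        full_rows = mask.all(axis=1)
        mask[full_rows, 0] = False
        values = table.to_numpy()
        values[mask] = np.nan
        table = pd.DataFrame(values, columns=table.columns)
    table.insert(0, "GEOID", geo["GEOID"].to_numpy())

    catalog = pd.DataFrame(catalog_rows)
    return TractData(table=table, catalog=catalog, geography=geo, factors=factors)


def generate_outcome(
    truth: SyntheticTruth,
    factor_draws: np.ndarray,
    geography: pd.DataFrame,
    seed: int,
    *,
    confounder_r2: float = 0.5,
    confounder_loadings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Generate the tract-level prevalence outcome and its confounders.

    ``prevalence = expit(b0 + F @ betas + C @ gammas + u_state + u_county + e)``
    with ``u`` and ``e`` normal with the truth SDs. Confounder columns (age,
    sex ratio, minority share, poverty) are noisy linear images of the
    factors with the requested R^2 against them, so they genuinely confound
    the factor-outcome relationship the way the covariates baked into a
    small-area-estimated prevalence would. ``confounder_loadings`` (k x
    n_confounders) overrides the random factor-to-confounder map — e.g. a
    matrix with a single non-zero row makes every confounder an image of one
    factor, the setup that attenuates that factor's adjusted effect size.
    """
    factor_draws = np.asarray(factor_draws, dtype=float)
    n, k = factor_draws.shape
    if len(geography) != n:
        raise ValueError(
            f"factor_draws has {n} rows but geography has {len(geography)}"
        )
    if k != truth.k:
        raise ValueError("factor_draws incompatible with truth")
    rng = np.random.default_rng(seed)

    n_conf = len(truth.confounder_betas)
    if confounder_loadings is not None:
        A = np.asarray(confounder_loadings, dtype=float)
        if A.shape != (k, n_conf):
            raise ValueError("confounder_loadings must be k x n_confounders")
    else:
        A = rng.uniform(-0.5, 0.5, size=(k, n_conf))
    signal = factor_draws @ A
    sig_var = signal.var(axis=0, ddof=0)
    sig_var[sig_var == 0] = 1.0
    noise_var = sig_var * (1.0 - confounder_r2) / max(confounder_r2, 1e-12)
    conf = signal + rng.standard_normal((n, n_conf)) * np.sqrt(noise_var)

    states = geography["state"].to_numpy()
    counties = (geography["state"] + "_" + geography["county"]).to_numpy()
    state_levels = np.unique(states)
    county_levels = np.unique(counties)
    u_s = dict(zip(state_levels, rng.standard_normal(len(state_levels)) * truth.state_sd))
    u_c = dict(zip(county_levels, rng.standard_normal(len(county_levels)) * truth.county_sd))

    eta = (
        truth.intercept
        + factor_draws @ truth.outcome_betas
        + conf @ truth.confounder_betas
        + np.vectorize(u_s.get)(states)
        + np.vectorize(u_c.get)(counties)
        + rng.standard_normal(n) * truth.noise_sd
    )
    out = pd.DataFrame(
        {
            "GEOID": geography["GEOID"].to_numpy(),
            "state": geography["state"].to_numpy(),
            "county": geography["county"].to_numpy(),
            "prevalence": expit(eta),
        }
    )
    for j, name in enumerate(CONFOUNDER_NAMES[:n_conf]):
        out[name] = conf[:, j]
    return out


def truth_to_dict(truth: SyntheticTruth) -> dict:
    """JSON-serializable form of a SyntheticTruth."""
    return {
        "loadings": truth.loadings.tolist(),
        "factor_corr": truth.factor_corr.tolist(),
        "uniquenesses": truth.uniquenesses.tolist(),
        "outcome_betas": truth.outcome_betas.tolist(),
        "confounder_betas": truth.confounder_betas.tolist(),
        "intercept": truth.intercept,
        "state_sd": truth.state_sd,
        "county_sd": truth.county_sd,
        "noise_sd": truth.noise_sd,
        "marginal_transforms": truth.marginal_transforms,
        "missing_rate": truth.missing_rate,
        "seed": truth.seed,
    }


def truth_from_dict(d: dict) -> SyntheticTruth:
    return SyntheticTruth(
        loadings=np.asarray(d["loadings"], dtype=float),
        factor_corr=np.asarray(d["factor_corr"], dtype=float),
        uniquenesses=np.asarray(d["uniquenesses"], dtype=float),
        outcome_betas=np.asarray(d["outcome_betas"], dtype=float),
        confounder_betas=np.asarray(d["confounder_betas"], dtype=float),
        intercept=float(d["intercept"]),
        state_sd=float(d["state_sd"]),
        county_sd=float(d["county_sd"]),
        noise_sd=float(d["noise_sd"]),
        marginal_transforms=list(d["marginal_transforms"]),
        missing_rate=float(d["missing_rate"]),
        seed=int(d["seed"]),
    )
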