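# neighborfactor

Latent-factor characterization of census-tract demographics and its
association with tract-level poor-mental-health prevalence.

## The problem

Studies of neighborhood effects on mental health disagree partly because
every study measures "the neighborhood" differently. One remedy is to
reduce a wide, objective, regularly updated demographic table — tract-level
shares and means covering age, race/ethnicity, nativity, mobility,
transportation, household type, marital status, education, disability,
income, employment, residential conditions and tenure — to a handful of
latent factors, score every tract on them, and then ask how much each
factor explains of a small-area-estimated health outcome such as the
proportion of adults reporting ≥14 poor-mental-health days in 30.

This package implements that pipeline end to end for researchers working
with tract-keyed CSV tables (11-digit GEOID keys), together with a
synthetic-data generator that reproduces every awkward property of such
tables — skewed marginals, redundant complement columns, near-constant
columns, strata subgroups, sparse missingness, a state→county→tract
hierarchy — with a known ground truth, so the whole pipeline is testable
offline.

## The model

**Measurement side.** After feature selection (drop declared complements,
drop coefficient of variation < 0.06, combine strata subgroups into single
statistics), each variable is Gaussianized by the transform minimizing
|sample skewness| (identity / log / √ / logit / Yeo–Johnson), standardized,
and missing cells are filled by a weighted 10-nearest-neighbor average.
The correlation matrix R of the resulting n×p matrix is then factored by
minimum-residual extraction — ψ chosen to minimize the squared residuals of
R − ΛΛᵀ − diag(ψ), with Λ the rank-k eigen-approximation of R − diag(ψ) —
followed by direct oblimin (quartimin) rotation, giving a pattern matrix Λ
and factor correlations Φ. Factor number is guided by Kaiser's rule
(eigenvalues ≥ 1), the scree elbow, and variance explained; loading
stability by 2000 bootstrap resamples with Hungarian/Tucker-congruence
factor alignment; tract scores are Thurstone regression scores
W = R⁻¹ΛΦ.

**Outcome side.** Bivariately, a cubic smoothing spline (penalty chosen by
generalized cross-validation) of prevalence on each factor score is fitted
per state and summarized by the median and IQR of R² across states.
Multivariably, linear mixed models with random state and county-within-state
intercepts are fitted by maximum likelihood:

- R²_model = (V_null − V_model) / V_null, with V the total estimated
  variance (state + county + residual) and M_null the random-effects-only
  model;
- unique variance of factor i: R²_{a,i} − R²_a, where M_a holds the
  confounders (age, sex, race/ethnicity, poverty) and M_{a,i} adds factor i;
- Cohen's local effect size f²_i = (R²_{a,i} − R²_a) / (1 − R²_{a,i}),
  labeled small/medium/large at ≥ 0.02 / 0.15 / 0.35.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (intermediates under `scratch/study/`, summary tables under
`results/`):

```bash
python analysis/01_simulate.py          # 5000 tracts x 45 variables, known truth
python analysis/02_select_transform.py  # 45 -> 39 variables, Gaussianize, impute
python analysis/03_factor_model.py      # diagnostics, EFA, scores, bootstrap
python analysis/04_association.py       # splines + variance decomposition
python analysis/05_published_table_check.py
```

`02` reports, for example:

```
selection: 45 -> 39 variables ({'kept': 7, 'redundant': 3, 'combined_into': 3, 'low_cv': 1})
transform families chosen: {'log_shift': 10, 'sqrt': 10, 'logit': 10, 'identity': 9}
imputed 308 missing cells (0.158% of the table)
```

— the three planted complement columns were dropped as redundant, the
near-constant column failed the CV screen, the three strata subgroups were
recombined into their parent, and the fitted transform family matches the
planted skew map for every core column. `03` then prints

```
factor-number diagnostics: Kaiser count 5, scree elbow 5
5-factor model: 48.3% of variance, off-diagonal fit 0.999, RMS residual 0.0064
bootstrap x2000: max loading SE 0.014, min alignment congruence 0.998
recovery of generating loadings: per-factor Tucker congruence [0.997, 0.998, 0.999, 0.997, 0.999]
```

so the fitted pattern matrix matches the generating loadings essentially
factor-for-factor. `04` produces the Table-1-shaped decomposition on the
synthetic study; with the default generator the first factor carries the
largest coefficient and dominates:

```
notation     r2  unique_variance     f2 effect_label
      Ma 0.5291              NaN    NaN
    Ma,1 0.6601           0.1310 0.3855        large
    ...
  Ma,1:5 0.7639           0.2348 0.9948        large
```

The same stages are available as a CLI (`neighborfactor simulate | select |
transform | factor | associate | run-all`) for running on real tract CSVs.

## Layout

- `src/neighborfactor/` — library: `synth` (generator), `selection`,
  `transform` (Gaussianize + k-NN imputation), `efa` (minres/oblimin,
  scores, bootstrap), `association` (splines, mixed models, f²),
  `pipeline` (orchestration, I/O), `cli`
- `analysis/` — numbered study drivers
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
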