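# leadlasso

Risk-factor analysis of elevated childhood blood lead levels (BLLs) near
informal e-waste recycling sites: descriptive epidemiology, group-Lasso
logistic regression with cross-validated tuning, and bootstrap/permutation
stability validation, driven by a seeded synthetic-survey generator so the
whole analysis runs without access to any restricted survey data.

**Who it is for**: biostatisticians and environmental-epidemiology
analysts who need grouped variable selection on dummy-coded questionnaire
data with a dichotomized biomarker outcome, and a reproducible harness to
test how stable the selection is.

## The model

Children are surveyed in an exposed area (adjacent to e-waste recycling)
and a reference area; BLL ≥ 10 µg/dL (inclusive) defines the elevated
outcome y.  Each k-category questionnaire item is dummy-coded into a
*group* of k−1 indicators, continuous anthropometrics are singleton
groups.  With groups g = 1..G of size df_g, the group-Lasso logistic
estimator minimizes

    (1/n) Σᵢ [ log(1 + exp(ηᵢ)) − yᵢ ηᵢ ]  +  λ Σ_g √df_g ‖β_g‖₂ ,
    η = β₀ + Xβ ,

so an item's dummies enter or leave together.  Optimization is group
descent: blocks are orthonormalized and each update is an exact group
soft-threshold under a 1/4-curvature majorization of the logistic loss.
λ is chosen by 10-fold cross-validated binomial deviance (per-observation
scale); selection stability is quantified by per-group selection
frequencies over bootstrap resamples and over outcome-permuted subsamples
(a negative control) at N ∈ {150, 200, 250}.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```bash
python analysis/01_simulate_survey.py --seed 0     # writes results/survey.csv
python analysis/02_describe.py
python analysis/03_select_risk_factors.py --seed 0
python analysis/04_validate_stability.py --seed 0  # the slow one (600 tuned fits)
```

`01` draws 842 children and reports the realized margins:

```
exposed  : n= 514  median  7.01 (target 7.06)  IQR  4.62 (target 4.71)  elevated 22.37%
reference: n= 328  median  5.98 (target 5.89)  IQR  3.87 (target 3.54)  elevated 14.33%
```

`02` reproduces the descriptive battery; on this dataset the exposed-area
children have significantly higher log-BLL (t = 4.03, p = 6×10⁻⁵;
ANCOVA-adjusted area effect 0.138 on the log scale), boys exceed girls in
both areas, and the two items most associated with the elevated stratum
are the e-waste-proximity item (χ² = 40.2, p = 2×10⁻¹⁰) and sex
(χ² = 22.3, p = 2×10⁻⁶) — the two effects the generator actually planted.

`03` tunes the penalty on the 514 exposed-area complete cases
(72 design columns, 31 groups):

```
selected lambda = 0.0243, CV deviance = 0.982
active groups: ['chest_circumference_cm', 'eat_bean_products',
                'ewaste_workshop_50m', 'pica_behavior', 'sex']
  sex[girl]                 beta=-0.7078  OR=0.49
  ewaste_workshop_50m[yes]  beta=+0.9075  OR=2.48
```

The two planted effects (true ORs 0.51 and 2.28) carry the only large
coefficients; the extra groups enter with near-zero norms, the familiar
mild overselection of deviance-minimizing tuning.  The unpenalized
72-column reference fit is printed alongside with Wald odds ratios.

`04` repeats the whole tuned pipeline on 100 bootstrap and 100
outcome-permuted datasets per sample size and writes the tidy frequency
table (`results/stability_frequencies.csv`).  On this dataset the planted
groups rank top-2 by bootstrap frequency at every N — e-waste proximity
0.80 / 0.89 / 0.94 and sex 0.69 / 0.77 / 0.84 at N = 150 / 200 / 250,
with the best noise group near 0.3 — while on permuted data no frequency
exceeds 0.17 and the leading group changes with N (pure noise).

The same stages are scriptable via the `leadlasso` CLI
(`simulate`, `describe`, `fit`, `cv`, `stability`, `run`).

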