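# riskseg

Latent-class segmentation of high-risk primary-care patients, with
two-wave stability analysis.

Healthcare systems flag patients at high predicted risk of
hospitalization, but "high risk" is clinically heterogeneous: a patient
dominated by cardiometabolic disease needs a different program than one
dominated by substance use. Segmentation models — here, latent class
analysis (LCA) of binary chronic-condition indicators — split the
high-risk population into clinically interpretable groups. Because such
cohorts are re-selected every year (patients die, improve, or leave
care), any group-tailored program also needs to know how stable the
groups and the individual assignments are across waves. `riskseg` is a
pipeline for exactly this workflow, aimed at health-services researchers
and quality-improvement analysts.

## What it does

1. **Cohort selection** — patients with ≥ 1 top-decile weekly
   hospitalization-risk score in a calendar year and an active
   primary-care panel assignment; entry date = first top-decile week.
2. **Indicators** — 26 binary chronic-condition flags from coded
   encounters in a 2-year lookback from entry.
3. **Latent class model** — a mixture of products of Bernoullis,

   P(y_i) = Σ_k π_k Π_j ρ_kj^{y_ij} (1 − ρ_kj)^{1 − y_ij},

   fitted by multistart EM over a 2–7 class grid, with AIC / BIC /
   adjusted BIC / relative entropy and a manual (interpretability)
   selection override.
4. **Assignment with abstention** — patients join the modal class only
   when max_k τ_ik ≥ 50%; the rest are "unassigned". Groups are
   profiled and labeled by prevalence lift over the cohort average.
5. **Two-wave stability** — classes matched across independently fitted
   waves (optimal L1 assignment), percentage-point prevalence drift,
   four-way wave-2 status (retained high risk / improved / died / out of
   care), row-percent transition matrix, and the group switch rate among
   dual-high-risk patients.
6. **Synthetic registries** — a seeded generator emulating the whole
   registry shape (encounters, weekly risk scores, panel intervals,
   deaths) from a known 5-class truth, so every stage is testable by
   parameter and label recovery. See `docs/methods.md` for the model,
   defaults and their rationale.

## Worked example

```python
import riskseg as rs

cfg = rs.default_truth(n_patients=10_000)          # 5 classes, 26 conditions
enc, risk, panel, truth = rs.generate_wave1(cfg, seed=1)

cohort = rs.select_cohort(risk, panel, 2018)        # top-decile weeks + active panel
matrix = rs.build_indicator_matrix(enc, rs.default_condition_map(), cohort)

fit = rs.fit_em(matrix, K=5, seed=1, n_starts=10)   # Bernoulli-mixture EM
print(f"loglik={fit.loglik:.1f}  BIC={fit.bic:.1f}  entropy={fit.entropy:.3f}")

result = rs.assign_patients(fit.posteriors, threshold=0.5,
                            patient_ids=matrix.patient_ids)
print("assigned:", rs.assignment_rate(result))

profiles = rs.label_groups(rs.group_profiles(result, matrix))
for p in sorted(profiles, key=lambda p: -p.size):
    print(f"{p.label:<25} n={p.size:>5}  mean conditions {p.mean_conditions:.1f}")
```

prints

```
loglik=-119649.2  BIC=240532.6  entropy=0.764
assigned: 9,396/10,000 (94.0%)
Low Diagnosis             n= 2562  mean conditions 2.4
Mental Health             n= 2220  mean conditions 6.3
Cardiometabolic           n= 2171  mean conditions 7.3
Substance Use Disorders   n= 1459  mean conditions 6.4
High Complexity           n=  984  mean conditions 13.2
Unassigned                n=  604  mean conditions 6.2
```

All 10,000 synthetic patients survive cohort selection (by
construction each has a top-decile week and a covering panel interval);
94% clear the 50% posterior threshold, and the five recovered groups
carry the expected burden ordering — the "High Complexity" group's mean
condition count (13.2) roughly doubles the cohort average, while "Low
Diagnosis" sits at 2.4. The 6% unassigned patients are the generator's
deliberately ambiguous boundary cases plus near-threshold noise.

The same flow is available from the shell:

```bash
riskseg simulate --n 20000 --seed 17 --out sim/
riskseg build --year 2018 --encounters sim/wave1/encounters.csv \
    --risk sim/wave1/risk.csv --panel sim/wave1/panel.csv \
    --map sim/condition_map.csv --out sim/wave1/indicators.csv
riskseg fit --indicators sim/wave1/indicators.csv --k 2-7 --seed 17 --out sim/wave1/fits
riskseg select --fits sim/wave1/fits --rule manual:5
riskseg assign --fit sim/wave1/fits/k5 --indicators sim/wave1/indicators.csv --out sim/wave1/assign
riskseg compare --wave1 sim/wave1 --wave2 sim/wave2 --out cmp/
```

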