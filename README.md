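# brecansurv

Population-based survival indicators for hormone-receptor-positive breast
cancer, with endocrine-therapy (ET) adherence as a prognostic factor.

Cancer registries usually know *that* a patient died but not *why*.
`brecansurv` is for biostatisticians and cancer epidemiologists who need
cause-related prognosis anyway: it combines an all-cause Cox model fitted
to a registry cohort with a general-population life table to decompose
mortality into the part attributable to the cancer and the part expected
from background mortality, and turns that decomposition into patient-level
prediction curves — including adherent vs non-adherent comparisons that
oncologists can use when discussing five-year endocrine therapy with
patients.

## The model

For a patient profile x (age at diagnosis, stage I–III, HER2 status,
adherence class) the overall hazard is a proportional-hazards model fitted
to all-cause mortality,

    λ_O(t | x) = λ₀(t) · exp(xβ),

with λ₀ the Breslow baseline hazard. Four covariate codings are provided:
C1 (age categorical: ≤49, 50–59, 60–74, 75–84), C2 (age linear), C3 (age
as a restricted cubic spline, 3 knots at the 10/50/90th percentiles), and
C4 (C3 with the adherence coefficient split at 5 years of follow-up by
episode splitting); models are compared by AIC and the proportionality of
the adherence effect is checked with scaled Schoenfeld residuals plus a
LOWESS smooth.

The population (expected) hazard λ_P(t) is read from a life table at the
patient's attained age and calendar year. From the two cumulative hazards
the package derives, on a monthly grid up to 10 years:

* overall survival `OS(T) = exp(−Λ_O(T))`
* expected survival `ES(T) = exp(−Λ_P(T))`
* relative survival `RS(T) = OS(T)/ES(T)`
* conditional five-year relative survival `RS5(T) = RS(T+5)/RS(T)`
* excess mortality `EM(T) = (1 − RS5(T))·100` (percent)
* crude probabilities of death due to breast cancer and to other causes,
  `P_BC(T)` and `P_OC(T)`, by accumulating the interval death mass
  `OS(t)·(1 − e^{−ΔΛ_O})` split between causes in proportion to the
  excess (`ΔΛ_O − ΔΛ_P`) and population (`ΔΛ_P`) hazard increments, so
  that `OS + P_BC + P_OC = 1` holds exactly on the grid.

Because registry data of this kind cannot be redistributed, the package
ships a synthetic-cohort generator with the study population's covariate
mix and known competing excess/population hazards, used by the test suite
to validate every estimator against analytic truth.

## Worked example

```python
import brecansurv as b

cfg = b.SimulationConfig(seed=42)          # study-like cohort, n = 1268
cohort = b.simulate_cohort(cfg)
table = cfg.make_lifetable()

fit = b.fit_cox(cohort, b.DesignSpec.C3())
print(b.hazard_ratio_table(fit)[["variable", "term", "display"]])

profile = {"age": 60, "stage": "III", "her2": "neg",
           "adherence": "non_adherent", "year_dx": 2008}
curves = b.predict_profile(fit, table, profile)
print(curves.report_frame())
```

The hazard-ratio table for this seed reads (reference levels marked
`Ref`):

```
 variable         term          display
    stage            I              Ref
    stage     stage_II 1.43 (1.09-1.88)
    stage    stage_III 2.80 (2.08-3.76)
adherence non_adherent              Ref
adherence     adherent 0.66 (0.49-0.88)
```

i.e. in this simulated cohort stage III triples the all-cause death rate
and adherence reduces it by about a third. The indicator report for the
60-year-old non-adherent stage III patient ends with

```
 T  OS_pct  ES_pct  RS_pct  RS5_pct  EM_pct  P_BC_pct  P_OC_pct
 5    79.6    97.5    81.6     79.3    20.7      18.4       2.0
10    60.4    93.2    64.8      NaN     NaN      34.9       4.7
```

read as: a 60% chance of being alive ten years after diagnosis (93%
expected from population mortality alone), a 34.9% chance of dying of the
cancer and 4.7% of dying of something else; having survived five years,
her survival over the next five is 79.3% of the general population's —
a 20.7% excess risk. `RS5`/`EM` stop at T = 5 because the ten-year
horizon supports no later five-year conditionals. Running
`b.compare_adherence(fit, table, {...})` for the same profile without the
adherence key prints both arms: P_BC(10) 34.9% if non-adherent vs 23.1%
if adherent (difference 11.8 points, a 1.19-fold higher OS and a 34%
lower cancer-death risk with adherence).

The same workflow is available from a shell:

```bash
brecansurv simulate --config sim.yaml --seed 7 --out data/
brecansurv fit      --config fit.yaml --out fits/
brecansurv predict  --config predict.yaml --out pred/
brecansurv compare  --config compare.yaml --out cmp/
```

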