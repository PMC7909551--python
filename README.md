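# amikpk

Population pharmacokinetics of amikacin in elderly patients (over 70
years), from sparse therapeutic-drug-monitoring (TDM) data to a
creatinine-clearance-based initial-dose nomogram.

Amikacin is a concentration-dependent aminoglycoside with a narrow
therapeutic window: efficacy tracks the peak-to-MIC ratio
(Cmax/MIC ≥ 8 predicts clinical success) while nephrotoxicity tracks
the trough (Cmin ≥ 4 mg/L raises the risk of renal injury). Elderly
patients combine reduced renal clearance with expanded extracellular
fluid, so dosing rules derived from younger adults misfire. This
package implements the full analysis pipeline for that problem, aimed
at clinical-pharmacology researchers and PK/PD modellers:

* **`pk_model`** — exact closed-form one-compartment (and comparator
  two-compartment) concentration profiles under zero-order infusion
  input, with the renal covariate model
  `CL = CLs × (CCr / 52.9)` (Cockcroft–Gault creatinine clearance,
  mL/min, normalized to the cohort reference).
* **`cohort_sim`** — a synthetic-cohort generator emulating the study
  population: 15+ elderly subjects, peak/trough sampling around
  once-daily 200–1000 mg infusions, assay error
  SD(C) = 0.1 + 0.06·C mg/L with a 0.8 mg/L detection limit.
* **`pop_fit`** — a nonparametric adaptive-grid (NPAG) estimator: the
  population distribution of (CLs, V) is a discrete set of support
  points and probabilities maximizing the mixture likelihood
  `Σᵢ log Σⱼ wⱼ p(yᵢ|θⱼ)`, refined by expectation–maximization,
  grid condensation and shrinking local expansion; plus the
  ΔLL > 3.84 covariate-building scan and parameter summaries.
* **`diagnostics`** — visual predictive check over each subject's own
  dose history, nonparametric bootstrap, and the Pearson chi-square
  outcome association test (no continuity correction).
* **`pta`** — Monte Carlo probability of target attainment: simulated
  first-course exposures (Cmax at 1 h after infusion start, Cmin at
  30 min before the next dose) scored against Cmax/MIC ≥ 8 and
  Cmin < 4 mg/L, and fractional target attainment against an MIC
  frequency distribution.
* **`nomogram`** / **`cli`** — regimen selection per renal-function
  level (joint attainment ≥ 90%, lowest dose, then longest interval)
  and a `click` command line (`amikpk simulate-cohort | fit | vpc |
  bootstrap | pta | fta | nomogram`).

## Worked example

```python
import numpy as np
from amikpk import (
    AssayErrorModel, CovariateModel, FitOptions, ParametricPopulation,
    TDMDesign, build_nomogram, fit_summary, npag_fit, pta_table,
    simulate_tdm_cohort,
)

# 1. simulate a monitoring cohort from the published population model
pop = ParametricPopulation()   # CL 2.25 L/h (CV 34.6%), V 18.0 L (CV 18.9%)
err = AssayErrorModel()        # SD(C) = 0.1 + 0.06 C, LOD 0.8 mg/L
design = TDMDesign(n_doses=2, sample_offsets_h=(1.0, 2.0, 4.0, 8.0, 23.5, 25.0))
cohort = simulate_tdm_cohort(pop, 50, design, err, seed=1)

# 2. nonparametric adaptive-grid fit with the renal covariate
fit = npag_fit(cohort, FitOptions(seed=1), err, CovariateModel())
print(f"-2LL = {fit.minus_two_ll:.1f}, AIC = {fit.aic:.1f}, "
      f"{fit.n_support} support points")
print(fit_summary(fit).round(2))

# 3. Monte Carlo dosing simulation and nomogram at MIC 8 mg/L
grid = pta_table(fit, n=1000, seed=2)
print(build_nomogram(grid, mic=8.0).to_markdown())
```

prints

```
-2LL = 1241.3, AIC = 1245.3, 107 support points
      mean    sd  median  se  cv_pct    var  shrink_pct
CLs   2.22  0.85    2.12 NaN   38.09   0.72        0.26
V    18.40  3.27   18.25 NaN   17.75  10.67        0.44
Recommended initial regimens (MIC 8 mg/L, joint attainment >= 90%)

| Renal function | CCr (mL/min) | Recommended regimen |
| --- | --- | --- |
| Kidney failure | 10 | NA |
| Kidney failure | 20 | NA |
| Severe impairment | 30 | NA |
| Severe impairment | 40 | NA |
| Moderate impairment | 50 | 1600 mg q72h |
| Moderate impairment | 60 | 1600 mg q72h |
| Mild impairment | 70 | 1600 mg q72h |
| Mild impairment | 80 | 1600 mg q72h |
| Normal | 90 | 1800 mg q72h |
```

The fitted population mean clearance (2.22 L/h) and volume (18.40 L)
recover the generating values (2.25 L/h, 18.0 L) to within a few
percent; the nomogram reproduces the qualitative dosing pattern — no
safe-and-effective regimen below CCr ≈ 40–50 mL/min at MIC 8 mg/L, and
high-dose extended-interval regimens (1600–1800 mg every 48–72 h)
above it. Exact cell values vary with the Monte Carlo seed and with
the population representation (fitted discrete distribution vs
log-normal summary).

## Layout

```
src/amikpk/          library (pk_model, population, cohort_sim,
                     pop_fit, diagnostics, pta, nomogram, io, cli)
src/amikpk/data/     bundled synthetic example MIC distribution
tests/               pytest suite (unit, property and end-to-end)
docs/methods.md      model, algorithms, numerical choices, limitations
scripts/acceptance.py  headline-result reproduction
```
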