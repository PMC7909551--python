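# Methods

## Structural model

Amikacin disposition is modelled as a one-compartment linear system
with zero-order (constant-rate) infusion input and first-order
elimination. For an infusion at rate `R0` starting at `t0` and ending
at `t1`, the central concentration is

    C(t) = (R0/CL) (1 − e^{−ke (t − t0)})                      t0 ≤ t ≤ t1
    C(t) = (R0/CL) (1 − e^{−ke (t1 − t0)}) e^{−ke (t − t1)}     t > t1

with `ke = CL/V`; multiple doses superpose by linearity. The time
origin is the start of the first infusion; units are hours, mg, L,
mg/L throughout, with creatinine clearance in mL/min. All production
computations use these closed forms — an ODE integrator appears only
in the test suite, as an independent oracle (agreement required to
1e−6 relative). This keeps the 10⁵–10⁶ profile evaluations of the
dosing simulation exact and fast.

A two-compartment model (intercompartmental clearance `Q`, peripheral
volume `Vp`; bi-exponential closed form via the usual hybrid
rate constants) is provided strictly as a structural comparator: on
sparse peak/trough data the one-compartment model is the selected
model, and the test suite asserts the expected AIC ordering when data
are generated one-compartment.

## Covariate model

Renal function is the sole clearance covariate:

    CL_i = CLs · (CCr_i / 52.9)

where `CLs` is the clearance of a subject at the reference creatinine
clearance and `CCr_i` is the subject's Cockcroft–Gault estimate. The
reference 52.9 mL/min is the cohort mean; the cohort median
(52.1 mL/min) can be selected via `CovariateModel(reference_ccr=52.1)`
when the median-normalized convention is preferred. No covariate acts
on `V` (none was supported by the data this model derives from), and
none acts on `Q`/`Vp` in the comparator.

## Nonparametric population estimation (NPAG)

The population distribution of `(CLs, V)` is estimated as a discrete
distribution — support points `θ_j` with probabilities `w_j` —
maximizing the mixture log-likelihood `Σ_i log Σ_j w_j p(y_i | θ_j)`.
The observation model is Gaussian with the assay-error SD evaluated at
the model prediction: `SD(C) = intercept + proportional · C` (defaults
0.1 mg/L and 6%). Below-detection-limit observations are excluded from
the likelihood by default (an option includes them at LOD/2).

The adaptive-grid loop:

1. **Initial grid** — scrambled Sobol points (default 256 in 2-D, 512
   for the 4-D comparator) over `CLs ∈ [0.1, 10] L/h`,
   `V ∈ [1, 60] L`: bounds bracketing the plausible elderly range by
   more than four population SDs.
2. **Weight optimization** — mixture-weight EM to a fixed point. The
   implementation iterates on the row-normalized likelihood matrix
   (`d = A w`, `w_j ← w_j · mean_i(A_ij/d_i)`), which is monotone in
   the likelihood and reduces each iteration to two BLAS
   matrix–vector products.
3. **Condensation** — points with probability below 1e−8 of the
   maximum are dropped; near-duplicates (within 1e−3 of the box span)
   are merged probability-weighted.
4. **Expansion** — axis-aligned probes at ±δ·span around every
   surviving point (clipped to bounds), δ starting at 0.2 and halving
   whenever a full cycle gains less than the tolerance, down to 1e−3.

The loop stops when a cycle at the finest radius improves the total
log-likelihood by less than `tol` (default 0.01) or after 100 cycles.
Reported criteria: −2LL and `AIC = −2LL + 2·(structural dimensions +
estimated error parameters)`; the assay polynomial is fixed by
default, so the penalty is 2·2 for the one-compartment model and 2·4
for the comparator.

Covariate building refits the model with each candidate scaling
clearance by `value / cohort median` and admits a candidate when
−2LL improves by more than 3.84 (chi-square with 1 df at 5%) and AIC
decreases; among qualifying candidates the largest improvement wins.
Constant covariates are flagged and skipped. Because the mixture has
identical dimensionality with and without the multiplicative
covariate, the AIC condition coincides with any positive likelihood
gain; the 3.84 cut is the binding rule. Note a structural property of
nonparametric mixtures: an unmodelled covariate inflates the apparent
clearance dispersion rather than the residuals, so the likelihood gain
per subject is modest and detection power grows with cohort size and
covariate spread — the power experiments below therefore use 50
subjects.

Posterior individual parameters weight each support point by
`prior × subject likelihood`, normalized per subject. Summaries
(mean, SD, median, CV%, variance) are probability-weighted moments of
the discrete distribution; SE, when requested, comes from the
nonparametric bootstrap. Shrinkage per parameter is
`100·(1 − SD(posterior means)/SD(population))`, asserted only for its
[0, 100] range and its noise-free limit; the definition is stated here
because published tables rarely print one.

## Synthetic cohorts

`cohort_sim` emulates the statistical structure of the elderly TDM
cohort the model derives from, so every downstream stage is testable
without hospital data:

* **Covariates** drawn uniformly within the observed ranges: age
  71–95 y, weight 32.5–67.3 kg, BMI 14.9–25.6 kg/m² (height derived),
  CCr 10.9–94.9 mL/min, 60% female. Serum creatinine is back-derived
  from the drawn CCr through Cockcroft–Gault so demographics and renal
  function remain mutually consistent. Body metrics use
  IBW = 22·height² and the sex-specific Janmahasatian lean-body-weight
  formula.
* **Dosing** — once daily by default, 200–1000 mg (100 mg steps),
  infused over 0.5 h (probability 2/3) or 1 h (1/3), matching the
  observed mean infusion time of 0.67 h.
* **Sampling** — a peak 1 h after the start of the first infusion and
  a trough 30 min before the next dose; a third sample (second-day
  peak) in 20% of subjects, reproducing the 33-observations-from-15-
  subjects bookkeeping. Fixed `sample_offsets_h` override this rule
  for rich-design experiments.
* **Parameters** — `(CLs, V)` log-normal with mean/CV
  (2.25 L/h, 34.6%) and (18.0 L, 18.9%), truncated to [0.1×, 10×] the
  mean by resampling; a truncated-normal family is selectable.
  Between-subject variability sits on `CLs` and is then scaled by
  `CCr/52.9`, matching the covariate placement of the final model. The
  log-normal is a stand-in for the unpublished nonparametric joint
  distribution: it matches the printed mean and CV and guarantees
  positivity, but it is unimodal and independent across parameters,
  which real nonparametric fits need not be.
* **Noise** — `N(0, SD(C)²)` with the assay polynomial; negative
  results are resampled (truncation); values below the 0.8 mg/L limit
  of detection are flagged and stored at LOD/2, a common convention
  for left-censored assay data.

What passing tests on these cohorts do **not** show: robustness to
covariate measurement error, non-uniform covariate distributions,
model misspecification (true two-compartment kinetics), or informative
sampling times — none of which the generator emulates.

## Model evaluation

The **visual predictive check** follows each subject's own dose
history (no time-after-dose binning): `n_sim` virtual subjects per
real subject are drawn from the population distribution, scaled by the
subject's CCr, pushed through the subject's dose schedule and
observation times, and perturbed with assay noise. The 5/25/50/75/95
percentile bands are computed per observation time; the summary is the
proportion of (non-censored) observations inside the 5th–95th band,
with ≥ 90% the a priori acceptance target. On self-simulated data the
statistic is centred slightly above 0.90 (clipping at zero and
censoring below the LOD both trim the lower tail); the coverage test
uses 300 subjects because observations within a subject share one
parameter draw, making the effective sample size the subject count.

The **bootstrap** resamples subjects with replacement, refits, and
reports per-parameter bootstrap mean, SE (SD of replicate means) and
2.5/97.5 percentile limits; non-converging replicates are dropped and
counted.

The **outcome association test** is the Pearson chi-square on a 2×2
table, 1 df, without continuity correction — the convention verified
to reproduce the published attainment-vs-outcome p-values (0.1368 and
0.0440); with Yates correction it does not.

## Dosing simulation

`simulate_exposures` draws `n` virtual subjects (default 1000 per
cell) at a fixed CCr and evaluates closed-form first-course exposures:
Cmax 1 h after the start of a 30-min infusion and Cmin 30 min before
the second dose (23.5, 47.5 or 71.5 h for q24/q48/q72) — initial-dose
framing, not steady state. Targets: efficacy `Cmax/MIC ≥ 8`, safety
`Cmin < 4 mg/L` (strict inequality by default; `≤` selectable — the
distinction is immaterial for continuous simulation), and the joint
target requires both on the same draw. The grid spans doses
200–2000 mg (step 200), intervals 24/48/72 h and CCr 10–90 mL/min
(step 10); each cell has an independent stream spawned deterministically
from the base seed.

**Fractional target attainment** weights the joint attainment by an
MIC frequency distribution supplied as CSV/JSON (never fetched from a
network resource). The bundled `data/synthetic_pa_mic.csv` is a
synthetic wild-type-like example for tests and demos, not surveillance
data; published FTA values depend on the surveillance snapshot used
and are not reproducible from it.

**Nomogram** selection per CCr level: among regimens with joint
attainment ≥ 90% (optionally also FTA ≥ 85%), choose the lowest dose,
then the longest interval — encoding the extended-interval
aminoglycoside rationale (high peaks for efficacy, long drug-free
troughs for safety, supported by the post-antibiotic effect).

## Numerical and design choices

* Degenerate inputs: non-positive parameters raise domain errors;
  subjects with all observations censored contribute zero
  log-likelihood; a subject with no finite-likelihood grid point
  aborts the fit with a diagnostic naming the subject.
* EM warm starts: after each expansion the previous weights carry over
  with mass 1e−6 assigned to the new candidates, so the cycle-level
  log-likelihood is non-decreasing (asserted in tests).
* Ties in nomogram selection are impossible after the
  lowest-dose/longest-interval ordering because (dose, interval) pairs
  are unique per cell.
* Problem sizes in the test suite and the reproduction script —
  50-subject cohorts with 6 samples for recovery (20 replicates),
  50-subject cohorts for covariate-scan power, 300 subjects for VPC
  coverage, 1000 virtual subjects per simulation cell — were chosen so
  that Monte Carlo error is small against the tolerance being checked,
  as discussed above.

## Known limitations

* The nonparametric fit estimates the population distribution only at
  the covariate structure given; it does not estimate assay-error
  parameters by default (an error-scale flag exists but is off).
* First-course troughs understate steady-state troughs for q24h
  regimens in renally impaired patients; the initial-dose framing is
  deliberate but should not be read as maintenance-dose advice.
* No handling of renal replacement therapy, nonlinear elimination or
  absorption; no interoccasion variability; no AUC/MIC targets.
* The discrete fitted distribution can concentrate on few support
  points for small cohorts; bootstrap SEs are then more informative
  than the point summaries.
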