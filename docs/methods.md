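# Methods

This note documents the statistical model behind `phptfrac`, what the
synthetic-data generator does and does not emulate, the numerical choices
made, and the package's known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis model

**Outcomes.** Follow-up is a single spell per patient from the cohort index
date (surgery date for treated patients, diagnosis for the rest) to the
first of: fracture (with a site), death, or loss to follow-up. Three
outcome definitions map sites to the event of interest: `mof` (hip, spine,
distal forearm, proximal humerus), `hip`, and `all` (any recorded site).
Death is always the competing event. A fracture at a site outside the
outcome definition ends the spell; because continued observation past it
does not exist in single-spell data, it is treated as censoring. Under the
generator's site-marking scheme (independent marks on the fracture process)
this censoring is independent, so the estimator below remains consistent;
in real coded data this is an approximation worth keeping in mind.

**Cumulative incidence.** The Aalen-Johansen product-limit transition
estimator gives the cause-specific CIF on the exact event-time grid (no
binning), with the counting-process delta-method variance
(Marubini-Valsecchi form), accumulated with running sums so the cost is
linear in the number of distinct times. Tie rule: at equal times, events
are processed before censorings and fracture before death. The estimator
enforces `CIF_event + CIF_death + S = 1` at every time to 1e-10.

**Calibration.** Patients are ranked by score with a stable sort (boundary
patients fall in the lower decile) and cut into ten equal-count groups.
Observed risk per decile is the AJ CIF at the 10-year horizon (carrying the
last value forward, flagged, when follow-up ends earlier); its 95% CI is a
normal approximation on the AJ variance truncated to [0, 100]. The
calibration line is unweighted OLS of observed on estimated over the ten
points — the simplest reading of a least-squares calibration summary;
weighting would move the line only through the extreme deciles. The
parental-history sensitivity analysis re-scores and re-stratifies each of
100 imputed resamples (unknown history set positive with 10% prevalence)
and fits the line to the across-resample mean observed and estimated risks
per decile.

**Discrimination.** Cumulative/dynamic time-dependent AUROC: cases at time
t are subjects with the qualifying fracture by t; controls are subjects
event-free beyond t. Censoring is corrected with IPCW weights from the
reverse Kaplan-Meier estimate of the censoring distribution pooled over
treatment arms (cases weighted 1/G(T−), controls 1/G(t)). Subjects dead by
t without the fracture are non-cases excluded from the control set by
default; `competing="control"` retains them as controls (weighted at their
death time) for sensitivity, since either convention is defensible.
Standard errors come from the estimated influence function of the weighted
two-sample statistic; the contribution of estimating G is ignored, the
usual first-order simplification. The simulation suite checks that the
resulting SE matches the across-replicate SD of the estimator within 20%.

**Treatment-effect model.** A logistic propensity model on the
surgical-selection covariates (age, sex, race and ethnicity, inclusion
decade, BMI, alcohol, smoking, rheumatoid arthritis, osteopenia,
osteoporosis, secondary osteoporosis, fracture history, glucocorticoids,
antiosteoporosis medication, CKD, kidney stones, peak calcium band) yields
ATE-style IPTW weights. The package default is **stabilized** weights
truncated at the 1st/99th weight percentiles: stabilization and mild
truncation keep the weight distribution tight enough that the
information-matrix covariance of the weighted Poisson fit — the object the
delta-method confidence bands are built from — remains a usable variance
estimate, which the parameter-recovery simulations confirm (the reported
SEs match the replicate SD and 2-SE coverage is nominal). Raw unstabilized
weights and a sandwich covariance are available behind flags. Balance is
declared at all weighted |SMD| < 0.1, computed with the identical formula
(weighted means and variances) as the unweighted SMD.

Follow-up is expanded into person-periods of 0.5 years (default): exposure
is conserved exactly, the time covariate is the midpoint of the exposed
part of each interval, and only a spell's final row can carry an event.
Halving or doubling the interval moves the treatment coefficient by less
than 0.01 at the default scenario (tested). The weighted Poisson model
with log-exposure offset has exactly the six-term linear predictor
(intercept, t, age, score, PTX, score×PTX); age is baseline age, constant
across a subject's rows — the same convention the generator uses, which is
what parameter-recovery requires. Scores enter in percent, so β₅ is per
percentage point. Competing death ends exposure without an event
(cause-specific hazard). HR curves, thresholds (smallest grid score above
which the upper 95% bound stays below 1) and the Wald interaction test
follow from (β, Σ) as described in the README. Four fits are produced per
run: MOF and hip outcomes against their own scores, and the all-fracture
outcome against both scores.

## The synthetic-data generator

The generator is the package's study population, not a test fixture. Its
defaults encode the baseline characteristics of a published ~59k-patient US
PHPT cohort: 75.2% female, 25.0% PTX, the published race/ethnicity,
inclusion-decade, calcium-band and comorbidity proportions, age 65.9 ± 10.8
truncated to [40, 90] (the risk calculator's accepted range), BMI
30.3 ± 7.2, and parental hip-fracture history entirely unknown (as in EHR
extracts), which the sensitivity resampler imputes.

* **Scores.** The surrogate calculator is an explicit two-cause model:
  constant cause-specific fracture hazards log-linear in age, sex, the
  classic clinical factors, and BMI below 25; Gompertz mortality in
  attained age with male and smoking effects. The 10-year probability is
  the CIF integral evaluated by fixed-step trapezoid (0.05 y); the
  mortality integral is closed-form, so quadrature error is tiny (halving
  the step moves scores by < 0.01 pp, tested). Intercepts are calibrated
  once so the population median scores are ≈ 6.4% (MOF) and ≈ 1.0% (hip),
  the scale on which published benefit thresholds are expressed. Hip has
  the steeper age slope and stronger smoking/parental/low-BMI effects, the
  familiar epidemiologic pattern. There is deliberately no BMD input.
* **Treatment.** PTX is assigned by a logistic model on age, CKD, Black
  race, osteoporosis, osteopenia, kidney stones and high calcium, with the
  intercept solved so the marginal PTX fraction matches 25%. This
  reproduces the qualitative selection pattern of the source population
  (younger, less CKD, more bone disease among the operated) and guarantees
  pre-weighting imbalance (|SMD| > 0.1 on age and CKD), so the IPTW stage
  is non-trivially exercised.
* **Event times.** In the default (`score_linear`) mode the all-fracture
  hazard is exp(β₀ + β₁t + β₂·age + β₃·F + β₄·PTX + β₅·F·PTX) with F the
  engine's MOF score — the same functional form the analysis fits, which is
  what makes parameter recovery a meaningful check. Because the log hazard
  is linear in t, the cumulative hazard is elementary and event times are
  drawn by exact analytic inversion (no discretization). Death is Gompertz
  (baseline log-rate −4.2 at 65, slope 0.09/y); loss to follow-up is
  exponential (0.22/y, calibrated once so median observed follow-up is
  ≈ 2.7 y) with a 24-year administrative cap. Defaults give ≈ 8% 10-year
  MOF cumulative incidence and HR(PTX) ≈ 0.88 at the median score — a
  plausible scenario, not a reproduction of any published estimate.
  Fracture sites are multinomial marks (hip .25, spine .30, forearm .15,
  humerus .10, other .20), so MOF sites carry 80% of fracture mass.
* **Engine mode.** With `hazard_model="engine"` the fracture and death
  hazards are taken directly from the surrogate (no treatment effect), so
  each patient's score *is* their true cumulative incidence; hip marks get
  probability proportional to the patient's hip hazard. This is the
  oracle regime in which decile calibration must approach the identity
  line and the AUC equals its pair-counting value — the self-consistency
  tests of the whole validation arm.

What the generator does **not** emulate: ICD coding noise, multi-site care
fragmentation, time-varying treatment (late surgery in the nonsurgical
arm), the ~0.3-year diagnosis-to-surgery gap, recurrent fractures within a
spell, or dependence of loss to follow-up on covariates. Passing tests
therefore demonstrate that the estimators are correct under the stated
sampling model, not that the pipeline is robust to those real-data
pathologies.

## Problem sizes and numerical choices

* Parameter recovery: 100 replicates at n = 50 000 through the full IPTW
  pipeline; β₄ and β₅ must land within 2 reported SEs of truth in ≥ 90.
  The interaction test's type-I error is checked on 500 replicates at
  n = 5 000 (unweighted fits — the Wald calibration question does not need
  the weighting machinery), requiring a rejection rate in [3%, 8%].
* The delta-method bands are validated against a 2 000-draw parametric
  bootstrap from (β, Σ) at a covariance scale typical of a ~60k-patient
  fit (σ(log HR) ≈ 0.03–0.045), where the bootstrap's own quantile noise
  is well inside the 0.005 comparison band.
* Poisson fits converge by IRLS to a relative log-likelihood change
  < 1e-10 (failure raises with the gradient norm); zero-event tables and
  propensity separation raise named errors, with single-covariate complete
  separation diagnosed explicitly.
* Degenerate inputs: n = 0 yields empty tables; β₀ = −∞ is the documented
  "no fracture hazard" case; all-identical scores make deciles undefined
  and raise; evaluation of a CIF beyond the last observed time carries the
  last value forward with an explicit truncation flag.
* Determinism: every random draw flows from one `numpy` Generator seeded
  by the config; identical configs give byte-identical outputs, and the
  run manifest records the config hash and per-file checksums.

## Limitations

The surrogate calculator shares risk-factor directions, not coefficients,
with any clinical tool, so absolute score levels are scenario-specific;
calibration and threshold values computed on synthetic cohorts characterize
the machinery, not any real population. Hip-specific event counts are small
at the default scenario, so hip HR curves are wide and the detected hip
threshold is often absent at n = 50 000. The influence-function SE omits
the censoring-estimation term; with heavy censoring at late horizons it can
be mildly conservative or anticonservative, which is why the simulation
check bounds the SD/SE ratio rather than assuming exactness. The
incident-fracture filter is a documented, configurable stand-in (365-day
site-specific washout) for claims-based algorithms whose exact parameters
vary; real deployments should tune it against chart review.
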