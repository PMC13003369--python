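# phptfrac

Fracture-risk validation and surgical-benefit stratification for primary
hyperparathyroidism (PHPT) cohorts.

PHPT causes progressive bone loss and pathologic fracture; parathyroidectomy
(PTX) is its only durable cure. `phptfrac` implements, as a tested and
reusable pipeline, the analysis needed to answer two questions on a
patient-level cohort with clinical risk factors, treatment, follow-up and
10-year fracture-probability scores (FRAX-type, computed without bone
mineral density):

1. **Validation** — do the 10-year major-osteoporotic-fracture (MOF) and hip
   scores calibrate against observed incidence, and do they discriminate?
   Observed probabilities come from the Aalen-Johansen estimator of the
   cause-specific cumulative incidence function (CIF) with death as a
   competing risk; calibration is summarised by a least-squares line through
   the ten decile points (ideal slope 1, intercept 0); discrimination by the
   cumulative/dynamic time-dependent AUROC with inverse-probability-of-
   censoring weights and influence-function confidence intervals.
2. **Benefit stratification** — how does the PTX-vs-nonsurgical hazard ratio
   vary with a patient's score, and above which score is PTX consistently
   associated with reduced fracture risk? After balancing surgical-selection
   confounders by inverse-probability-of-treatment weighting (IPTW,
   standardized mean differences < 0.1), a weighted Poisson regression on a
   person-period expansion estimates the cause-specific fracture hazard

   ```
   h(t) = exp(β₀ + β₁·t + β₂·age + β₃·F + β₄·PTX + β₅·F·PTX)
   ```

   with `F` the 10-year score in percent and `t` years since index. The
   treatment association is the curve HR(F) = exp(β₄ + β₅·F) with
   delta-method 95% bands from the weighted-model covariance; the **benefit
   threshold** is the smallest score above which the upper band stays below
   1, and β₅/√V₅₅ is the Wald test of effect modification by score.

Because real PHPT extracts of this kind live in protected EHR networks, the
package ships a first-class synthetic-cohort generator (`phptfrac.cohort`)
whose defaults emulate a published 59 194-patient US PHPT cohort: covariate
marginals, confounded treatment assignment (25% PTX, younger and less
comorbid), cause-specific fracture and Gompertz death hazards of exactly the
model form above, and loss to follow-up giving a median follow-up of
≈ 2.7 years. Scores come from a transparent surrogate calculator
(`phptfrac.risk`) — an explicit two-cause competing-hazard model over the
classic clinical risk factors; it makes no attempt to reproduce any
proprietary calculator numerically.

## Worked example

```python
from phptfrac import (SimulationConfig, generate_cohort, decile_calibration,
                      td_auroc, fit_propensity, person_time_expand,
                      fit_poisson_hazard, hr_curve, interaction_test)
import pandas as pd, numpy as np

cohort, fu = generate_cohort(SimulationConfig(n=50_000, seed=1))
scores = pd.Series(cohort.mof_pct.to_numpy(), index=cohort.patient_id)

cal = decile_calibration(scores, fu, "mof")
print(f"calibration slope {cal.slope:.2f}, intercept {cal.intercept:.1f} pp")
print(f"AUROC(10y) {td_auroc(scores, fu, 'mof', [10.0]).auc[0]:.3f}")

prop = fit_propensity(cohort)           # IPTW: all weighted |SMD| < 0.1
pp = person_time_expand(fu, 0.5, "mof").join(
    cohort.set_index("patient_id")[["age", "mof_pct", "ptx"]], on="patient_id")
fit = fit_poisson_hazard(pp, pd.Series(prop.weights, index=cohort.patient_id))
curve = hr_curve(fit, np.arange(0, 20.1, 0.1))
print(f"HR at median score {curve.hr[64]:.2f}, threshold {curve.threshold}")
print(f"interaction p = {interaction_test(fit).p:.2f}")
```

prints (seed 1):

```
calibration slope 0.83, intercept 2.1 pp
AUROC(10y) 0.666
HR at median score 0.93, threshold 7.7
interaction p = 0.06
```

The slope below 1 with a positive intercept says observed MOF incidence runs
slightly above the surrogate's estimates in every decile under the default
scenario; the AUROC of ≈ 0.67 is the discrimination the scores achieve on
this synthetic population; the HR curve says PTX is associated with reduced
MOF hazard, consistently (upper confidence bound below 1) above a MOF score
of 7.7% in this particular draw; and the interaction test does not reject
constancy of the effect on the log scale.

The same pipeline runs from the shell:

```sh
phptfrac all --outdir run/            # simulate → … → report + manifest
phptfrac simulate --n 10000 --seed 7 --outdir run2/
phptfrac calibrate --outdir run2/ --outcome mof
```

Every run writes a manifest (config hash, seed, row counts, file checksums),
and identical configs reproduce byte-identical outputs.

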