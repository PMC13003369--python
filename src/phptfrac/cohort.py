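"""Seeded synthetic PHPT cohort generator.

Draws patient covariates from the configured marginals, scores them with
the risk engine, assigns parathyroidectomy (PTX) through a confounded
logistic selection model, and simulates competing event times:

* fracture — cause-specific hazard either log-linear in (t, age, MOF
  score, PTX, score x PTX) with analytic inversion of the cumulative
  hazard, or taken directly from the risk engine's surrogate hazards
  ("engine" mode, used for calibration self-consistency checks);
* death — Gompertz hazard in attained age, analytic inversion;
* loss to follow-up — exponential, plus an administrative cap.

Observed follow-up is the earliest of the three, with event codes
0 = censored, 1 = fracture, 2 = death.  Fracture sites are multinomial
marks; in engine mode the hip mark probability is proportional to the
patient's hip hazard so hip-specific incidence is also self-consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .config import SimulationConfig
from .risk import (
    SurrogateModel,
    default_surrogate,
    fracture_hazards,
    mortality_hazard_parts,
    score_cohort,
)

__all__ = ["generate_cohort", "EVENT_CENSORED", "EVENT_FRACTURE", "EVENT_DEATH"]

EVENT_CENSORED = 0
EVENT_FRACTURE = 1
EVENT_DEATH = 2

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "race_ethnicity", "height", "weight", "bmi",
    "prior_fracture", "parental_hip_fracture", "current_smoking",
    "glucocorticoid_use", "rheumatoid_arthritis", "secondary_osteoporosis",
    "alcohol_excess", "osteopenia", "osteoporosis", "ckd_stage3plus",
    "kidney_stones", "highest_calcium_band", "antiosteoporosis_med",
    "inclusion_period", "ptx", "mof_pct", "hip_pct",
]

FOLLOWUP_COLUMNS = ["patient_id", "time", "event", "fracture_site"]


def _trunc_normal(rng, spec, size):
    a = (spec["lo"] - spec["mean"]) / spec["sd"]
    b = (spec["hi"] - spec["mean"]) / spec["sd"]
    return truncnorm.rvs(a, b, loc=spec["mean"], scale=spec["sd"], size=size,
                         random_state=rng)


def _draw_categorical(rng, table, size):
    levels = list(table.keys())
    probs = np.asarray([table[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=size, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def _selection_design(cohort: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Linear predictor of the treatment-selection model (no intercept).

    Keys are plain column names for booleans / continuous fields ("age" is
    centred at 65) or ``column=level`` for one categorical level.
    """
    lp = np.zeros(len(cohort))
    for key, beta in coefs.items():
        if "=" in key:
            col, level = key.split("=", 1)
            x = (cohort[col].astype(str) == level).to_numpy(dtype=float)
        elif key == "age":
            x = cohort["age"].to_numpy(dtype=float) - 65.0
        else:
            x = cohort[key].to_numpy(dtype=float)
        lp += beta * x
    return lp


def _assign_treatment(rng, cohort, coefs, p_target):
    if p_target <= 0.0:
        return np.zeros(len(cohort), dtype=bool)
    if p_target >= 1.0:
        return np.ones(len(cohort), dtype=bool)
    lp = _selection_design(cohort, coefs)
    # intercept solved so the realised marginal PTX fraction matches the
    # configured marginal in expectation
    c0 = brentq(lambda c: expit(c + lp).mean() - p_target, -30.0, 30.0)
    return rng.random(len(cohort)) < expit(c0 + lp)


def _invert_loglinear(rng, lam0: np.ndarray, slope: float, size: int) -> np.ndarray:
    """Event times for hazard lam0 * exp(slope * t) by inverse transform.

    Cumulative hazard H(t) = lam0 (e^{slope t} - 1)/slope is elementary, so
    T = log1p(slope * E / lam0) / slope with E ~ Exp(1); patients whose
    exhausted cumulative hazard never reaches E never fail (T = inf).
    """
    e = rng.exponential(size=size)
    t = np.full(size, np.inf)
    pos = lam0 > 0
    if slope == 0.0:
        t[pos] = e[pos] / lam0[pos]
        return t
    arg = slope * e[pos] / lam0[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        ti = np.log1p(arg) / slope
    ti[arg <= -1.0] = np.inf  # negative slope: hazard exhausted
    t[pos] = ti
    return t


def generate_cohort(
    config: SimulationConfig,
    model: SurrogateModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one seeded cohort: (patients, follow-up) DataFrames.

    Deterministic given ``config.seed``.  The returned cohort frame carries
    the risk-engine scores (``mof_pct``, ``hip_pct``) used inside the
    fracture hazard, so downstream stages see exactly the scores the data
    were generated under.
    """
    config.validate()
    model = model or default_surrogate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return (
            pd.DataFrame(columns=COHORT_COLUMNS),
            pd.DataFrame(columns=FOLLOWUP_COLUMNS),
        )

    cont = config.continuous_marginals
    marg = config.covariate_marginals

    cohort = pd.DataFrame({"patient_id": [f"P{i:07d}" for i in range(n)]})
    cohort["age"] = _trunc_normal(rng, cont["age"], n)
    for name, table in marg.items():
        if name == "ptx":
            continue
        values = list(table.keys())
        if set(values) == {True, False}:
            cohort[name] = rng.random(n) < table[True]
        else:
            cohort[name] = _draw_categorical(rng, table, n)
    female = cohort["sex"].to_numpy() == "female"
    height = np.where(
        female,
        _trunc_normal(rng, cont["height_female"], n),
        _trunc_normal(rng, cont["height_male"], n),
    )
    bmi = _trunc_normal(rng, cont["bmi"], n)
    cohort["height"] = np.round(height, 1)
    cohort["bmi"] = bmi
    cohort["weight"] = bmi * (cohort["height"] / 100.0) ** 2

    scores = score_cohort(cohort, model)
    cohort["mof_pct"] = scores["mof_pct"].to_numpy()
    cohort["hip_pct"] = scores["hip_pct"].to_numpy()

    p_ptx = marg.get("ptx", {True: 0.25, False: 0.75})[True]
    cohort["ptx"] = _assign_treatment(rng, cohort, config.selection_coefs, p_ptx)

    # --- event-time simulation -------------------------------------------
    age = cohort["age"].to_numpy(dtype=float)
    ptx = cohort["ptx"].to_numpy(dtype=float)

    if config.hazard_model == "score_linear":
        b0, b1, b2, b3, b4, b5 = config.hazard_coefs
        score = cohort["mof_pct"].to_numpy(dtype=float)
        lp = b0 + b2 * age + b3 * score + b4 * ptx + b5 * score * ptx
        lam0 = np.exp(lp)
        if not np.all(np.isfinite(lam0)):
            i = int(np.argmax(~np.isfinite(lam0)))
            terms = {
                "beta0": b0, "beta2*age": b2 * age[i],
                "beta3*score": b3 * score[i], "beta4*ptx": b4 * ptx[i],
                "beta5*score*ptx": b5 * score[i] * ptx[i],
            }
            worst = max(terms, key=lambda k: abs(terms[k]))
            raise ValueError(
                f"non-finite fracture hazard for patient {i}: dominant term {worst}"
            )
        t_frac = _invert_loglinear(rng, lam0, b1, n)
        d0, d1 = config.death_hazard_coefs
        lam_d0 = np.exp(d0 + d1 * (age - 65.0))
        t_death = _invert_loglinear(rng, lam_d0, d1, n)
        site_levels = list(config.site_probs.keys())
        site_p = np.tile(
            np.asarray([config.site_probs[s] for s in site_levels]), (n, 1)
        )
    else:  # engine mode: hazards shared with the risk engine
        h_mof, h_hip = fracture_hazards(cohort, model)
        h_hip = np.minimum(h_hip, 0.95 * h_mof)
        h_total = 1.25 * h_mof  # non-MOF "other" sites add 25% of MOF hazard
        t_frac = _invert_loglinear(rng, h_total, 0.0, n)
        hd0, g = mortality_hazard_parts(cohort, model)
        t_death = _invert_loglinear(rng, hd0, g, n)
        p_hip = h_hip / h_total
        p_other = np.full(n, 0.2)
        rest = 1.0 - p_hip - p_other  # spine + forearm + humerus
        site_levels = ["hip", "spine", "forearm", "humerus", "other"]
        w = np.asarray([0.30, 0.15, 0.10]) / 0.55
        site_p = np.column_stack(
            [p_hip, rest * w[0], rest * w[1], rest * w[2], p_other]
        )

    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_censor_years)

    time = np.minimum(np.minimum(t_frac, t_death), t_cens)
    # ties (measure-zero for continuous draws): fracture beats death beats
    # censoring, the conventional ordering
    event = np.where(
        t_frac <= time, EVENT_FRACTURE, np.where(t_death <= time, EVENT_DEATH, EVENT_CENSORED)
    )
    time = np.maximum(time, 1e-9)

    u = rng.random(n)
    cum = np.cumsum(site_p, axis=1)
    site_idx = (u[:, None] > cum).sum(axis=1)
    sites = np.asarray(site_levels, dtype=object)[np.minimum(site_idx, len(site_levels) - 1)]
    sites = np.where(event == EVENT_FRACTURE, sites, "none")

    followup = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "time": time,
            "event": event.astype(int),
            "fracture_site": sites,
        }
    )
    return cohort[COHORT_COLUMNS], followup
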