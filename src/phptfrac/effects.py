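"""Treatment-effect stratification: IPTW Poisson hazard model.

The association of parathyroidectomy (PTX) with fracture is estimated in
a pseudo-population balanced by inverse-probability-of-treatment
weighting (IPTW), fitting the piecewise-exponential Poisson model

    h(t) = exp(b0 + b1*t + b2*age + b3*score + b4*ptx + b5*score*ptx)

on a person-period expansion of follow-up, with a log-exposure offset.
The score is a 10-year fracture probability in percent, so b5 has units
per percentage point.  Hazard-ratio curves HR(F) = exp(b4 + b5*F) carry
delta-method 95% bands from the weighted-model covariance, and the
benefit threshold is the smallest score above which the upper band stays
below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import EVENT_DEATH, EVENT_FRACTURE
from .incidence import outcome_sites

__all__ = [
    "PropensityResult",
    "HazardFit",
    "HRCurve",
    "fit_propensity",
    "person_time_expand",
    "fit_poisson_hazard",
    "hr_curve",
    "find_threshold",
    "interaction_test",
    "standardized_mean_difference",
    "PROPENSITY_COVARIATES",
]

#: surgical-selection covariates entering the propensity model
PROPENSITY_COVARIATES = [
    "age", "sex", "race_ethnicity", "inclusion_period", "bmi",
    "alcohol_excess", "current_smoking", "rheumatoid_arthritis",
    "osteopenia", "osteoporosis", "secondary_osteoporosis",
    "prior_fracture", "glucocorticoid_use", "antiosteoporosis_med",
    "ckd_stage3plus", "kidney_stones", "highest_calcium_band",
]

_CATEGORICAL = {"sex", "race_ethnicity", "inclusion_period", "highest_calcium_band"}


@dataclass
class PropensityResult:
    propensity: np.ndarray       # per patient, P(ptx | x)
    weights: np.ndarray          # per patient IPTW weight
    smd_table: pd.DataFrame      # covariate, smd_unweighted, smd_weighted
    balanced: bool               # all weighted |SMD| < 0.1


@dataclass
class HazardFit:
    beta: np.ndarray             # (b0..b5)
    covariance: np.ndarray       # 6x6
    n_intervals: int
    loglik: float
    term_names: tuple[str, ...] = (
        "intercept", "t", "age", "score", "ptx", "score_ptx"
    )


@dataclass
class HRCurve:
    score_grid: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    threshold: float | None


class InteractionTest(NamedTuple):
    hr_per_unit: float
    ci_low: float
    ci_high: float
    p: float


def _design(cohort: pd.DataFrame, covariates=None) -> pd.DataFrame:
    covariates = covariates or PROPENSITY_COVARIATES
    cols = {}
    for name in covariates:
        s = cohort[name]
        if name in _CATEGORICAL:
            levels = sorted(s.astype(str).unique())
            for lv in levels[1:]:  # first level is the reference
                cols[f"{name}={lv}"] = (s.astype(str) == lv).to_numpy(dtype=float)
        elif s.dtype == bool or s.dtype == object:
            cols[name] = s.to_numpy(dtype=float)
        else:
            cols[name] = s.to_numpy(dtype=float)
    return pd.DataFrame(cols)


def standardized_mean_difference(
    x: np.ndarray, treated: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """SMD = (mean_t - mean_c) / sqrt((var_t + var_c)/2), optionally weighted.

    The weighted version applies the same formula with weighted means and
    variances, so unweighted and weighted SMDs are directly comparable.
    """
    if weights is None:
        weights = np.ones(len(x))
    xt, wt = x[treated], weights[treated]
    xc, wc = x[~treated], weights[~treated]
    mt = np.average(xt, weights=wt)
    mc = np.average(xc, weights=wc)
    vt = np.average((xt - mt) ** 2, weights=wt)
    vc = np.average((xc - mc) ** 2, weights=wc)
    pooled = np.sqrt((vt + vc) / 2.0)
    if pooled == 0:
        return 0.0
    return float((mt - mc) / pooled)


def fit_propensity(
    cohort: pd.DataFrame,
    covariates=None,
    stabilized: bool = True,
    truncate: tuple[float, float] | None = (0.01, 0.99),
) -> PropensityResult:
    """Logistic propensity model for PTX and ATE-style IPTW weights.

    Weights default to stabilized form (marginal treatment probability in
    the numerator) truncated at the 1st/99th weight percentiles; pass
    ``stabilized=False, truncate=None`` for raw 1/p weights.  Emits a
    balance warning if any weighted |SMD| >= 0.1.
    """
    z = cohort["ptx"].to_numpy(dtype=bool)
    if z.all() or not z.any():
        raise ValueError("cohort must contain both treated and untreated subjects")
    X = _design(cohort, covariates)

    def _diagnose_separation() -> None:
        # name the single covariate with non-overlapping supports, if any
        for col in X.columns:
            x = X[col].to_numpy()
            if x[z].min() > x[~z].max() or x[~z].min() > x[z].max():
                raise ValueError(f"perfect separation on covariate {col!r}")
        raise ValueError("propensity model did not converge (quasi-separation)")

    exog = sm.add_constant(X.to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(z.astype(float), exog, family=sm.families.Binomial()).fit(
                maxiter=100
            )
    except Exception:
        _diagnose_separation()
        raise
    p = np.asarray(res.predict(exog))
    eps = 1e-10
    if np.any(p < eps) or np.any(p > 1 - eps) or not res.converged:
        _diagnose_separation()

    if stabilized:
        pbar = z.mean()
        w = np.where(z, pbar / p, (1.0 - pbar) / (1.0 - p))
    else:
        w = np.where(z, 1.0 / p, 1.0 / (1.0 - p))
    if truncate is not None:
        lo, hi = np.quantile(w, truncate)
        w = np.clip(w, lo, hi)

    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        rows.append(
            {
                "covariate": col,
                "smd_unweighted": standardized_mean_difference(x, z),
                "smd_weighted": standardized_mean_difference(x, z, w),
            }
        )
    smd = pd.DataFrame(rows)
    balanced = bool((smd["smd_weighted"].abs() < 0.1).all())
    if not balanced:
        worst = smd.loc[smd["smd_weighted"].abs().idxmax()]
        warnings.warn(
            f"IPTW balance not achieved: |SMD|={abs(worst['smd_weighted']):.3f} "
            f"for {worst['covariate']}",
            stacklevel=2,
        )
    return PropensityResult(propensity=p, weights=w, smd_table=smd, balanced=balanced)


def person_time_expand(
    followups: pd.DataFrame,
    interval_years: float = 0.5,
    outcome_def: str = "all",
) -> pd.DataFrame:
    """Split each follow-up spell into person-period rows.

    Each subject contributes ceil(time/interval) rows; exposures sum to
    total follow-up exactly.  The time covariate ``t`` is the midpoint of
    the exposed part of each interval.  ``event`` is 1 only in the final
    row of subjects whose spell ends in a qualifying fracture; death and
    censoring end exposure without an event (cause-specific framing).
    """
    if interval_years <= 0:
        raise ValueError("interval_years must be > 0")
    fu = followups.reset_index(drop=True)
    time = fu["time"].to_numpy(dtype=float)
    sites = outcome_sites(outcome_def)
    is_event = (
        (fu["event"].to_numpy(dtype=int) == EVENT_FRACTURE)
        & np.isin(fu["fracture_site"].to_numpy(), list(sites))
    )
    k = np.maximum(1, np.ceil(time / interval_years - 1e-12).astype(int))
    total = int(k.sum())
    subj = np.repeat(np.arange(len(fu)), k)
    # within-subject interval index 0..k-1
    row = np.arange(total) - np.repeat(np.cumsum(k) - k, k)
    start = row * interval_years
    exposure = np.minimum(time[subj] - start, interval_years)
    last = row == (k[subj] - 1)
    event = np.zeros(total, dtype=int)
    event[last] = is_event[subj[last]].astype(int)
    return pd.DataFrame(
        {
            "patient_id": fu["patient_id"].to_numpy()[subj],
            "interval_start": start,
            "t": start + exposure / 2.0,
            "exposure": exposure,
            "event": event,
        }
    )


def fit_poisson_hazard(
    person_periods: pd.DataFrame,
    weights: pd.Series | np.ndarray | None = None,
    score_col: str = "mof_pct",
    tol: float = 1e-10,
    maxiter: int = 100,
    start_params: np.ndarray | None = None,
) -> HazardFit:
    """Weighted Poisson fit of the six-term log-linear hazard.

    ``person_periods`` must carry the merged covariates ``age``,
    ``score_col`` and ``ptx`` alongside ``t``, ``exposure`` and ``event``.
    ``weights`` are per-patient IPTW weights (Series indexed by
    patient_id) or per-row weights.  The covariance is the inverse of the
    weighted information matrix, exactly the object the delta-method CIs
    are built from.
    """
    pp = person_periods
    y = pp["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("no events in person-period table: hazard not identifiable")
    score = pp[score_col].to_numpy(dtype=float)
    ptxv = pp["ptx"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(pp)),
            pp["t"].to_numpy(dtype=float),
            pp["age"].to_numpy(dtype=float),
            score,
            ptxv,
            score * ptxv,
        ]
    )
    if weights is None:
        w = None
    elif isinstance(weights, pd.Series):
        w = pp["patient_id"].map(weights).to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(pp):
            raise ValueError("row weights must align with person_periods")
    offset = np.log(pp["exposure"].to_numpy(dtype=float))
    model = sm.GLM(
        y, X, family=sm.families.Poisson(), offset=offset, var_weights=w
    )
    res = model.fit(maxiter=maxiter, tol=tol, start_params=start_params)
    if not res.converged:
        grad = np.linalg.norm(model.score(res.params))
        raise RuntimeError(
            f"Poisson fit did not converge in {maxiter} iterations "
            f"(gradient norm {grad:.3e})"
        )
    return HazardFit(
        beta=np.asarray(res.params, dtype=float),
        covariance=np.asarray(res.cov_params(), dtype=float),
        n_intervals=len(pp),
        loglik=float(res.llf),
    )


def hr_curve(fit: HazardFit, score_grid) -> HRCurve:
    """HR(F) = exp(b4 + b5 F) with delta-method 95% bands.

    var(log HR) = V44 + 2 F V45 + F^2 V55; bands symmetric on the log
    scale.
    """
    grid = np.asarray(score_grid, dtype=float)
    b4, b5 = fit.beta[4], fit.beta[5]
    V = fit.covariance
    log_hr = b4 + b5 * grid
    var = V[4, 4] + 2.0 * grid * V[4, 5] + grid**2 * V[5, 5]
    if np.any(var < 0):
        raise ValueError("negative delta-method variance (covariance not PSD)")
    half = 1.96 * np.sqrt(var)
    curve = HRCurve(
        score_grid=grid,
        hr=np.exp(log_hr),
        ci_low=np.exp(log_hr - half),
        ci_high=np.exp(log_hr + half),
        threshold=None,
    )
    curve.threshold = find_threshold(curve)
    return curve


def find_threshold(curve: HRCurve) -> float | None:
    """Smallest grid score above which the HR upper bound stays below 1."""
    below = curve.ci_high < 1.0
    if not below.any():
        return None
    # last index from which everything onward is below 1
    suffix_ok = np.cumprod(below[::-1])[::-1].astype(bool)
    if not suffix_ok.any():
        return None
    return float(curve.score_grid[int(np.argmax(suffix_ok))])


def interaction_test(fit: HazardFit) -> InteractionTest:
    """Wald test of the score x PTX interaction (b5), per unit of score."""
    b5 = float(fit.beta[5])
    se = float(np.sqrt(fit.covariance[5, 5]))
    if se == 0:
        raise ValueError("degenerate interaction variance")
    zstat = b5 / se
    p = 2.0 * float(norm.sf(abs(zstat)))
    return InteractionTest(
        hr_per_unit=float(np.exp(b5)),
        ci_low=float(np.exp(b5 - 1.96 * se)),
        ci_high=float(np.exp(b5 + 1.96 * se)),
        p=p,
    )
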