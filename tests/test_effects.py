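"""IPTW, person-time expansion, Poisson hazard fit, HR curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phptfrac import (
    SimulationConfig,
    find_threshold,
    fit_poisson_hazard,
    fit_propensity,
    generate_cohort,
    hr_curve,
    interaction_test,
    person_time_expand,
)
from phptfrac.effects import HazardFit, standardized_mean_difference


def _merged_pp(cohort, fu, interval=0.5, outcome="all"):
    pp = person_time_expand(fu, interval, outcome)
    return pp.join(
        cohort.set_index("patient_id")[["age", "mof_pct", "hip_pct", "ptx"]],
        on="patient_id",
    )


# ---------------------------------------------------------------------------
# propensity / SMD
# ---------------------------------------------------------------------------

def test_smd_hand_computed():
    """Group means 0.5 vs 0.3 with pooled SD 0.4 give SMD = 0.5 exactly."""
    x = np.array([0.9, 0.1, 0.7, -0.1])
    treated = np.array([True, True, False, False])
    assert standardized_mean_difference(x, treated) == pytest.approx(0.5)


def test_randomized_treatment_is_balanced():
    """Fair-coin treatment: all unweighted SMDs < 0.1 and raw ATE weights
    are approximately 2."""
    cfg = SimulationConfig(n=20_000, seed=71, selection_coefs={})
    cfg.covariate_marginals["ptx"] = {True: 0.5, False: 0.5}
    cohort, _ = generate_cohort(cfg)
    prop = fit_propensity(cohort, stabilized=False, truncate=None)
    assert prop.smd_table["smd_unweighted"].abs().max() < 0.1
    assert prop.weights.mean() == pytest.approx(2.0, abs=0.1)


def test_confounded_default_rebalanced(default_cohort_50k):
    cohort, _ = default_cohort_50k
    prop = fit_propensity(cohort)
    assert prop.smd_table["smd_unweighted"].abs().max() >= 0.1
    assert prop.smd_table["smd_weighted"].abs().max() < 0.1
    assert prop.balanced


def test_perfect_separation_named():
    cfg = SimulationConfig(n=200, seed=3, selection_coefs={})
    cohort, _ = generate_cohort(cfg)
    cohort = cohort.copy()
    cohort["ptx"] = cohort["age"] > 65  # age separates treatment exactly
    with pytest.raises(ValueError, match="age"):
        fit_propensity(cohort, covariates=["age"])


# ---------------------------------------------------------------------------
# person-time expansion
# ---------------------------------------------------------------------------

def _single_fu(time, event=0, site="none"):
    return pd.DataFrame(
        {"patient_id": ["p"], "time": [time], "event": [event], "fracture_site": [site]}
    )


def test_expansion_examples():
    pp = person_time_expand(_single_fu(2.5), 1.0)
    assert pp["exposure"].tolist() == pytest.approx([1.0, 1.0, 0.5])
    assert pp["exposure"].sum() == pytest.approx(2.5)
    assert pp["t"].tolist() == pytest.approx([0.5, 1.5, 2.25])

    pp = person_time_expand(_single_fu(0.2, 1, "hip"), 1.0)
    assert len(pp) == 1
    assert pp.iloc[0]["exposure"] == pytest.approx(0.2)
    assert pp.iloc[0]["event"] == 1


@given(st.lists(st.floats(0.01, 30.0), min_size=1, max_size=1000))
def test_person_time_conserved(times):
    fu = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(times))],
            "time": times,
            "event": 0,
            "fracture_site": "none",
        }
    )
    pp = person_time_expand(fu, 0.5)
    assert abs(pp["exposure"].sum() - sum(times)) < 1e-9
    per_subject = pp.groupby("patient_id")["exposure"].sum()
    assert np.allclose(per_subject.reindex([f"p{i}" for i in range(len(times))]),
                       times, atol=1e-9)


def test_death_and_other_site_end_exposure_without_event():
    fu = pd.concat(
        [_single_fu(1.2, 2, "none"), _single_fu(1.2, 1, "other")]
    ).reset_index(drop=True)
    fu["patient_id"] = ["a", "b"]
    pp = person_time_expand(fu, 1.0, "mof")
    assert pp["event"].sum() == 0
    assert pp["exposure"].sum() == pytest.approx(2.4)


# ---------------------------------------------------------------------------
# Poisson hazard fit
# ---------------------------------------------------------------------------

def test_closed_form_rate_recovered():
    """With no covariate variation the MLE is beta0 = ln(events / person-time)."""
    pp = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(10)],
            "t": 0.0,
            "exposure": [2.0] * 10,
            "event": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
            "age": 0.0,
            "mof_pct": 0.0,
            "ptx": 0.0,
        }
    )
    fit = fit_poisson_hazard(pp, None, "mof_pct")
    assert fit.beta[0] == pytest.approx(np.log(3 / 20.0), abs=1e-8)


def test_zero_events_rejected():
    pp = pd.DataFrame(
        {
            "patient_id": ["p"],
            "t": [0.5],
            "exposure": [1.0],
            "event": [0],
            "age": [65.0],
            "mof_pct": [5.0],
            "ptx": [0.0],
        }
    )
    with pytest.raises(ValueError, match="no events"):
        fit_poisson_hazard(pp, None, "mof_pct")


def test_score_equation_holds(small_cohort):
    """Poisson MLE: fitted weighted events equal observed weighted events."""
    cohort, fu = small_cohort
    prop = fit_propensity(cohort)
    pp = _merged_pp(cohort, fu)
    w_series = pd.Series(prop.weights, index=cohort["patient_id"])
    fit = fit_poisson_hazard(pp, w_series, "mof_pct")
    X = np.column_stack(
        [
            np.ones(len(pp)), pp["t"], pp["age"], pp["mof_pct"], pp["ptx"],
            pp["mof_pct"] * pp["ptx"],
        ]
    )
    mu = pp["exposure"].to_numpy() * np.exp(X @ fit.beta)
    w = pp["patient_id"].map(w_series).to_numpy()
    lhs = float(np.sum(w * mu))
    rhs = float(np.sum(w * pp["event"]))
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_interval_discretization_stable():
    cfg = SimulationConfig(n=20_000, seed=81)
    cohort, fu = generate_cohort(cfg)
    coarse = fit_poisson_hazard(_merged_pp(cohort, fu, 1.0), None, "mof_pct")
    fine = fit_poisson_hazard(_merged_pp(cohort, fu, 0.25), None, "mof_pct")
    assert abs(coarse.beta[4] - fine.beta[4]) < 0.01


def test_strong_interaction_detected():
    """Power check: a strong negative score x PTX interaction is rejected by
    the Wald test in nearly all replicates at n=50 000."""
    rejections = 0
    n_rep = 10
    for seed in range(n_rep):
        cfg = SimulationConfig(n=50_000, seed=90_000 + seed)
        cfg.hazard_coefs = (-6.72, -0.02, 0.030, 0.060, 0.10, -0.05)
        cohort, fu = generate_cohort(cfg)
        fit = fit_poisson_hazard(_merged_pp(cohort, fu), None, "mof_pct")
        if interaction_test(fit).p < 0.05:
            rejections += 1
    assert rejections >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# HR curve, threshold, interaction test
# ---------------------------------------------------------------------------

def _toy_fit(b4, b5, v44, v45, v55):
    beta = np.array([-7.0, 0.0, 0.0, 0.0, b4, b5])
    cov = np.zeros((6, 6))
    cov[4, 4], cov[5, 5] = v44, v55
    cov[4, 5] = cov[5, 4] = v45
    return HazardFit(beta=beta, covariance=cov, n_intervals=0, loglik=0.0)


def test_hr_at_zero_score_uses_v44_only():
    fit = _toy_fit(-0.2, -0.01, 0.01, 0.0, 0.0001)
    c = hr_curve(fit, [0.0])
    assert c.hr[0] == pytest.approx(np.exp(-0.2))
    assert c.ci_high[0] == pytest.approx(np.exp(-0.2 + 1.96 * 0.1))


@given(
    st.floats(-0.5, 0.5), st.floats(-0.05, 0.05),
    st.floats(0.0, 20.0), st.floats(0.0, 20.0),
)
def test_log_hr_exactly_linear(b4, b5, a, c):
    fit = _toy_fit(b4, b5, 0.01, 0.0, 1e-4)
    grid = np.array([a, (a + c) / 2.0, c])
    curve = hr_curve(fit, grid)
    lh = np.log(curve.hr)
    assert lh[0] + lh[2] == pytest.approx(2 * lh[1], abs=1e-9)


def test_delta_method_matches_parametric_bootstrap():
    """95% delta-method bounds vs 2 000-draw parametric bootstrap from
    (beta, covariance): within 0.005 on the HR scale at 4 grid points."""
    fit = _toy_fit(-0.096, -0.005, 0.002, -0.00015, 1.2e-5)
    grid = np.array([1.0, 5.0, 10.0, 20.0])
    curve = hr_curve(fit, grid)
    rng = np.random.default_rng(0)
    draws = rng.multivariate_normal(fit.beta, fit.covariance, size=2000)
    hrs = np.exp(draws[:, 4][:, None] + draws[:, 5][:, None] * grid[None, :])
    lo = np.quantile(hrs, 0.025, axis=0)
    hi = np.quantile(hrs, 0.975, axis=0)
    assert np.max(np.abs(lo - curve.ci_low)) < 0.005
    assert np.max(np.abs(hi - curve.ci_high)) < 0.005


def test_threshold_detection():
    grid = np.arange(0.0, 10.01, 0.5)
    always = hr_curve(_toy_fit(-0.5, -0.01, 1e-6, 0.0, 1e-8), grid)
    assert always.threshold == pytest.approx(0.0)
    never = hr_curve(_toy_fit(0.5, 0.01, 1e-6, 0.0, 1e-8), grid)
    assert never.threshold is None


def test_threshold_analytic_crossing():
    """b5 < 0 with the upper band crossing 1 at F = 2.9 (solved by hand from
    exp(b4 + 1.96*sqrt(V44) + b5 F) = 1) detects the first grid point >= 2.9."""
    b5, v44 = -0.05, 0.0025
    b4 = -b5 * 2.9 - 1.96 * np.sqrt(v44)
    curve = hr_curve(_toy_fit(b4, b5, v44, 0.0, 0.0), np.arange(0.0, 10.01, 0.5))
    assert curve.threshold == pytest.approx(3.0)


def test_interaction_wald_identities():
    fit = _toy_fit(0.0, 0.0, 0.01, 0.0, 1.0)
    assert interaction_test(fit).p == pytest.approx(1.0)
    fit2 = _toy_fit(0.0, 1.96 * np.sqrt(0.25), 0.01, 0.0, 0.25)
    assert interaction_test(fit2).p == pytest.approx(0.05, abs=1e-3)
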