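"""Aalen-Johansen estimator: oracles, invariants, variance calibration."""

import numpy as np
import pandas as pd
import pytest
from lifelines import AalenJohansenFitter, KaplanMeierFitter

from phptfrac import (
    SimulationConfig,
    aalen_johansen,
    generate_cohort,
    incident_filter,
    observed_probability_at,
)
from phptfrac.incidence import CIFEstimate
from phptfrac.risk import _cif_pct
from tests.conftest import make_uncensored_followups


def test_no_censoring_no_death_equals_direct_counting():
    rng = np.random.default_rng(42)
    fu = make_uncensored_followups(rng, 200)
    cif = aalen_johansen(fu, "all")
    for t in (1.0, 3.0, 7.0):
        direct = (fu["time"] <= t).mean()
        assert observed_probability_at(cif, t).value_pct == pytest.approx(
            100 * direct, abs=1e-10
        )


def test_deaths_only():
    fu = pd.DataFrame(
        {
            "patient_id": list("abcd"),
            "time": [1.0, 2.0, 3.0, 4.0],
            "event": [2, 2, 2, 0],
            "fracture_site": ["none"] * 4,
        }
    )
    cif = aalen_johansen(fu, "mof")
    assert np.all(cif.cif_event == 0)
    assert cif.cif_death[-1] == pytest.approx(0.75)


def test_single_cause_reduces_to_one_minus_km():
    """With death hazard off, AJ cumulative incidence equals 1 - KM."""
    cfg = SimulationConfig(
        n=400, seed=5, death_hazard_coefs=(-50.0, 0.0), censor_rate=0.4
    )
    _, fu = generate_cohort(cfg)
    cif = aalen_johansen(fu, "all")
    km = KaplanMeierFitter().fit(fu["time"], fu["event"] == 1)
    for t in (1.0, 2.0, 5.0):
        expect = 1.0 - km.predict(t)
        assert observed_probability_at(cif, t).value_pct == pytest.approx(
            100 * expect, abs=1e-8
        )


def test_hand_computed_six_subject_aj(toy_followups):
    """Fracture at t=1 (hip) and t=4 (spine), deaths at 2 and 5, censored at
    3 and 6: CIF_mof(10) = 7/18 by hand."""
    cif = aalen_johansen(toy_followups, "mof")
    res = observed_probability_at(cif, 10.0)
    assert res.value_pct == pytest.approx(100 * 7 / 18, abs=1e-10)
    assert res.truncated


def test_matches_lifelines_aalen_johansen():
    cfg = SimulationConfig(n=500, seed=9)
    _, fu = generate_cohort(cfg)
    cif = aalen_johansen(fu, "mof")
    code = np.zeros(len(fu), dtype=int)
    code[(fu["event"] == 1) & fu["fracture_site"].isin(["hip", "spine", "forearm", "humerus"])] = 1
    code[fu["event"] == 2] = 2
    code[(fu["event"] == 1) & (code == 0)] = 0  # other-site: censored
    ajf = AalenJohansenFitter(calculate_variance=False)
    ajf.fit(fu["time"], code, event_of_interest=1)
    ll = ajf.cumulative_density_.iloc[:, 0]
    for t in (1.0, 3.0, 8.0):
        idx = np.searchsorted(ll.index.to_numpy(), t, side="right") - 1
        assert observed_probability_at(cif, t).value_pct == pytest.approx(
            100 * float(ll.iloc[idx]), abs=1e-8
        )


def test_probability_conservation(default_cohort_50k):
    _, fu = default_cohort_50k
    for outcome in ("mof", "hip", "all"):
        cif = aalen_johansen(fu, outcome)
        total = cif.cif_event + cif.cif_death + cif.surv
        assert np.max(np.abs(total - 1.0)) < 1e-10
        assert np.all(np.diff(cif.cif_event) >= -1e-12)
        assert np.all(np.diff(cif.cif_death) >= -1e-12)
        assert np.all(np.diff(cif.surv) <= 1e-12)


def test_step_lookup_and_truncation_flag():
    cif = CIFEstimate(
        times=np.array([1.0, 5.0, 9.0]),
        cif_event=np.array([0.02, 0.07, 0.11]),
        cif_death=np.array([0.0, 0.0, 0.0]),
        surv=np.array([0.98, 0.93, 0.89]),
        variance=np.zeros(3),
        n_at_risk=np.array([10, 8, 5]),
    )
    res = observed_probability_at(cif, 10.0)
    assert res.value_pct == pytest.approx(11.0) and res.truncated
    assert observed_probability_at(cif, 0.0).value_pct == 0.0
    mid = observed_probability_at(cif, 6.0)
    assert mid.value_pct == pytest.approx(7.0) and not mid.truncated


def test_errors_on_bad_input(toy_followups):
    with pytest.raises(ValueError, match="empty"):
        aalen_johansen(toy_followups.iloc[:0], "mof")
    bad = toy_followups.copy()
    bad.loc[0, "time"] = -1.0
    with pytest.raises(ValueError, match="non-positive"):
        aalen_johansen(bad, "mof")


def test_mean_cif_matches_analytic_and_se_calibrated():
    """1 000 generator replicates (n=500, b1=0): the mean AJ CIF at t=5
    tracks the population-average analytic CIF within 3 MC SE, and the
    estimated SE of CIF(10) matches the replicate SD within 15%."""
    coefs = (-6.72, 0.0, 0.030, 0.060, -0.0958, -0.005)
    vals5, vals10, ses10 = [], [], []
    for seed in range(1000):
        cfg = SimulationConfig(n=500, seed=20_000 + seed, hazard_coefs=coefs)
        _, fu = generate_cohort(cfg)
        cif = aalen_johansen(fu, "all")
        vals5.append(observed_probability_at(cif, 5.0).value_pct / 100)
        r10 = observed_probability_at(cif, 10.0)
        vals10.append(r10.value_pct / 100)
        ses10.append(np.sqrt(r10.variance))
    # analytic population CIF: average patient-level two-cause closed form
    cfg0 = SimulationConfig(n=20_000, seed=99, hazard_coefs=coefs)
    cohort, _ = generate_cohort(cfg0)
    b = coefs
    ptx = cohort["ptx"].to_numpy(float)
    lam = np.exp(
        b[0] + b[2] * cohort["age"].to_numpy(float)
        + b[3] * cohort["mof_pct"].to_numpy(float)
        + b[4] * ptx + b[5] * cohort["mof_pct"].to_numpy(float) * ptx
    )
    d0, d1 = cfg0.death_hazard_coefs
    hd0 = np.exp(d0 + d1 * (cohort["age"].to_numpy(float) - 65.0))
    analytic5 = np.mean(_cif_pct(lam, hd0, d1, 5.0, 0.01)) / 100
    mc_se = np.std(vals5) / np.sqrt(len(vals5))
    assert abs(np.mean(vals5) - analytic5) < 3 * mc_se
    assert abs(np.std(vals10) / np.mean(ses10) - 1.0) < 0.15


class TestIncidentFilter:
    def test_prevalent_site_suppressed(self):
        ev = pd.DataFrame(
            {"patient_id": ["p", "p"], "date": [-30.0, 40.0], "site": ["hip", "hip"]}
        )
        out = incident_filter(ev, {"p": 0.0}, washout_days=180)
        assert len(out) == 0

    def test_clean_post_index_code_kept(self):
        ev = pd.DataFrame({"patient_id": ["p"], "date": [55.0], "site": ["spine"]})
        out = incident_filter(ev, {"p": 0.0}, washout_days=180)
        assert out.iloc[0]["site"] == "spine" and out.iloc[0]["date"] == 55.0

    def test_washout_is_site_specific(self):
        ev = pd.DataFrame(
            {"patient_id": ["p", "p"], "date": [-30.0, 40.0], "site": ["forearm", "hip"]}
        )
        out = incident_filter(ev, {"p": 0.0}, washout_days=180)
        assert out.iloc[0]["site"] == "hip"

    def test_duplicates_collapsed_and_earliest_kept(self):
        ev = pd.DataFrame(
            {
                "patient_id": ["p"] * 3,
                "date": [40.0, 40.0, 10.0],
                "site": ["hip", "hip", "spine"],
            }
        )
        out = incident_filter(ev, {"p": 0.0}, washout_days=180)
        assert len(out) == 1 and out.iloc[0]["site"] == "spine"
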