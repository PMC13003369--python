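"""Time-dependent AUROC with cumulative sensitivity / dynamic specificity.

At each evaluation time t, cases are subjects with the fracture of
interest by t and controls are subjects still event-free beyond t.
Right censoring is corrected by inverse-probability-of-censoring weights
(IPCW) from the reverse Kaplan-Meier estimate of the censoring
distribution, pooled over treatment arms: a case observed at T gets
weight 1/G(T-), a control at time t gets weight 1/G(t).  Subjects dead
by t without the fracture are, by default, non-cases excluded from the
control set (``competing="exclude"``); ``competing="control"`` retains
them as controls weighted at their death time.

The AUC is the weighted probability that a random case outranks a random
control (ties count 1/2), computed in O(n log n) by sorting.  Standard
errors come from the estimated influence function of the weighted
two-sample U-statistic (the censoring-estimation contribution is
ignored, the usual first-order approximation), giving asymptotic normal
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EVENT_CENSORED, EVENT_DEATH, EVENT_FRACTURE
from .incidence import outcome_sites

__all__ = ["TdAUROC", "td_auroc"]


@dataclass
class TdAUROC:
    eval_times: np.ndarray
    auc: np.ndarray       # NaN where undefined
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    defined: np.ndarray   # bool per time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.eval_times,
                "auc": self.auc,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _censoring_km(time: np.ndarray, censored: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reverse Kaplan-Meier: survival function G of the censoring time.

    Step function, right-continuous; returns (times, G at those times).
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    c = censored[order].astype(float)
    uniq, idx = np.unique(t, return_index=True)
    k = len(uniq)
    dc = np.zeros(k)
    leave = np.zeros(k)
    pos = np.searchsorted(uniq, t)
    np.add.at(dc, pos, c)
    np.add.at(leave, pos, 1.0)
    at_risk = len(t) - np.concatenate(([0.0], np.cumsum(leave)[:-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(at_risk > 0, dc / at_risk, 0.0)
    return uniq, np.cumprod(1.0 - frac)


def _g_at(km_t: np.ndarray, km_g: np.ndarray, query: np.ndarray, left: bool) -> np.ndarray:
    side = "left" if left else "right"
    idx = np.searchsorted(km_t, query, side=side) - 1
    out = np.ones(len(query))
    ok = idx >= 0
    out[ok] = km_g[idx[ok]]
    return out


def _weighted_auc_parts(score, a, b):
    """theta and per-subject pair means for the influence function.

    a, b: nonnegative case/control weights (disjoint supports).  Returns
    (theta, qbar, rbar) with qbar_k = (1/n) sum_j b_j h(s_k, s_j) and
    rbar_k = (1/n) sum_i a_i h(s_i, s_k), h = 1(>) + 1/2 1(=).
    """
    n = len(score)
    order = np.argsort(score, kind="mergesort")
    s = score[order]
    aw = a[order]
    bw = b[order]
    # group boundaries of tied scores
    new = np.empty(n, dtype=bool)
    new[0] = True
    new[1:] = s[1:] != s[:-1]
    gid = np.cumsum(new) - 1
    ngrp = gid[-1] + 1
    a_grp = np.zeros(ngrp)
    b_grp = np.zeros(ngrp)
    np.add.at(a_grp, gid, aw)
    np.add.at(b_grp, gid, bw)
    b_below = np.concatenate(([0.0], np.cumsum(b_grp)[:-1]))
    a_totals = np.cumsum(a_grp[::-1])[::-1]
    a_above = np.concatenate((a_totals[1:], [0.0]))
    q_grp = b_below + 0.5 * b_grp          # sum_j b_j h(s_grp, s_j)
    r_grp = a_above + 0.5 * a_grp          # sum_i a_i h(s_i, s_grp)
    A = aw.sum()
    B = bw.sum()
    U = float(np.dot(a_grp, q_grp))
    theta = U / (A * B)
    qbar = np.empty(n)
    rbar = np.empty(n)
    qbar[order] = q_grp[gid] / n
    rbar[order] = r_grp[gid] / n
    return theta, qbar, rbar, A / n, B / n


def td_auroc(
    scores: pd.Series,
    followups: pd.DataFrame,
    outcome_def: str = "mof",
    eval_times=None,
    competing: str = "exclude",
) -> TdAUROC:
    """Cumulative/dynamic time-dependent AUROC with IPCW and IF-based CIs."""
    if competing not in ("exclude", "control"):
        raise ValueError(f"competing must be 'exclude' or 'control', got {competing!r}")
    if eval_times is None:
        eval_times = np.arange(1.0, 11.0)
    eval_times = np.asarray(eval_times, dtype=float)

    fu = followups.reset_index(drop=True)
    if isinstance(scores, pd.Series) and not isinstance(scores.index, pd.RangeIndex):
        score = scores.reindex(fu["patient_id"]).to_numpy(dtype=float)
    else:
        score = np.asarray(scores, dtype=float)
    time = fu["time"].to_numpy(dtype=float)
    event = fu["event"].to_numpy(dtype=int)
    site = fu["fracture_site"].to_numpy()
    sites = outcome_sites(outcome_def)
    is_case_event = (event == EVENT_FRACTURE) & np.isin(site, list(sites))
    n = len(fu)

    km_t, km_g = _censoring_km(time, event == EVENT_CENSORED)
    g_at_obs_left = _g_at(km_t, km_g, time, left=True)

    k = len(eval_times)
    auc = np.full(k, np.nan)
    se = np.full(k, np.nan)
    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    defined = np.zeros(k, dtype=bool)

    for i, t in enumerate(eval_times):
        cases = is_case_event & (time <= t)
        controls = time > t
        a = np.zeros(n)
        b = np.zeros(n)
        with np.errstate(divide="ignore"):
            a[cases] = 1.0 / g_at_obs_left[cases]
        g_t = _g_at(km_t, km_g, np.asarray([t]), left=False)[0]
        if g_t > 0:
            b[controls] = 1.0 / g_t
        if competing == "control":
            dead = (event == EVENT_DEATH) & (time <= t) & ~cases
            b[dead] = 1.0 / g_at_obs_left[dead]
        a[~np.isfinite(a)] = 0.0
        b[~np.isfinite(b)] = 0.0
        if a.sum() == 0 or b.sum() == 0:
            continue
        theta, qbar, rbar, abar, bbar = _weighted_auc_parts(score, a, b)
        phi = (a * (qbar - theta * bbar) + b * (rbar - theta * abar)) / (abar * bbar)
        s = float(np.sqrt(np.sum(phi**2)) / n)
        auc[i] = theta
        se[i] = s
        lo[i] = theta - 1.96 * s
        hi[i] = theta + 1.96 * s
        defined[i] = True

    return TdAUROC(eval_times=eval_times, auc=auc, se=se, ci_low=lo, ci_high=hi,
                   defined=defined)
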