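"""Decile calibration of estimated vs observed 10-year fracture risk.

Patients are ranked by risk score (stable sort; boundary patients fall in
the lower decile) and cut into ten equal-count groups.  Per decile the
observed probability is the Aalen-Johansen cumulative incidence at the
horizon (95% CI from its delta-method variance, normal approximation,
truncated to [0, 100]); the estimated probability is the group mean
score.  The calibration line is the unweighted ordinary least-squares fit
of observed on estimated across the ten points — ideal slope 1,
intercept 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import aalen_johansen, observed_probability_at
from .risk import SurrogateModel, impute_parental_history, score_cohort

__all__ = ["CalibrationResult", "decile_calibration", "sensitivity_calibration",
           "plot_calibration"]


@dataclass
class CalibrationResult:
    deciles: pd.DataFrame  # mean_estimated_pct, observed_pct, ci bounds, n
    slope: float
    intercept: float  # percentage points


def _decile_groups(score: np.ndarray) -> list[np.ndarray]:
    """Indices of the 10 equal-count score groups (stable ties, lower-decile
    boundary rule)."""
    n = len(score)
    order = np.argsort(score, kind="mergesort")
    bounds = [int(np.floor(i * n / 10)) for i in range(11)]
    return [order[bounds[i]:bounds[i + 1]] for i in range(10)]


def decile_calibration(
    scores: pd.Series,
    followups: pd.DataFrame,
    outcome_def: str = "mof",
    horizon: float = 10.0,
) -> CalibrationResult:
    """Observed-vs-estimated calibration by score decile.

    ``scores`` is a per-patient percent score indexed by patient_id (or
    positionally aligned with ``followups``).
    """
    fu = followups.reset_index(drop=True)
    if isinstance(scores, pd.Series) and not isinstance(scores.index, pd.RangeIndex):
        score = scores.reindex(fu["patient_id"]).to_numpy(dtype=float)
    else:
        score = np.asarray(scores, dtype=float)
    if len(score) != len(fu):
        raise ValueError("scores and followups must cover the same patients")
    n = len(fu)
    if n < 10:
        raise ValueError(f"need at least 10 patients for deciles, got {n}")
    if np.all(score == score[0]):
        raise ValueError("all scores identical: deciles undefined")

    rows = []
    for d, idx in enumerate(_decile_groups(score), start=1):
        cif = aalen_johansen(fu.iloc[idx], outcome_def)
        obs = observed_probability_at(cif, horizon)
        half = 1.96 * 100.0 * np.sqrt(max(obs.variance, 0.0))
        rows.append(
            {
                "decile": d,
                "mean_estimated_pct": float(score[idx].mean()),
                "observed_pct": obs.value_pct,
                "observed_ci_low": max(obs.value_pct - half, 0.0),
                "observed_ci_high": min(obs.value_pct + half, 100.0),
                "n": len(idx),
            }
        )
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(
        table["mean_estimated_pct"], table["observed_pct"], 1
    )
    return CalibrationResult(deciles=table, slope=float(slope), intercept=float(intercept))


def sensitivity_calibration(
    cohort: pd.DataFrame,
    followups: pd.DataFrame,
    model: SurrogateModel | None = None,
    outcome_def: str = "mof",
    score_kind: str = "mof",
    prevalence: float = 0.10,
    n_resamples: int = 100,
    seed: int = 0,
    horizon: float = 10.0,
) -> CalibrationResult:
    """Parental-history imputation sensitivity analysis.

    Each resample probabilistically assigns unknown parental hip-fracture
    history positive (prevalence default 10%), rescores the cohort and
    re-stratifies into deciles; the calibration line is fit to the
    across-resample mean observed and estimated risks per decile.
    """
    col = "mof_pct" if score_kind == "mof" else "hip_pct"
    est = np.zeros((n_resamples, 10))
    obs = np.zeros((n_resamples, 10))
    ns = None
    for r, resample in enumerate(
        impute_parental_history(cohort, prevalence, n_resamples, seed)
    ):
        scored = score_cohort(resample, model)
        scores = pd.Series(
            scored[col].to_numpy(), index=scored["patient_id"].to_numpy()
        )
        res = decile_calibration(scores, followups, outcome_def, horizon)
        est[r] = res.deciles["mean_estimated_pct"].to_numpy()
        obs[r] = res.deciles["observed_pct"].to_numpy()
        ns = res.deciles["n"].to_numpy()
    mean_est = est.mean(axis=0)
    mean_obs = obs.mean(axis=0)
    slope, intercept = np.polyfit(mean_est, mean_obs, 1)
    table = pd.DataFrame(
        {
            "decile": np.arange(1, 11),
            "mean_estimated_pct": mean_est,
            "observed_pct": mean_obs,
            "observed_ci_low": np.nan,
            "observed_ci_high": np.nan,
            "n": ns,
        }
    )
    return CalibrationResult(deciles=table, slope=float(slope), intercept=float(intercept))


def plot_calibration(result: CalibrationResult, path: str, title: str = "") -> None:
    """Calibration plot: decile points with CIs, unity line, best-fit line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.deciles
    fig, ax = plt.subplots(figsize=(5, 5))
    yerr = np.vstack(
        [
            t["observed_pct"] - t["observed_ci_low"],
            t["observed_ci_high"] - t["observed_pct"],
        ]
    )
    if np.isfinite(yerr).all():
        ax.errorbar(t["mean_estimated_pct"], t["observed_pct"], yerr=yerr,
                    fmt="o", capsize=3)
    else:
        ax.plot(t["mean_estimated_pct"], t["observed_pct"], "o")
    lim = max(t["mean_estimated_pct"].max(), t["observed_pct"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "--", color="gray", label="perfect calibration")
    xs = np.array([0.0, lim])
    ax.plot(xs, result.intercept + result.slope * xs, "-",
            label=f"fit: {result.slope:.2f}x + {result.intercept:.1f}")
    ax.set_xlabel("estimated 10-year probability (%)")
    ax.set_ylabel("observed 10-year probability (%)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
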