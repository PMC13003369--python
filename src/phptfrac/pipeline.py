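"""End-to-end orchestration: simulate -> score -> incidence -> calibration
-> discrimination -> effects -> report.

Every stage writes its outputs (CSV/JSON) before the next begins, and a
run manifest records the config hash, seed, per-stage row counts and a
checksum inventory of every emitted file, so a run is reproducible and
auditable.  The report stage also computes the guideline-criteria
summary: the fraction of patients meeting none of the conventional
surgical criteria (age < 50, osteoporosis, nephrolithiasis, CKD stage
>= 3) and, among them, the fractions above each detected
benefit threshold.
"""

from __future__ import annotations

import hashlib
import json
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import decile_calibration, sensitivity_calibration
from .cohort import generate_cohort
from .config import SimulationConfig, _jsonable
from .discrimination import td_auroc
from .effects import (
    fit_poisson_hazard,
    fit_propensity,
    hr_curve,
    interaction_test,
    person_time_expand,
)
from .io import write_cohort_csv, write_followup_csv
from .risk import SurrogateModel, default_surrogate

logger = logging.getLogger("phptfrac")

#: outcome / score-kind pairs fitted by the effects stage (MOF and hip
#: outcomes against their own scores; the all-fracture outcome against both)
EFFECT_PAIRS = [
    ("mof", "mof"), ("hip", "hip"), ("all", "mof"), ("all", "hip"),
]

SCORE_PERCENTILES = (10, 25, 50, 75, 90)


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    interval_years: float = 0.5
    horizon: float = 10.0
    eval_times: tuple[float, ...] = tuple(float(t) for t in range(1, 11))
    exclude_antiosteoporosis_med: bool = False
    sensitivity_resamples: int = 0   # parental-history resampling (0 = off)
    hr_grid_step: float = 0.1

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        return _jsonable(dataclasses.asdict(self))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    row_counts: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def percentage(numerator: int, denominator: int) -> float:
    """Printed percentage with 1-decimal rounding (e.g. 6522/26136 -> 25.0)."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    return round(100.0 * numerator / denominator, 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def guideline_summary(cohort: pd.DataFrame, thresholds: dict[str, float | None]) -> dict:
    """Fractions of guideline-nonqualifying patients above each threshold.

    Nonqualifying = meets none of: age < 50, osteoporosis, kidney stones,
    CKD stage >= 3.
    """
    qualifies = (
        (cohort["age"] < 50)
        | cohort["osteoporosis"].astype(bool)
        | cohort["kidney_stones"].astype(bool)
        | cohort["ckd_stage3plus"].astype(bool)
    )
    non = cohort.loc[~qualifies]
    n_total = len(cohort)
    n_non = len(non)
    out = {
        "n_total": n_total,
        "n_nonqualifying": n_non,
        "pct_nonqualifying": percentage(n_non, n_total) if n_total else None,
        "above_threshold": {},
    }
    for key, score_col in (
        ("mof", "mof_pct"), ("hip", "hip_pct"),
        ("all_mof", "mof_pct"), ("all_hip", "hip_pct"),
    ):
        thr = thresholds.get(key)
        if thr is None or n_non == 0:
            out["above_threshold"][key] = None
            continue
        num = int((non[score_col] > thr).sum())
        out["above_threshold"][key] = {
            "threshold_pct": thr,
            "numerator": num,
            "denominator": n_non,
            "pct": percentage(num, n_non),
        }
    return out


def run_pipeline(
    config: PipelineConfig | str,
    outdir: str,
    model: SurrogateModel | None = None,
) -> RunManifest:
    """Execute all stages into ``outdir`` and return the run manifest."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(str(config))
    model = model or default_surrogate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    config_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    (out / "config.yaml").write_text(cfg_yaml)
    model.to_yaml(str(out / "surrogate_model.yaml"))

    # -- simulate (scores are computed inside the generator) --------------
    logger.info("simulate: n=%d seed=%d", config.simulation.n, config.simulation.seed)
    cohort, followup = generate_cohort(config.simulation, model)
    if config.exclude_antiosteoporosis_med:
        keep = ~cohort["antiosteoporosis_med"].astype(bool)
        logger.info("excluding %d patients with prior antiosteoporosis medication",
                    int((~keep).sum()))
        cohort = cohort.loc[keep].reset_index(drop=True)
        followup = followup.loc[keep.to_numpy()].reset_index(drop=True)
    write_cohort_csv(cohort, str(out / "cohort.csv"))
    write_followup_csv(followup, str(out / "followup.csv"))
    counts["cohort"] = len(cohort)
    if len(cohort) == 0:
        raise ValueError("simulate produced an empty cohort; nothing to analyse")

    scores = {
        "mof": pd.Series(cohort["mof_pct"].to_numpy(), index=cohort["patient_id"]),
        "hip": pd.Series(cohort["hip_pct"].to_numpy(), index=cohort["patient_id"]),
    }

    # -- incidence ---------------------------------------------------------
    from .incidence import aalen_johansen, observed_probability_at

    incidence_summary = {}
    for outcome in ("mof", "hip", "all"):
        cif = aalen_johansen(followup, outcome)
        cif.to_frame().to_csv(out / f"cif_{outcome}.csv", index=False)
        obs = observed_probability_at(cif, config.horizon)
        incidence_summary[outcome] = {
            "observed_pct_at_horizon": obs.value_pct,
            "truncated": obs.truncated,
        }
        counts[f"cif_{outcome}"] = len(cif.times)
    (out / "incidence.json").write_text(json.dumps(incidence_summary, indent=2))

    # -- calibration -------------------------------------------------------
    calib_summary = {}
    for outcome in ("mof", "hip"):
        res = decile_calibration(scores[outcome], followup, outcome, config.horizon)
        res.deciles.to_csv(out / f"calibration_{outcome}.csv", index=False)
        calib_summary[outcome] = {"slope": res.slope, "intercept_pct": res.intercept}
        if config.sensitivity_resamples > 0:
            sens = sensitivity_calibration(
                cohort, followup, model, outcome, outcome,
                n_resamples=config.sensitivity_resamples,
                seed=config.simulation.seed + 1,
                horizon=config.horizon,
            )
            sens.deciles.to_csv(
                out / f"calibration_{outcome}_parental_sensitivity.csv", index=False
            )
            calib_summary[f"{outcome}_parental_sensitivity"] = {
                "slope": sens.slope, "intercept_pct": sens.intercept,
            }
    (out / "calibration.json").write_text(json.dumps(calib_summary, indent=2))

    # -- discrimination ----------------------------------------------------
    auroc_summary = {}
    for outcome in ("mof", "hip"):
        td = td_auroc(scores[outcome], followup, outcome, config.eval_times)
        td.to_frame().to_csv(out / f"auroc_{outcome}.csv", index=False)
        at_horizon = td.to_frame().iloc[-1]
        auroc_summary[outcome] = {
            "auc_at_horizon": None if np.isnan(at_horizon["auc"]) else float(at_horizon["auc"]),
            "se": None if np.isnan(at_horizon["se"]) else float(at_horizon["se"]),
        }
    (out / "auroc.json").write_text(json.dumps(auroc_summary, indent=2))

    # -- effects -----------------------------------------------------------
    prop = fit_propensity(cohort)
    prop.smd_table.to_csv(out / "smd.csv", index=False)
    weights = pd.Series(prop.weights, index=cohort["patient_id"])
    effects_summary: dict = {"balanced": prop.balanced}
    table2_rows = []
    curves = []
    for outcome, score_kind in EFFECT_PAIRS:
        pp = person_time_expand(followup, config.interval_years, outcome)
        cov_cols = cohort.set_index("patient_id")[["age", "mof_pct", "hip_pct", "ptx"]]
        pp = pp.join(cov_cols, on="patient_id")
        score_col = f"{score_kind}_pct"
        fit = fit_poisson_hazard(pp, weights, score_col)
        grid = np.arange(
            0.0,
            float(np.ceil(cohort[score_col].quantile(0.99))) + config.hr_grid_step,
            config.hr_grid_step,
        )
        curve = hr_curve(fit, grid)
        curves.append(
            pd.DataFrame(
                {
                    "outcome": outcome, "score_kind": score_kind,
                    "score_pct": curve.score_grid, "hr": curve.hr,
                    "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                }
            )
        )
        pct_scores = np.percentile(cohort[score_col], SCORE_PERCENTILES)
        at_pct = hr_curve(fit, pct_scores)
        for pctl, s, h, lo, hi in zip(
            SCORE_PERCENTILES, pct_scores, at_pct.hr, at_pct.ci_low, at_pct.ci_high
        ):
            table2_rows.append(
                {
                    "outcome": outcome, "score_kind": score_kind,
                    "percentile": pctl, "score_pct": round(float(s), 1),
                    "hr": h, "ci_low": lo, "ci_high": hi,
                }
            )
        it = interaction_test(fit)
        effects_summary[f"{outcome}_{score_kind}"] = {
            "beta": fit.beta.tolist(),
            "threshold_pct": curve.threshold,
            "interaction": {
                "hr_per_unit": it.hr_per_unit, "ci_low": it.ci_low,
                "ci_high": it.ci_high, "p": it.p,
            },
        }
    pd.concat(curves).to_csv(out / "hr_curves.csv", index=False)
    pd.DataFrame(table2_rows).to_csv(out / "hr_table.csv", index=False)
    (out / "effects.json").write_text(json.dumps(effects_summary, indent=2))
    counts["person_periods"] = int(len(pp))

    # -- report ------------------------------------------------------------
    thresholds = {
        "mof": effects_summary["mof_mof"]["threshold_pct"],
        "hip": effects_summary["hip_hip"]["threshold_pct"],
        "all_mof": effects_summary["all_mof"]["threshold_pct"],
        "all_hip": effects_summary["all_hip"]["threshold_pct"],
    }
    report = {
        "median_followup_years": float(followup["time"].median()),
        "ptx_pct": percentage(int(cohort["ptx"].sum()), len(cohort)),
        "guideline": guideline_summary(cohort, thresholds),
        "thresholds_pct": thresholds,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))

    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = RunManifest(
        config_hash=config_hash,
        seed=config.simulation.seed,
        version=__version__,
        row_counts=counts,
        outputs={f: _sha256(out / f) for f in files},
    )
    manifest.write(out / "manifest.json")
    return manifest
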