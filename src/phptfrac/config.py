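"""Simulation configuration and population-level defaults.

The default covariate marginals encode the baseline characteristics of a
large US primary-hyperparathyroidism (PHPT) cohort (n = 59 194; 75.2%
female; 25.0% treated with parathyroidectomy).  They drive the synthetic
cohort generator so that every downstream stage — risk scoring, competing
risk incidence, calibration, discrimination and IPTW hazard modelling —
can be exercised end to end without access to protected health records.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

FRACTURE_SITES = ("hip", "spine", "forearm", "humerus", "other")

#: Fixed multinomial over fracture sites used by the score-linear generator.
#: Major osteoporotic (MOF) sites — hip, spine, distal forearm, proximal
#: humerus — carry 80% of the mass; "other" stands for the remaining
#: non-skull/hand/foot sites counted only in the all-fracture outcome.
DEFAULT_SITE_PROBS = {
    "hip": 0.25,
    "spine": 0.30,
    "forearm": 0.15,
    "humerus": 0.10,
    "other": 0.20,
}

MOF_SITES = frozenset({"hip", "spine", "forearm", "humerus"})
ALL_SITES = frozenset(FRACTURE_SITES)

#: fracture log-hazard coefficients (beta0..beta5) of the score-linear
#: generator: exp(b0 + b1*t + b2*age + b3*score + b4*ptx + b5*score*ptx),
#: with the MOF score in percent.  b4, b5 give HR(PTX) = 0.88 at the median
#: score (6.4%); b0 is calibrated so 10-year MOF cumulative incidence under
#: the default marginals is roughly 8%.
DEFAULT_HAZARD_COEFS = (-6.72, -0.02, 0.030, 0.060, -0.0958, -0.005)

#: Gompertz mortality: exp(d0 + d1*(attained_age - 65)).
DEFAULT_DEATH_COEFS = (-4.20, 0.09)

#: Exponential loss-to-follow-up rate per year, calibrated so median
#: observed follow-up is about 2.7 years.
DEFAULT_CENSOR_RATE = 0.22

#: Log-odds of parathyroidectomy per covariate; mirrors the surgical
#: selection pattern of the source population (younger, less CKD, more
#: osteopenia/osteoporosis and nephrolithiasis among the operated).
DEFAULT_SELECTION_COEFS = {
    "age": -0.035,  # per year, centred at 65
    "ckd_stage3plus": -1.20,
    "race_ethnicity=Black": -0.70,
    "osteoporosis": 0.50,
    "osteopenia": 0.60,
    "kidney_stones": 0.30,
    "highest_calcium_band=ge11.5": 0.20,
}

_N_REF = 59_194  # reference cohort size behind the published proportions


def default_marginals() -> dict[str, dict[Any, float]]:
    """Probability tables for every categorical/boolean patient field.

    Boolean fields map ``{True: p, False: 1-p}``; categorical fields map
    level -> probability.  Every table sums to 1.
    """
    m: dict[str, dict[Any, float]] = {
        "sex": {"female": 0.752, "male": 0.248},
        "ptx": _bool(0.250),
        "race_ethnicity": {
            "Asian": 0.025,
            "Black": 0.230,
            "Hispanic": 0.046,
            "White": 0.699,
        },
        "inclusion_period": {
            "2000s": 2561 / _N_REF,
            "2010s": 28747 / _N_REF,
            "2020s": 27886 / _N_REF,
        },
        "highest_calcium_band": {
            "lt11.5": 44262 / _N_REF,
            "ge11.5": 9494 / _N_REF,
            "unknown": 5438 / _N_REF,
        },
        # parental hip fracture history is unavailable in the source data;
        # scoring treats "unknown" as negative, and the sensitivity
        # resampler imputes it probabilistically.
        "parental_hip_fracture": {"yes": 0.0, "no": 0.0, "unknown": 1.0},
        "prior_fracture": _bool(7807 / _N_REF),
        "current_smoking": _bool(7638 / _N_REF),
        "glucocorticoid_use": _bool(186 / _N_REF),
        "rheumatoid_arthritis": _bool(2204 / _N_REF),
        "secondary_osteoporosis": _bool(11949 / _N_REF),
        "alcohol_excess": _bool(1840 / _N_REF),
        "osteopenia": _bool(7013 / _N_REF),
        "osteoporosis": _bool(9436 / _N_REF),
        "ckd_stage3plus": _bool(8881 / _N_REF),
        "kidney_stones": _bool(6820 / _N_REF),
        "antiosteoporosis_med": _bool(11972 / _N_REF),
    }
    return m


def _bool(p: float) -> dict[Any, float]:
    return {True: p, False: 1.0 - p}


def default_continuous() -> dict[str, dict[str, float]]:
    """Truncated-normal parameters for the continuous patient fields.

    Ages outside [40, 90] are outside the risk calculator's accepted range
    and are excluded by design, so the generator never draws them.  Height
    is drawn per sex; weight is derived from BMI and height.
    """
    return {
        "age": {"mean": 65.9, "sd": 10.8, "lo": 40.0, "hi": 90.0},
        "bmi": {"mean": 30.3, "sd": 7.2, "lo": 15.0, "hi": 60.0},
        "height_female": {"mean": 162.0, "sd": 7.0, "lo": 140.0, "hi": 200.0},
        "height_male": {"mean": 176.0, "sd": 7.0, "lo": 150.0, "hi": 210.0},
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic-cohort draw.

    ``hazard_model`` selects the fracture-hazard structure:

    * ``"score_linear"`` (default): cause-specific all-fracture hazard
      ``exp(b0 + b1 t + b2 age + b3 score + b4 ptx + b5 score ptx)`` with the
      MOF score (percent) computed by the risk engine on the drawn
      covariates, and fracture sites from a fixed multinomial.
    * ``"engine"``: fracture and death hazards taken directly from the risk
      engine's surrogate model (no treatment effect), so a patient's
      10-year score equals their true cumulative incidence — the
      self-consistency regime used to validate calibration.
    """

    n: int = 50_000
    seed: int = 0
    hazard_coefs: tuple[float, ...] = DEFAULT_HAZARD_COEFS
    death_hazard_coefs: tuple[float, float] = DEFAULT_DEATH_COEFS
    censor_rate: float = DEFAULT_CENSOR_RATE
    admin_censor_years: float = 24.0
    selection_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SELECTION_COEFS)
    )
    covariate_marginals: dict[str, dict[Any, float]] = field(
        default_factory=default_marginals
    )
    continuous_marginals: dict[str, dict[str, float]] = field(
        default_factory=default_continuous
    )
    site_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_PROBS)
    )
    hazard_model: str = "score_linear"

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if self.censor_rate < 0:
            raise ValueError(f"censor_rate must be >= 0, got {self.censor_rate}")
        if len(self.hazard_coefs) != 6:
            raise ValueError("hazard_coefs must have exactly 6 entries (beta0..beta5)")
        for i, b in enumerate(self.hazard_coefs):
            # beta0 = -inf is the documented "no fracture hazard" degenerate
            # case; anything non-finite elsewhere would overflow the hazard.
            if math.isnan(b) or b == math.inf or (i != 0 and math.isinf(b)):
                raise ValueError(
                    f"hazard coefficient beta{i} is not finite: {b!r}"
                )
        for name, table in self.covariate_marginals.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal table for {name!r} sums to {total}, expected 1"
                )
            if any(p < 0 for p in table.values()):
                raise ValueError(f"marginal table for {name!r} has negative mass")
        if abs(sum(self.site_probs.values()) - 1.0) > 1e-9:
            raise ValueError("site_probs must sum to 1")
        if self.hazard_model not in ("score_linear", "engine"):
            raise ValueError(f"unknown hazard_model {self.hazard_model!r}")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(dataclasses.asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "hazard_coefs" in kwargs:
            kwargs["hazard_coefs"] = tuple(float(x) for x in kwargs["hazard_coefs"])
        if "death_hazard_coefs" in kwargs:
            kwargs["death_hazard_coefs"] = tuple(
                float(x) for x in kwargs["death_hazard_coefs"]
            )
        if "covariate_marginals" in kwargs:
            kwargs["covariate_marginals"] = {
                name: _parse_table(tab)
                for name, tab in kwargs["covariate_marginals"].items()
            }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _parse_table(tab: dict) -> dict[Any, float]:
    out: dict[Any, float] = {}
    for k, v in tab.items():
        if isinstance(k, str) and k in ("true", "false", "True", "False"):
            out[k.lower() == "true"] = float(v)
        else:
            out[k] = float(v)
    return out


def _jsonable(obj: Any) -> Any:
    """Make dataclass dicts YAML-safe (bool keys -> strings, tuples -> lists)."""
    if isinstance(obj, dict):
        return {
            (str(k).lower() if isinstance(k, bool) else k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return str(obj)
    return obj
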