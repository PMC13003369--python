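"""CSV round-trip helpers for the cohort and follow-up tables.

Column dictionary (cohort CSV, one row per patient):

    patient_id            opaque identifier
    age                   years at index (40-90)
    sex                   female | male
    race_ethnicity        Asian | Black | Hispanic | White
    height, weight, bmi   cm, kg, kg/m^2 (bmi = weight / (height/100)^2)
    prior_fracture .. antiosteoporosis_med   0/1 clinical factors
    parental_hip_fracture yes | no | unknown
    highest_calcium_band  lt11.5 | ge11.5 | unknown
    inclusion_period      2000s | 2010s | 2020s
    ptx                   0/1 treatment (parathyroidectomy)
    mof_pct, hip_pct      10-year fracture probabilities, percent

Follow-up CSV (one row per patient): patient_id, time (years > 0),
event (0 censored / 1 fracture / 2 death), fracture_site
(hip|spine|forearm|humerus|other|none).
"""

from __future__ import annotations

import pandas as pd

BOOL_COLS = [
    "prior_fracture", "current_smoking", "glucocorticoid_use",
    "rheumatoid_arthritis", "secondary_osteoporosis", "alcohol_excess",
    "osteopenia", "osteoporosis", "ckd_stage3plus", "kidney_stones",
    "antiosteoporosis_med", "ptx",
]


def write_cohort_csv(cohort: pd.DataFrame, path: str) -> None:
    out = cohort.copy()
    for col in BOOL_COLS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_followup_csv(followup: pd.DataFrame, path: str) -> None:
    followup.to_csv(path, index=False)


def read_followup_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"patient_id": str, "event": int, "fracture_site": str}
    )
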