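"""Cohort covariate table: demographics and clinical scores.

The table is a thin validated wrapper around a pandas DataFrame with one row
per analysed subject.  Clinical scores follow the ALS conventions: ALSFRS-R
is a 0-48 functional rating (lower = more disabled), the change-from-baseline
score is ``48 - ALSFRS-R``, the progression rate deltaALSFRS-R is that change
divided by years since symptom onset, and the UMN score counts pathological
reflexes.  Healthy controls carry a clinical score of 0 whenever scores are
used as regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "handedness",
    "alsfrs_r",
    "umn_score",
    "years_from_onset",
]


@dataclass(frozen=True)
class CohortTable:
    """Validated per-subject covariates for the analysed cohort."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad_group = sorted(set(df["group"]) - {"ALS", "control"})
        if bad_group:
            raise ValueError(f"unknown group labels: {bad_group}")
        bad_sex = sorted(set(df["sex"]) - {"M", "F"})
        if bad_sex:
            raise ValueError(f"unknown sex codes: {bad_sex}")
        bad_hand = sorted(set(df["handedness"]) - {"right", "left"})
        if bad_hand:
            raise ValueError(f"unknown handedness codes: {bad_hand}")
        als = df[df["group"] == "ALS"]
        a = als["alsfrs_r"].to_numpy(dtype=float)
        if np.isnan(a).any():
            raise ValueError("ALS subjects must carry an ALSFRS-R score")
        if ((a < 0) | (a > 48)).any():
            raise ValueError("ALSFRS-R must lie in [0, 48]")
        y = als["years_from_onset"].to_numpy(dtype=float)
        if np.isnan(y).any() or (y <= 0).any():
            raise ValueError("ALS years_from_onset must be positive")
        u = als["umn_score"].to_numpy(dtype=float)
        if np.isnan(u).any() or (u < 0).any():
            raise ValueError("UMN score must be >= 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    @property
    def is_als(self) -> np.ndarray:
        return (self.df["group"] == "ALS").to_numpy()

    def clinical_score(self, mode: str) -> np.ndarray:
        """Per-subject clinical score with healthy controls fixed at 0.

        Modes: ``alsfrs_change`` = 48 - ALSFRS-R; ``umn`` = UMN score;
        ``delta_alsfrs`` = (48 - ALSFRS-R) / years_from_onset.
        """
        df = self.df
        als = self.is_als
        score = np.zeros(len(df), dtype=float)
        if mode == "alsfrs_change":
            score[als] = 48.0 - df.loc[als, "alsfrs_r"].to_numpy(dtype=float)
        elif mode == "umn":
            score[als] = df.loc[als, "umn_score"].to_numpy(dtype=float)
        elif mode == "delta_alsfrs":
            change = 48.0 - df.loc[als, "alsfrs_r"].to_numpy(dtype=float)
            score[als] = change / df.loc[als, "years_from_onset"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown clinical score mode {mode!r}")
        if not np.all(np.isfinite(score)) or (score < 0).any():
            raise ValueError("clinical scores must be finite and >= 0")
        return score

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        return cls(df)
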