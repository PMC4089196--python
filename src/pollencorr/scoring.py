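"""Diary scoring: RTSS, TRMS and the combined symptom-medication score (CSMS).

The daily outcome of an allergic-rhinitis diary is scored in three parts:

* **RTSS** (rhinoconjunctivitis total symptom score): the sum of six
  ordinal symptom grades (sneezing, runny nose, itchy nose, nasal
  congestion, tearing, itchy eyes), each graded 0-3, so RTSS lies in 0-18.
* **TRMS** (total rescue medication score): a weighted sum over rescue
  drug classes used that day — chromone eyedrops 1 point, oral
  antihistamine 2, nasal corticosteroid 3, leukotriene antagonist 5.
  Use is a per-class daily flag; repeated intakes of one class on one day
  count once.
* **CSMS** = RTSS + TRMS, the daily severity outcome that downstream
  cross-correlation analyses use.

Diaries are tabular: one row per patient-day (see :mod:`pollencorr.io`
for the CSV schema). Days without a diary entry are *gaps*, never zeros:
a missing day drops out of cohort means instead of dragging them down.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pollencorr.errors import EmptyCohortError, ValidationError

#: Six RTSS symptom components, each graded 0-3.
SYMPTOM_COLUMNS: tuple[str, ...] = (
    "sneezing",
    "runny_nose",
    "itchy_nose",
    "nasal_congestion",
    "tearing",
    "itchy_eyes",
)

#: Rescue-medication classes and their TRMS point weights.
MED_POINTS: dict[str, int] = {
    "med_chromone": 1,
    "med_antihistamine": 2,
    "med_corticosteroid": 3,
    "med_leukotriene": 5,
}

MED_COLUMNS: tuple[str, ...] = tuple(MED_POINTS)

#: Maximum possible RTSS (six symptoms at grade 3).
RTSS_MAX = 18


@dataclass(frozen=True)
class SymptomRecord:
    """Six ordinal symptom grades for one patient-day, each in {0, 1, 2, 3}."""

    sneezing: int
    runny_nose: int
    itchy_nose: int
    nasal_congestion: int
    tearing: int
    itchy_eyes: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or not 0 <= v <= 3:
                raise ValidationError(
                    f"symptom grade {f.name!r} must be an integer in 0..3, got {v!r}"
                )

    def grades(self) -> tuple[int, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class MedicationRecord:
    """Per-class daily medication-use flags. Absence of a record means all False."""

    chromone_eyedrops: bool = False
    antihistamine_oral: bool = False
    corticosteroid_nasal: bool = False
    leukotriene_antagonist: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (bool, np.bool_)):
                raise ValidationError(f"medication flag {f.name!r} must be boolean, got {v!r}")


def compute_rtss(record: SymptomRecord) -> int:
    """Sum the six symptom grades; range 0-18."""
    return int(sum(record.grades()))


def compute_trms(record: MedicationRecord) -> int:
    """Weighted medication score: 1*chromone + 2*antihistamine + 3*corticosteroid + 5*leukotriene."""
    return (
        1 * record.chromone_eyedrops
        + 2 * record.antihistamine_oral
        + 3 * record.corticosteroid_nasal
        + 5 * record.leukotriene_antagonist
    )


def compute_csms(symptoms: SymptomRecord, meds: MedicationRecord) -> int:
    """Combined symptom-medication score: RTSS + TRMS for one patient-day."""
    return compute_rtss(symptoms) + compute_trms(meds)


def _validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    required = ["patient_id", "date", *SYMPTOM_COLUMNS]
    missing = [c for c in required if c not in diary.columns]
    if missing:
        raise ValidationError(f"diary table is missing columns: {missing}")
    out = diary.copy()
    out["date"] = pd.to_datetime(out["date"])
    for col in SYMPTOM_COLUMNS:
        vals = out[col]
        bad = vals.isna() | ~vals.isin([0, 1, 2, 3])
        if bad.any():
            row = out[bad].iloc[0]
            raise ValidationError(
                f"invalid grade for symptom {col!r} on {row['date'].date()} "
                f"(patient {row['patient_id']}): {row[col]!r}"
            )
    for col in MED_COLUMNS:
        if col not in out.columns:
            out[col] = 0  # no medication record on file means no use
        else:
            vals = out[col].fillna(0)
            if not vals.isin([0, 1, True, False]).all():
                raise ValidationError(f"medication column {col!r} must be 0/1 flags")
            out[col] = vals.astype(int)
    dup = out.duplicated(subset=["patient_id", "date"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValidationError(
            f"duplicate diary entry for patient {row['patient_id']} on {row['date'].date()}"
        )
    return out


def score_diary(diary: pd.DataFrame) -> pd.DataFrame:
    """Score a whole diary table.

    Parameters
    ----------
    diary:
        One row per patient-day with columns ``patient_id``, ``date``, the
        six symptom grades and (optionally) the four 0/1 medication flags.

    Returns
    -------
    DataFrame with columns ``patient_id, date, rtss, trms, csms``, one row
    per input row. CSMS = RTSS + TRMS holds exactly for every row.
    """
    d = _validate_diary(diary)
    rtss = d[list(SYMPTOM_COLUMNS)].sum(axis=1).astype(int)
    trms = sum(d[col] * pts for col, pts in MED_POINTS.items()).astype(int)
    return pd.DataFrame(
        {
            "patient_id": d["patient_id"].to_numpy(),
            "date": d["date"].to_numpy(),
            "rtss": rtss.to_numpy(),
            "trms": trms.to_numpy(),
            "csms": (rtss + trms).to_numpy(),
        }
    )


def _restrict(scores: pd.DataFrame, period: tuple | None) -> pd.DataFrame:
    if period is None:
        return scores
    start, end = pd.to_datetime(period[0]), pd.to_datetime(period[1])
    if start > end:
        raise ValidationError(f"empty period: {start.date()} > {end.date()}")
    return scores[(scores["date"] >= start) & (scores["date"] <= end)]


def cohort_mean_csms_series(
    scores: pd.DataFrame,
    patient_ids: Iterable | None = None,
    period: tuple | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Daily mean CSMS across a patient subset, with per-day contributor counts.

    Only patients with a diary entry on a given day contribute to that
    day's mean; days with no entries at all are gaps (absent dates).

    Returns ``(mean_series, count_series)`` indexed by date.
    """
    sub = scores if patient_ids is None else scores[scores["patient_id"].isin(set(patient_ids))]
    if sub.empty or sub["patient_id"].nunique() == 0:
        raise EmptyCohortError("empty cohort: no patients with diary entries in subset")
    sub = _restrict(sub, period)
    if sub.empty:
        raise EmptyCohortError("empty cohort: no diary entries in period")
    grouped = sub.groupby("date")["csms"]
    mean = grouped.mean().sort_index()
    mean.name = "csms"
    count = grouped.size().sort_index()
    count.name = "n_patients"
    return mean, count


def patient_mean_csms(scores: pd.DataFrame, patient_id, period: tuple | None = None) -> float:
    """Mean of one patient's daily CSMS over days with entries in ``period``."""
    sub = _restrict(scores[scores["patient_id"] == patient_id], period)
    if sub.empty:
        raise EmptyCohortError(f"patient {patient_id!r} has no diary entries in period")
    return float(sub["csms"].mean())


def weekly_average(series: pd.Series) -> pd.Series:
    """Average a daily series per ISO week, stamped on the week's Monday.

    Presentation aid for plots only; all statistics run on daily series.
    """
    if series.empty:
        raise ValidationError("cannot weekly-average an empty series")
    idx = pd.DatetimeIndex(series.index)
    mondays = idx - pd.to_timedelta(idx.dayofweek, unit="D")
    out = series.groupby(mondays).mean()
    out.index.name = series.index.name
    return out
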