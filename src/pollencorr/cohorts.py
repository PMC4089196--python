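"""Patient subgroup construction.

Four stratifications of a centre's cohort are supported:

1. the whole cohort (averaged CSMS),
2. grass-specific IgE split: "IgE high" (class >= III, i.e. >= 3.5 kU/L)
   versus "IgE low" (class < III),
3. asthma comorbidity split,
4. CSMS split: "CSMS low" = patients whose mean CSMS is strictly below
   50% of the centre's cohort mean (computed as the unweighted mean of
   per-patient means), "CSMS high" = the rest;

plus pooled "severe" / "mild" groups combining the three criteria under
a configurable conjunction rule (see :class:`SevereMildRule`).

IgE classes follow the standard specific-IgE banding:
0: <0.35, I: 0.35-0.69, II: 0.70-3.49, III: 3.50-17.49, IV: 17.5-49.99,
V: 50-100, VI: >100 kU/L. Boundary concentrations belong to the class
whose range starts there.

Patient profiles are a DataFrame with columns ``patient_id, centre,
ige_kUL, ige_class, asthma, rrtss`` (see :mod:`pollencorr.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from pollencorr.errors import EmptyCohortError, ValidationError
from pollencorr.scoring import patient_mean_csms

logger = logging.getLogger(__name__)

#: Lower bound (kU/L) of IgE classes I..V; class 0 is below the first,
#: class V is closed at 100 and class VI is strictly above it.
_IGE_LOWER_BOUNDS = (0.35, 0.70, 3.50, 17.5, 50.0)

#: Class at which "IgE high" starts (class III = 3.5 kU/L).
IGE_HIGH_CLASS = 3


def ige_class_from_kUL(value: float) -> int:
    """Map a specific-IgE concentration (kU/L) to its ordinal class 0-6."""
    if value < 0 or not np.isfinite(value):
        raise ValidationError(f"IgE concentration must be a finite non-negative number, got {value!r}")
    if value > 100.0:
        return 6
    cls = 0
    for bound in _IGE_LOWER_BOUNDS:
        if value >= bound:
            cls += 1
    return cls


def resolve_ige_classes(profiles: pd.DataFrame) -> pd.Series:
    """Per-patient IgE class, deriving it from kU/L where only the concentration is given.

    Patients with neither a class nor a concentration get NaN.
    """
    cls = profiles.get("ige_class")
    cls = pd.Series(np.nan, index=profiles.index) if cls is None else cls.copy().astype(float)
    kul = profiles.get("ige_kUL")
    if kul is not None:
        derivable = cls.isna() & kul.notna()
        cls.loc[derivable] = [ige_class_from_kUL(v) for v in kul[derivable]]
    return cls


class IgeSplit(NamedTuple):
    high: list
    low: list
    excluded: list  # missing IgE, logged and left out


def split_by_ige(profiles: pd.DataFrame) -> IgeSplit:
    """Partition patients into IgE high (class >= III) and low (class < III).

    Patients with no IgE information are excluded with a warning rather
    than guessed into a group.
    """
    cls = resolve_ige_classes(profiles)
    excluded = profiles.loc[cls.isna(), "patient_id"].tolist()
    if excluded:
        logger.warning("IgE value missing for %d patient(s), excluded from IgE split: %s",
                       len(excluded), excluded)
    known = profiles[cls.notna()]
    kcls = cls[cls.notna()]
    high = known.loc[kcls >= IGE_HIGH_CLASS, "patient_id"].tolist()
    low = known.loc[kcls < IGE_HIGH_CLASS, "patient_id"].tolist()
    return IgeSplit(high=high, low=low, excluded=excluded)


def split_by_asthma(profiles: pd.DataFrame) -> tuple[list, list]:
    """Partition patients on the asthma comorbidity flag."""
    if "asthma" not in profiles.columns:
        raise ValidationError("profiles lack an 'asthma' column")
    flag = profiles["asthma"].astype(bool)
    return (
        profiles.loc[flag, "patient_id"].tolist(),
        profiles.loc[~flag, "patient_id"].tolist(),
    )


class CsmsSplit(NamedTuple):
    high: list
    low: list
    threshold: float  # half the cohort mean of per-patient mean CSMS
    per_patient_mean: dict


def split_by_csms(
    scores: pd.DataFrame, patient_ids: Iterable, period: tuple | None = None
) -> CsmsSplit:
    """Split a cohort at 50% of its mean CSMS.

    Each patient's mean daily CSMS over the period is computed; the
    cohort mean is the unweighted mean of those per-patient means; "low"
    is strictly below half of it, ties and everyone else go to "high".
    """
    ids = list(patient_ids)
    if not ids:
        raise EmptyCohortError("empty cohort for CSMS split")
    means = {pid: patient_mean_csms(scores, pid, period) for pid in ids}
    threshold = 0.5 * float(np.mean(list(means.values())))
    low = [pid for pid in ids if means[pid] < threshold]
    high = [pid for pid in ids if means[pid] >= threshold]
    return CsmsSplit(high=high, low=low, threshold=threshold, per_patient_mean=means)


@dataclass(frozen=True)
class SevereMildRule:
    """Which criteria the pooled severe/mild grouping conjoins.

    ``use_ige`` / ``use_csms``: require the IgE-high resp. CSMS-high
    criterion for "severe" (and their complements for "mild").
    ``asthma_mode``: ``"auto"`` (default) requires the asthma criterion
    only when the cohort contains at least one asthmatic — a cohort
    without asthmatics would otherwise have an empty severe group by
    construction; ``"require"`` always conjoins it; ``"ignore"`` never.
    """

    use_ige: bool = True
    use_csms: bool = True
    asthma_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.asthma_mode not in ("auto", "require", "ignore"):
            raise ValidationError(f"asthma_mode must be auto/require/ignore, got {self.asthma_mode!r}")


def severe_mild_groups(
    profiles: pd.DataFrame,
    scores: pd.DataFrame,
    period: tuple | None = None,
    rule: SevereMildRule = SevereMildRule(),
) -> tuple[list, list]:
    """Pooled severity groups: severe = every active criterion high, mild = every one low.

    Patients satisfying a mix of criteria belong to neither group.
    Returns ``(severe_ids, mild_ids)``.
    """
    ids = profiles["patient_id"].tolist()
    if not ids:
        raise EmptyCohortError("empty cohort for severe/mild grouping")
    cls = resolve_ige_classes(profiles)
    ige_high = dict(zip(profiles["patient_id"], cls >= IGE_HIGH_CLASS))
    ige_known = dict(zip(profiles["patient_id"], cls.notna()))
    asthma = dict(zip(profiles["patient_id"], profiles["asthma"].astype(bool)))
    csms = split_by_csms(scores, ids, period)
    csms_high = {pid: pid in set(csms.high) for pid in ids}

    use_asthma = rule.asthma_mode == "require" or (
        rule.asthma_mode == "auto" and any(asthma.values())
    )
    severe, mild = [], []
    for pid in ids:
        sev_crit, mild_crit = [], []
        if rule.use_ige:
            if not ige_known[pid]:
                continue  # cannot classify without IgE
            sev_crit.append(ige_high[pid])
            mild_crit.append(not ige_high[pid])
        if rule.use_csms:
            sev_crit.append(csms_high[pid])
            mild_crit.append(not csms_high[pid])
        if use_asthma:
            sev_crit.append(asthma[pid])
            mild_crit.append(not asthma[pid])
        if all(sev_crit):
            severe.append(pid)
        elif all(mild_crit):
            mild.append(pid)
    if not severe:
        logger.warning("severe group is empty under rule %s", rule)
    if not mild:
        logger.warning("mild group is empty under rule %s", rule)
    return severe, mild
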