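"""Full-analysis orchestration: inputs -> scores -> adjustment -> subgroup CCF table.

For one centre and period, :func:`run_analysis` scores the diaries,
builds the requested patient subgroups, constructs each predictor series
(a station's grass counts, the normalized search index, or the
birch-adjusted search index), and reports the best-lag cross-correlation
of every (subgroup x predictor) pair as one results row — the
machine-readable twin of the per-centre CCF tables such studies print.

An audit log records every subgroup-membership decision per patient and
flags low-n groups; empty groups are skipped with a warning rather than
failing the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path

import pandas as pd
import yaml

from pollencorr import cohorts, io
from pollencorr.crosscorr import LagWindow, align_series, best_lag, cross_correlation
from pollencorr.errors import EmptyCohortError, PollencorrError, ValidationError
from pollencorr.scoring import cohort_mean_csms_series, score_diary
from pollencorr.search_adjustment import adjust_search_series, birch_adjustment_factors, normalize_index

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "group", "n_patients", "predictor", "n_pairs",
    "ccf", "lag", "se", "p_two_sided", "strength",
]

SUBGROUP_CHOICES = ("cohort", "ige", "asthma", "csms", "severe_mild")


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor series: a pollen count or a (raw/adjusted) search index."""

    label: str
    kind: str  # pollen | search_raw | search_adjusted
    station: str | None = None  # pollen source and adjustment-factor source
    taxon: str = "grass"
    region: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pollen", "search_raw", "search_adjusted"):
            raise ValidationError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "pollen" and not self.station:
            raise ValidationError(f"pollen predictor {self.label!r} needs a station")
        if self.kind != "pollen" and not self.region:
            raise ValidationError(f"search predictor {self.label!r} needs a region")
        if self.kind == "search_adjusted" and not self.station:
            raise ValidationError(
                f"adjusted-search predictor {self.label!r} needs a station for the pollen factors"
            )


@dataclass
class AnalysisConfig:
    """Declarative description of one centre's analysis run."""

    period: tuple[str, str]
    centre: str
    predictors: list[PredictorSpec]
    inputs: dict = field(default_factory=dict)  # pollen/search/diary/patients paths
    subgroups: tuple[str, ...] = SUBGROUP_CHOICES
    lag_window: LagWindow = field(default_factory=LagWindow)
    best_lag_rule: str = "signed"
    degenerate_rule: str = "zero"  # both-taxa-zero day rule for adjustment factors
    severe_mild_rule: cohorts.SevereMildRule = field(default_factory=cohorts.SevereMildRule)
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValidationError("analysis needs at least one predictor")
        unknown = set(self.subgroups) - set(SUBGROUP_CHOICES)
        if unknown:
            raise ValidationError(f"unknown subgroups: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        preds = [PredictorSpec(**p) for p in raw.pop("predictors")]
        window = raw.pop("lag_window", None)
        kwargs = dict(raw)
        kwargs["predictors"] = preds
        kwargs["period"] = tuple(raw["period"])
        if window is not None:
            kwargs["lag_window"] = LagWindow(int(window["min_lag"]), int(window["max_lag"]))
        if "subgroups" in kwargs:
            kwargs["subgroups"] = tuple(kwargs["subgroups"])
        if "severe_mild_rule" in kwargs:
            kwargs["severe_mild_rule"] = cohorts.SevereMildRule(**kwargs["severe_mild_rule"])
        return cls(**kwargs)


def _restrict_period(series: pd.Series, period) -> pd.Series:
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    return series[(series.index >= start) & (series.index <= end)]


def build_predictor_series(
    spec: PredictorSpec, pollen: pd.DataFrame, search: pd.DataFrame, period, degenerate_rule="zero"
) -> pd.Series:
    """Materialize one predictor spec into a daily value series over the period."""
    if spec.kind == "pollen":
        return _restrict_period(io.pollen_series(pollen, spec.station, spec.taxon), period)
    raw = _restrict_period(io.search_series(search, spec.region), period)
    index = normalize_index(raw, region=spec.region)
    if spec.kind == "search_raw":
        return index.values.rename(spec.label)
    grass = _restrict_period(io.pollen_series(pollen, spec.station, "grass"), period)
    birch = _restrict_period(io.pollen_series(pollen, spec.station, "birch"), period)
    factors = birch_adjustment_factors(grass, birch, degenerate=degenerate_rule)
    return adjust_search_series(index, factors).values.rename(spec.label)


def _build_groups(config: AnalysisConfig, profiles: pd.DataFrame, scores: pd.DataFrame, audit: list):
    """Expand the subgroup toggles into labelled patient-id lists, auditing every decision."""
    all_ids = profiles["patient_id"].tolist()
    groups: list[tuple[str, list]] = []

    def record(analysis: str, label: str, ids: list) -> None:
        groups.append((label, ids))
        for pid in ids:
            audit.append({"event": "membership", "analysis": analysis, "group": label, "patient_id": pid})

    for name in config.subgroups:
        if name == "cohort":
            record("cohort", "cohort_mean", all_ids)
        elif name == "ige":
            split = cohorts.split_by_ige(profiles)
            record("ige", "ige_high", split.high)
            record("ige", "ige_low", split.low)
            for pid in split.excluded:
                audit.append({"event": "excluded", "analysis": "ige",
                              "group": None, "patient_id": pid, "reason": "missing IgE"})
        elif name == "asthma":
            asthma, no_asthma = cohorts.split_by_asthma(profiles)
            record("asthma", "asthma", asthma)
            record("asthma", "no_asthma", no_asthma)
        elif name == "csms":
            split = cohorts.split_by_csms(scores, all_ids, config.period)
            record("csms", "csms_high", split.high)
            record("csms", "csms_low", split.low)
        elif name == "severe_mild":
            severe, mild = cohorts.severe_mild_groups(
                profiles, scores, config.period, config.severe_mild_rule
            )
            record("severe_mild", "severe", severe)
            record("severe_mild", "mild", mild)
    return groups


def run_analysis_frames(
    config: AnalysisConfig,
    pollen: pd.DataFrame,
    search: pd.DataFrame,
    diary: pd.DataFrame,
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Run the analysis on in-memory tables; see :func:`run_analysis`."""
    profiles = patients[patients["centre"] == config.centre]
    if profiles.empty:
        raise EmptyCohortError(f"no patients for centre {config.centre!r}")
    centre_ids = set(profiles["patient_id"])
    scores = score_diary(diary[diary["patient_id"].isin(centre_ids)])

    audit: list[dict] = []
    groups = _build_groups(config, profiles, scores, audit)
    predictors = {
        spec.label: build_predictor_series(spec, pollen, search, config.period, config.degenerate_rule)
        for spec in config.predictors
    }

    rows = []
    for label, ids in groups:
        if not ids:
            logger.warning("subgroup %r is empty; skipped", label)
            audit.append({"event": "skipped", "analysis": label, "group": label,
                          "patient_id": None, "reason": "empty subgroup"})
            continue
        if len(ids) < 5:
            logger.warning("subgroup %r has only %d patient(s); results are fragile", label, len(ids))
            audit.append({"event": "low_n", "analysis": label, "group": label,
                          "patient_id": None, "reason": f"n={len(ids)}"})
        csms, _counts = cohort_mean_csms_series(scores, ids, config.period)
        for spec in config.predictors:
            try:
                xv, yv, n = align_series(predictors[spec.label], csms)
                results = cross_correlation(xv, yv, config.lag_window)
                top = best_lag(results, rule=config.best_lag_rule)
            except PollencorrError as exc:
                raise type(exc)(f"group {label!r}, predictor {spec.label!r}: {exc}") from exc
            rows.append(
                {
                    "group": label,
                    "n_patients": len(ids),
                    "predictor": spec.label,
                    "n_pairs": n,
                    "ccf": top.ccf,
                    "lag": top.lag,
                    "se": top.se,
                    "p_two_sided": top.p_two_sided,
                    "strength": top.strength,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), audit


def run_analysis(config: AnalysisConfig) -> tuple[pd.DataFrame, list]:
    """Run the full analysis from the CSV inputs named in ``config.inputs``.

    Returns ``(results, audit)``: one row per (subgroup x predictor) with
    the best-lag CCF, its SE, two-sided p and strength band, plus the
    audit log of membership decisions and warnings. Deterministic given
    identical inputs and config.
    """
    pollen = io.read_pollen(config.inputs["pollen"])
    search = io.read_search(config.inputs["search"])
    diary = io.read_diary(config.inputs["diary"])
    patients = io.read_patients(config.inputs["patients"])
    return run_analysis_frames(config, pollen, search, diary, patients)


def _round3(x: float) -> str:
    return str(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN))


def band_p(p: float) -> str:
    """Print band for a p-value: '<0.001', '<0.01', or the 3-decimal value."""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return "<0.01"
    return _round3(p)


def format_results_table(results: pd.DataFrame) -> str:
    """Render a results frame as CSV text with table-style rounding.

    ccf and se are printed to 3 decimals (round-half-even), p as its band;
    the exact p is kept in a machine-readable column.
    """
    header = "group,n_patients,predictor,n_pairs,ccf,lag,se,p,p_exact,strength"
    lines = [header]
    for _, r in results.iterrows():
        lines.append(
            ",".join(
                [
                    str(r["group"]),
                    str(int(r["n_patients"])),
                    str(r["predictor"]),
                    str(int(r["n_pairs"])),
                    _round3(r["ccf"]),
                    str(int(r["lag"])),
                    _round3(r["se"]),
                    band_p(float(r["p_two_sided"])),
                    repr(float(r["p_two_sided"])),
                    str(r["strength"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_outputs(results: pd.DataFrame, audit: list, out_dir) -> dict:
    """Write results.csv (formatted), results_raw.csv and audit.csv; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formatted = out / "results.csv"
    formatted.write_text(format_results_table(results))
    raw = out / "results_raw.csv"
    results.to_csv(raw, index=False)
    audit_path = out / "audit.csv"
    pd.DataFrame(audit).to_csv(audit_path, index=False)
    return {"results": str(formatted), "results_raw": str(raw), "audit": str(audit_path)}
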