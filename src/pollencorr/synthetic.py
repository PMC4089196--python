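"""Synthetic study generator with known ground truth.

Real inputs for this kind of analysis — volumetric pollen-trap counts,
regional search-volume indices and per-patient symptom diaries — are not
publicly deposited, so the pipeline is validated on coupled synthetic
datasets whose generative parameters are recorded as ground truth:

* **Pollen seasons** are unimodal Gaussian pulses with multiplicative
  log-normal day-to-day noise, truncated at +/-3 sd. The grass season
  peaks in mid-June and spans the whole May-July diary window; the birch
  season peaks in late April, so only its tail (through roughly mid-May)
  intrudes into the window — the phasing that makes early-season search
  contamination possible.
* **The search index** is a baseline plus a weighted mixture of the
  grass and birch counts *advanced by ``lead_days``* (queries anticipate
  exposure: pollen forecasts are in the media before symptoms peak),
  plus Gaussian noise, clipped at zero. With a 1-day lead the best
  cross-correlation lag against a grass-driven outcome is -1 by
  construction.
* **Diaries** arise from a latent daily burden
  ``coupling * grass_t / max(grass) + noise``; each of the six symptom
  grades is the count of fixed ordinal cut-points (0.5, 1.5, 2.5) below
  the burden plus independent per-symptom noise, and medication flags
  fire with class-specific probabilities once the same-day RTSS crosses
  a class threshold. Severe patients get a larger coupling (and IgE
  class >= III), mild patients a smaller one (class < III), so the
  severe/mild CCF contrast has a known direction.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pollencorr.errors import AlignmentError, ValidationError
from pollencorr.scoring import MED_COLUMNS, SYMPTOM_COLUMNS

#: Ordinal cut-points turning the latent burden into a 0-3 grade.
GRADE_CUTPOINTS = (0.5, 1.5, 2.5)

#: Diary window of the emulated study season.
DEFAULT_PERIOD = ("2009-05-01", "2009-07-31")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SeasonParams:
    """Unimodal pollen-season pulse for one taxon.

    ``peak_day`` is the calendar date of maximal release, ``duration_sd``
    the Gaussian width in days, ``amplitude`` the noise-free peak count in
    grains/m3 per 24 h, and ``dispersion`` the sigma of the multiplicative
    log-normal day-to-day noise (0 gives the exact pulse).
    """

    peak_day: str
    duration_sd: float
    amplitude: float
    dispersion: float = 0.35
    taxon: str = "grass"

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration_sd <= 0:
            raise ValidationError("amplitude and duration_sd must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")


@dataclass(frozen=True)
class SearchParams:
    """Generative model of the raw search-volume signal.

    ``w_grass`` / ``w_birch`` weight the grass- and birch-driven query
    interest; ``lead_days`` advances the pollen drivers (queries precede
    exposure); ``baseline`` is season-independent query volume in raw
    index units; ``noise_sd`` the sd of additive Gaussian noise.
    """

    w_grass: float = 0.8
    w_birch: float = 0.8
    lead_days: int = 1
    baseline: float = 25.0
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.w_grass < 0 or self.w_birch < 0 or self.w_grass + self.w_birch == 0:
            raise ValidationError("mixture weights must be >= 0 with a positive sum")
        if self.lead_days < 0:
            raise ValidationError("lead_days must be >= 0")


@dataclass(frozen=True)
class PatientParams:
    """Cohort composition and symptom/medication response model."""

    n_patients: int = 20
    severity_mix: tuple[float, float] = (0.5, 0.5)  # (severe, mild) proportions
    coupling_severe: float = 3.0  # latent-burden gain at peak pollen
    coupling_mild: float = 0.5
    symptom_noise_sd: float = 0.4
    #: RTSS threshold and firing probability per medication class.
    med_thresholds: tuple[tuple[str, int, float], ...] = (
        ("med_chromone", 3, 0.35),
        ("med_antihistamine", 4, 0.55),
        ("med_corticosteroid", 6, 0.45),
        ("med_leukotriene", 10, 0.15),
    )
    missing_day_rate: float = 0.05
    asthma_frac_severe: float = 0.25

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.severity_mix):
            raise ValidationError("severity_mix proportions must be non-negative and sum to 1")
        if not 0 <= self.missing_day_rate < 1:
            raise ValidationError("missing_day_rate must be in [0, 1)")


@dataclass
class StudyConfig:
    """Everything needed to simulate one centre's study."""

    period: tuple[str, str] = DEFAULT_PERIOD
    centre: str = "CentreA"
    station: str = "StationA"
    region: str = "RegionA"
    grass_season: SeasonParams = field(
        default_factory=lambda: SeasonParams(
            peak_day="2009-06-15", duration_sd=16.0, amplitude=80.0, taxon="grass"
        )
    )
    birch_season: SeasonParams = field(
        default_factory=lambda: SeasonParams(
            peak_day="2009-04-25", duration_sd=9.0, amplitude=120.0, taxon="birch"
        )
    )
    search: SearchParams = field(default_factory=SearchParams)
    patients: PatientParams = field(default_factory=PatientParams)


def simulate_pollen_season(params: SeasonParams, period: tuple, seed) -> pd.Series:
    """Daily pollen counts over ``period`` for one season pulse.

    count_t = amplitude * exp(-(t - peak)^2 / (2 sd^2)) * LogNormal(0, dispersion),
    zeroed outside peak +/- 3 sd and clipped at zero.
    """
    rng = _rng(seed)
    idx = pd.date_range(period[0], period[1], freq="D")
    peak = pd.Timestamp(params.peak_day)
    t = (idx - peak).days.to_numpy(dtype=float)
    pulse = params.amplitude * np.exp(-(t**2) / (2.0 * params.duration_sd**2))
    pulse[np.abs(t) > 3.0 * params.duration_sd] = 0.0
    noise = rng.lognormal(mean=0.0, sigma=params.dispersion, size=len(idx)) if params.dispersion > 0 else 1.0
    out = pd.Series(np.clip(pulse * noise, 0.0, None), index=idx, name=params.taxon)
    return out


def simulate_search_index(
    grass: pd.Series, birch: pd.Series, params: SearchParams, seed
) -> pd.Series:
    """Raw (unnormalized) search-volume signal driven by advanced pollen counts.

    The output covers every date whose ``lead_days``-ahead pollen value
    exists in the inputs; simulate the pollen a few days past the study
    window to get a search series covering the whole window.
    """
    rng = _rng(seed)
    if not grass.index.equals(birch.index):
        raise AlignmentError("grass and birch series must share their date index")
    lead = pd.Timedelta(days=params.lead_days)
    out_idx = grass.index[(grass.index + lead) <= grass.index.max()]
    if len(out_idx) == 0:
        raise ValidationError("pollen series too short for the requested lead")
    g = grass.reindex(out_idx + lead).to_numpy()
    b = birch.reindex(out_idx + lead).to_numpy()
    raw = (
        params.baseline
        + params.w_grass * g
        + params.w_birch * b
        + (rng.normal(0.0, params.noise_sd, len(out_idx)) if params.noise_sd > 0 else 0.0)
    )
    return pd.Series(np.clip(raw, 0.0, None), index=out_idx, name="search_raw")


def simulate_patients(params: PatientParams, seed, centre: str = "CentreA") -> pd.DataFrame:
    """Patient profiles with ground-truth severity.

    Severe patients draw grass-specific IgE log-uniformly from class III
    and above (3.5-100 kU/L), mild patients from below class III
    (0.05-3.4 kU/L); asthma is assigned to a fraction of the severe
    patients; retrospective RTSS is at least 8 (the eligibility screen).
    The ``severity`` column is generator truth, not an observable.
    """
    from pollencorr.cohorts import ige_class_from_kUL

    rng = _rng(seed)
    n = params.n_patients
    n_severe = int(round(n * params.severity_mix[0]))
    severity = np.array(["severe"] * n_severe + ["mild"] * (n - n_severe))
    ige = np.where(
        severity == "severe",
        np.exp(rng.uniform(np.log(3.5), np.log(100.0), n)),
        np.exp(rng.uniform(np.log(0.05), np.log(3.4), n)),
    )
    asthma = (severity == "severe") & (rng.random(n) < params.asthma_frac_severe)
    rrtss = rng.integers(8, 19, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "centre": centre,
            "ige_kUL": np.round(ige, 2),
            "ige_class": [ige_class_from_kUL(v) for v in np.round(ige, 2)],
            "asthma": asthma,
            "rrtss": rrtss,
            "severity": severity,
        }
    )


def simulate_diaries(
    profiles: pd.DataFrame, grass: pd.Series, params: PatientParams, seed
) -> pd.DataFrame:
    """Per-patient daily diaries driven by the grass-pollen series.

    Latent burden = coupling * grass_t / max(grass) + noise; each symptom
    grade counts the ordinal cut-points below burden + independent
    per-symptom noise; medication flags fire with their class probability
    once the day's RTSS reaches the class threshold; a fraction of
    patient-days is dropped to emulate incomplete diaries.
    """
    rng = _rng(seed)
    if grass.empty:
        raise ValidationError("grass series is empty")
    peak = float(grass.max())
    rel = (grass / peak).to_numpy() if peak > 0 else np.zeros(len(grass))
    dates = grass.index
    n_days = len(dates)
    cuts = np.asarray(GRADE_CUTPOINTS)

    rows = []
    for _, patient in profiles.iterrows():
        coupling = params.coupling_severe if patient["severity"] == "severe" else params.coupling_mild
        burden = coupling * rel
        if params.symptom_noise_sd > 0:
            eta = rng.normal(0.0, params.symptom_noise_sd, (n_days, len(SYMPTOM_COLUMNS)))
        else:
            eta = np.zeros((n_days, len(SYMPTOM_COLUMNS)))
        latent = burden[:, None] + eta  # (days, symptoms)
        grades = (latent[:, :, None] > cuts[None, None, :]).sum(axis=2).astype(int)
        rtss = grades.sum(axis=1)
        meds = {}
        for med, threshold, prob in params.med_thresholds:
            meds[med] = ((rtss >= threshold) & (rng.random(n_days) < prob)).astype(int)
        keep = rng.random(n_days) >= params.missing_day_rate
        for d in range(n_days):
            if not keep[d]:
                continue
            row = {"patient_id": patient["patient_id"], "date": dates[d]}
            row.update(dict(zip(SYMPTOM_COLUMNS, grades[d])))
            row.update({med: int(meds[med][d]) for med in MED_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """In-memory synthetic study: the four input tables plus ground truth."""

    pollen: pd.DataFrame
    search: pd.DataFrame
    diary: pd.DataFrame
    patients: pd.DataFrame
    truth: dict


def simulate_study(config: StudyConfig = None, seed: int = 0) -> StudyBundle:
    """Simulate one centre's complete study under ``config``.

    Pollen is simulated a few days past the diary window so the search
    signal (which looks ``lead_days`` ahead) covers the whole window; all
    emitted tables are restricted to the window.
    """
    config = config or StudyConfig()
    if config.patients.n_patients < 1:
        raise ValidationError("study needs at least one patient")
    rng = _rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    start, end = pd.Timestamp(config.period[0]), pd.Timestamp(config.period[1])
    ext_end = end + pd.Timedelta(days=config.search.lead_days)
    ext = (start, ext_end)

    grass = simulate_pollen_season(config.grass_season, ext, seeds[0])
    birch = simulate_pollen_season(config.birch_season, ext, seeds[1])
    search_raw = simulate_search_index(grass, birch, config.search, seeds[2])

    window = pd.date_range(start, end, freq="D")
    grass_w, birch_w = grass.reindex(window), birch.reindex(window)
    search_w = search_raw.reindex(window)

    profiles = simulate_patients(config.patients, seeds[3], centre=config.centre)
    diary = simulate_diaries(profiles, grass_w, config.patients, seeds[4])

    pollen = pd.concat(
        [
            pd.DataFrame(
                {"station": config.station, "date": window, "taxon": taxon, "count": s.to_numpy()}
            )
            for taxon, s in (("grass", grass_w), ("birch", birch_w))
        ],
        ignore_index=True,
    )
    search = pd.DataFrame(
        {"region": config.region, "date": window, "index": search_w.to_numpy()}
    )
    truth = {
        "seed": int(seed),
        "lead_days": config.search.lead_days,
        "w_grass": config.search.w_grass,
        "w_birch": config.search.w_birch,
        "coupling_severe": config.patients.coupling_severe,
        "coupling_mild": config.patients.coupling_mild,
        "severe_patients": profiles.loc[profiles["severity"] == "severe", "patient_id"].tolist(),
        "mild_patients": profiles.loc[profiles["severity"] == "mild", "patient_id"].tolist(),
        "expected_best_lag_search": -config.search.lead_days,
    }
    return StudyBundle(pollen=pollen, search=search, diary=diary, patients=profiles, truth=truth)


def generate_study(config: StudyConfig = None, seed: int = 0, out_dir="study") -> dict:
    """Write a simulated study bundle to CSV files plus ``truth.json``.

    Returns a dict of the written paths. ``patients.csv`` omits the
    ground-truth severity column (it lives in ``truth.json`` only).
    """
    bundle = simulate_study(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv" for name in ("pollen", "search", "diary", "patients")}
    for df, path in (
        (bundle.pollen, paths["pollen"]),
        (bundle.search, paths["search"]),
        (bundle.diary, paths["diary"]),
        (bundle.patients.drop(columns=["severity"]), paths["patients"]),
    ):
        df = df.copy()
        if "date" in df.columns:
            df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth, indent=2))
    paths["truth"] = truth_path
    return {k: str(v) for k, v in paths.items()}
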