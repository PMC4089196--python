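"""CSV readers/writers for the pipeline's tabular interfaces.

Schemas (one row per observation, ISO-8601 dates):

* ``pollen.csv``   — station, date, taxon (grass|birch), count (grains/m3/24h)
* ``search.csv``   — region, date, index (>= 0), optional provenance
* ``diary.csv``    — patient_id, date, six symptom grades 0-3, four 0/1 med flags
* ``patients.csv`` — patient_id, centre, ige_kUL?, ige_class?, asthma (0/1), rrtss?
* ``scores.csv``   — patient_id, date, rtss, trms, csms
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pollencorr.errors import ValidationError

POLLEN_TAXA = ("grass", "birch")


def _read(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file {path} is missing columns: {missing}")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def read_pollen(path) -> pd.DataFrame:
    df = _read(path, ["station", "date", "taxon", "count"], "pollen")
    bad = ~df["taxon"].isin(POLLEN_TAXA)
    if bad.any():
        raise ValidationError(f"unknown pollen taxa: {sorted(df.loc[bad, 'taxon'].unique())}")
    if (df["count"] < 0).any():
        raise ValidationError("pollen counts must be non-negative")
    return df


def pollen_series(pollen: pd.DataFrame, station: str, taxon: str) -> pd.Series:
    """Daily count series for one (station, taxon); absent days stay gaps."""
    sub = pollen[(pollen["station"] == station) & (pollen["taxon"] == taxon)]
    if sub.empty:
        raise ValidationError(f"no pollen rows for station {station!r}, taxon {taxon!r}")
    s = sub.set_index("date")["count"].sort_index()
    s.name = f"{taxon}@{station}"
    return s


def read_search(path) -> pd.DataFrame:
    df = _read(path, ["region", "date", "index"], "search")
    if (df["index"] < 0).any():
        raise ValidationError("search index values must be non-negative")
    return df


def search_series(search: pd.DataFrame, region: str) -> pd.Series:
    sub = search[search["region"] == region]
    if sub.empty:
        raise ValidationError(f"no search rows for region {region!r}")
    s = sub.set_index("date")["index"].sort_index()
    s.name = f"search@{region}"
    return s


def write_search(df_or_series, path, region: str | None = None, provenance: str = "raw") -> None:
    """Emit a search series back in the search.csv schema with a provenance column."""
    if isinstance(df_or_series, pd.Series):
        out = pd.DataFrame(
            {
                "region": region or "",
                "date": df_or_series.index.strftime("%Y-%m-%d"),
                "index": df_or_series.to_numpy(),
                "provenance": provenance,
            }
        )
    else:
        out = df_or_series
    out.to_csv(path, index=False)


def read_diary(path) -> pd.DataFrame:
    from pollencorr.scoring import SYMPTOM_COLUMNS

    return _read(path, ["patient_id", "date", *SYMPTOM_COLUMNS], "diary")


def read_patients(path) -> pd.DataFrame:
    df = _read(path, ["patient_id", "centre", "asthma"], "patients")
    if df["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in patients file")
    df["asthma"] = df["asthma"].astype(bool)
    return df


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    return _read(path, ["patient_id", "date", "rtss", "trms", "csms"], "scores")
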