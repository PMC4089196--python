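import pandas as pd
import pytest

import pollencorr as pc

PERIOD = ("2009-05-01", "2009-07-31")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study (20 patients, 92 days, seed 7)."""
    return pc.simulate_study(seed=7)


@pytest.fixture(scope="session")
def default_config():
    return pc.AnalysisConfig(
        period=PERIOD,
        centre="CentreA",
        predictors=[
            pc.PredictorSpec("grass", "pollen", station="StationA"),
            pc.PredictorSpec("search_raw", "search_raw", region="RegionA"),
            pc.PredictorSpec("search_adj", "search_adjusted", station="StationA", region="RegionA"),
        ],
    )


@pytest.fixture
def small_diary():
    """Two patients, three days; patient P2 misses the middle day."""
    rows = []
    grades = {
        ("P1", "2009-06-01"): (1, 2, 0, 3, 0, 1),
        ("P1", "2009-06-02"): (0, 0, 0, 0, 0, 0),
        ("P1", "2009-06-03"): (3, 3, 3, 3, 3, 3),
        ("P2", "2009-06-01"): (1, 1, 1, 1, 1, 1),
        ("P2", "2009-06-03"): (2, 2, 2, 0, 0, 0),
    }
    meds = {("P1", "2009-06-03"): dict(med_antihistamine=1, med_corticosteroid=1)}
    for (pid, date), g in grades.items():
        row = dict(
            patient_id=pid,
            date=date,
            sneezing=g[0],
            runny_nose=g[1],
            itchy_nose=g[2],
            nasal_congestion=g[3],
            tearing=g[4],
            itchy_eyes=g[5],
            med_chromone=0,
            med_antihistamine=0,
            med_corticosteroid=0,
            med_leukotriene=0,
        )
        row.update(meds.get((pid, date), {}))
        rows.append(row)
    return pd.DataFrame(rows)


def daily_series(values, start="2009-06-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    return pd.Series(list(values), index=idx, dtype=float)
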