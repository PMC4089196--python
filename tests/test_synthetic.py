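"""Synthetic study generator: determinism, season shapes, coupling, round-trips."""

import numpy as np
import pandas as pd
import pytest

import pollencorr as pc
from pollencorr import io
from pollencorr.crosscorr import LagWindow, align_series, best_lag, cross_correlation
from pollencorr.errors import ValidationError
from pollencorr.scoring import SYMPTOM_COLUMNS, score_diary
from pollencorr.synthetic import DEFAULT_PERIOD, StudyConfig

GRASS = pc.SeasonParams(peak_day="2009-06-15", duration_sd=16.0, amplitude=80.0, taxon="grass")
BIRCH = pc.SeasonParams(peak_day="2009-04-25", duration_sd=9.0, amplitude=120.0, taxon="birch")


class TestPollenSeason:
    def test_noise_free_limit_is_exact_gaussian_pulse(self):
        params = pc.SeasonParams("2009-06-15", 16.0, 80.0, dispersion=0.0)
        s = pc.simulate_pollen_season(params, DEFAULT_PERIOD, seed=0)
        t = (s.index - pd.Timestamp("2009-06-15")).days.to_numpy(dtype=float)
        expected = 80.0 * np.exp(-(t**2) / (2 * 16.0**2))
        np.testing.assert_allclose(s.to_numpy(), expected, rtol=1e-12)

    def test_deterministic_under_seed(self):
        a = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=5)
        b = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_zero_outside_three_sd(self):
        params = pc.SeasonParams("2009-06-15", 5.0, 80.0, dispersion=0.3)
        s = pc.simulate_pollen_season(params, DEFAULT_PERIOD, seed=1)
        far = abs((s.index - pd.Timestamp("2009-06-15")).days) > 15
        assert (s[far] == 0).all() and (s[~far] > 0).all()

    def test_birch_mass_precedes_grass_mass(self):
        period = ("2009-04-01", "2009-07-31")
        grass = pc.simulate_pollen_season(GRASS, period, seed=2)
        birch = pc.simulate_pollen_season(BIRCH, period, seed=3)

        def weighted_mean_day(s):
            w = s.to_numpy()
            days = np.arange(len(s))
            return (days * w).sum() / w.sum()

        assert weighted_mean_day(birch) < weighted_mean_day(grass)


class TestSearchIndex:
    def test_affine_in_grass_without_birch_lead_or_noise(self):
        grass = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=0)
        birch = grass * 0.0
        params = pc.SearchParams(w_grass=0.7, w_birch=0.0, lead_days=0, baseline=10.0, noise_sd=0.0)
        raw = pc.simulate_search_index(grass, birch, params, seed=0)
        np.testing.assert_allclose(raw.to_numpy(), 10.0 + 0.7 * grass.to_numpy(), rtol=1e-12)

    def test_lead_shifts_peak_earlier(self):
        params_season = pc.SeasonParams("2009-06-15", 16.0, 80.0, dispersion=0.0)
        grass = pc.simulate_pollen_season(params_season, ("2009-05-01", "2009-08-05"), seed=0)
        birch = grass * 0.0
        raw = pc.simulate_search_index(
            grass, birch, pc.SearchParams(w_birch=0.0, lead_days=1, noise_sd=0.0), seed=0
        )
        assert raw.idxmax() == grass.idxmax() - pd.Timedelta(days=1)

    def test_flat_baseline_outside_season(self):
        idx = pd.date_range("2009-05-01", "2009-05-30")
        zero = pd.Series(0.0, index=idx)
        raw = pc.simulate_search_index(
            zero, zero, pc.SearchParams(baseline=30.0, lead_days=0, noise_sd=0.0), seed=0
        )
        assert (raw == 30.0).all()

    def test_noise_free_search_recovers_lead_as_negative_lag(self):
        """With no birch and no noise, CCF peaks at lag -lead_days, approaching 1.

        The truncated-sum estimator uses full-series moments, so even a
        perfect shifted copy scores slightly below 1 at a nonzero lag.
        """
        grass = pc.simulate_pollen_season(GRASS, ("2009-05-01", "2009-08-03"), seed=4)
        birch = grass * 0.0
        raw = pc.simulate_search_index(
            grass, birch, pc.SearchParams(w_birch=0.0, lead_days=3, noise_sd=0.0, baseline=0.0),
            seed=0,
        )
        xv, yv, _ = align_series(raw, grass)
        top = best_lag(cross_correlation(xv, yv, LagWindow(-7, 7)))
        assert top.lag == -3
        assert top.ccf > 0.95


class TestPatientsAndDiaries:
    def test_cohort_size_and_determinism(self):
        params = pc.PatientParams(n_patients=22)
        a = pc.simulate_patients(params, seed=1)
        b = pc.simulate_patients(params, seed=1)
        assert len(a) == 22
        pd.testing.assert_frame_equal(a, b)

    def test_all_severe_mix_gives_high_ige_classes(self):
        params = pc.PatientParams(n_patients=10, severity_mix=(1.0, 0.0))
        profiles = pc.simulate_patients(params, seed=0)
        assert (profiles["ige_class"] >= 3).all()
        assert (profiles["rrtss"] >= 8).all()

    def test_mild_patients_have_low_ige(self):
        params = pc.PatientParams(n_patients=10, severity_mix=(0.0, 1.0))
        profiles = pc.simulate_patients(params, seed=0)
        assert (profiles["ige_class"] < 3).all()
        assert not profiles["asthma"].any()

    def test_zero_coupling_zero_noise_gives_all_zero_scores(self):
        grass = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=0)
        params = pc.PatientParams(
            n_patients=4, coupling_severe=0.0, coupling_mild=0.0,
            symptom_noise_sd=0.0, missing_day_rate=0.0,
        )
        profiles = pc.simulate_patients(params, seed=0)
        diary = pc.simulate_diaries(profiles, grass, params, seed=0)
        scores = score_diary(diary)
        assert (scores["csms"] == 0).all()

    def test_diaries_respect_scoring_invariants(self, bundle):
        for col in SYMPTOM_COLUMNS:
            assert bundle.diary[col].isin([0, 1, 2, 3]).all()
        scores = score_diary(bundle.diary)  # raises if any invariant is broken
        assert (scores["rtss"] <= 18).all()

    def test_diaries_deterministic(self):
        grass = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=0)
        params = pc.PatientParams(n_patients=5)
        profiles = pc.simulate_patients(params, seed=3)
        a = pc.simulate_diaries(profiles, grass, params, seed=9)
        b = pc.simulate_diaries(profiles, grass, params, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_severe_score_higher_at_peak(self):
        """Monte Carlo: severe mean CSMS exceeds mild mean CSMS around the peak."""
        grass = pc.simulate_pollen_season(GRASS, DEFAULT_PERIOD, seed=0)
        params = pc.PatientParams(n_patients=10, missing_day_rate=0.0)
        wins = 0
        reps = 100
        for rep in range(reps):
            profiles = pc.simulate_patients(params, seed=rep)
            diary = pc.simulate_diaries(profiles, grass, params, seed=10_000 + rep)
            scores = score_diary(diary)
            peak = ("2009-06-08", "2009-06-22")
            sev = profiles.loc[profiles["severity"] == "severe", "patient_id"]
            mld = profiles.loc[profiles["severity"] == "mild", "patient_id"]
            m_sev, _ = pc.cohort_mean_csms_series(scores, sev, peak)
            m_mld, _ = pc.cohort_mean_csms_series(scores, mld, peak)
            wins += m_sev.mean() > m_mld.mean()
        assert wins == reps


class TestGenerateStudy:
    def test_round_trip_through_all_readers(self, tmp_path):
        paths = pc.generate_study(seed=0, out_dir=tmp_path)
        pollen = io.read_pollen(paths["pollen"])
        search = io.read_search(paths["search"])
        diary = io.read_diary(paths["diary"])
        patients = io.read_patients(paths["patients"])
        assert set(pollen["taxon"]) == {"grass", "birch"}
        assert len(search) == 92
        assert patients["patient_id"].is_unique
        assert score_diary(diary)["csms"].ge(0).all()
        assert "severity" not in patients.columns  # truth stays out of observables

    def test_truth_records_generative_parameters(self, tmp_path):
        import json

        paths = pc.generate_study(seed=0, out_dir=tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["lead_days"] == 1
        assert truth["expected_best_lag_search"] == -1
        assert len(truth["severe_patients"]) + len(truth["mild_patients"]) == 20

    def test_zero_patients_rejected(self):
        with pytest.raises(ValidationError):
            StudyConfig(patients=pc.PatientParams(n_patients=0))
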