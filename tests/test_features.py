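"""Cleaning pipeline: mood interpolation, zero-filling, outlier and
participant filtering."""

import numpy as np
import pandas as pd
import pytest

from resilsense import synthetic as syn
from resilsense.features import (
    clean_pipeline,
    drop_incomplete_hours,
    fill_step_sleep_missing,
    filter_outliers,
    filter_participants,
    interpolate_mood,
)
from resilsense.indicators import FEATURES


def _hourly_frame(pid, start, sleep_by_hour, n_hours=None):
    """Build a minimal hourly table with a given sleep profile."""
    n_hours = n_hours or len(sleep_by_hour)
    hours = pd.date_range(start, periods=n_hours, freq="h")
    sleep = np.zeros(n_hours)
    sleep[: len(sleep_by_hour)] = sleep_by_hour
    return pd.DataFrame(
        {
            "participant_id": pid,
            "period": "BL",
            "hour_start": hours,
            "step_count": 100,
            "sleep_seconds": sleep,
            "in_bed_seconds": sleep,
            "mean_heart_rate": 70.0,
        }
    )


class TestInterpolateMood:
    def test_fill_window_between_wake_anchors(self):
        """One EMA of 7 at 18:00 with wake at 08:00 fills forward to the
        wake ending the next >2 h sleep cycle, values in [7, 7.2)."""
        # sleep 00:00-07:59 (8h) then awake; next night sleep 23:00-06:59
        day = np.zeros(48)
        day[0:8] = 3600  # wake anchor at hour 8
        day[23:31] = 3600  # next cycle ends hour 31 (07:00 next day)
        hourly = _hourly_frame("P1", "2020-01-01", day)
        ema = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "timestamp": [pd.Timestamp("2020-01-01 18:00")],
                "mood": [7],
            }
        )
        mood = interpolate_mood(ema, hourly, noise_seed=0)
        hours = sorted(mood["hour_index"])
        base = int(pd.Timestamp("2020-01-01").timestamp() // 3600)
        assert hours[0] == base + 8
        assert hours[-1] == base + 30  # last filled hour before the 07:00 wake
        assert mood["mood"].between(7.0, 7.2).all()

    def test_same_day_emas_are_averaged(self):
        day = np.zeros(48)
        day[0:8] = 3600
        day[23:31] = 3600
        hourly = _hourly_frame("P1", "2020-01-01", day)
        ema = pd.DataFrame(
            {
                "participant_id": ["P1", "P1"],
                "timestamp": pd.to_datetime(["2020-01-01 12:00", "2020-01-01 19:00"]),
                "mood": [6, 7],
            }
        )
        mood = interpolate_mood(ema, hourly, noise_seed=0)
        assert mood["mood"].between(6.5, 6.7).all()

    def test_fill_capped_at_24_hours(self):
        # no qualifying sleep cycle after the EMA at all
        hourly = _hourly_frame("P1", "2020-01-01", np.zeros(72))
        ema = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "timestamp": [pd.Timestamp("2020-01-01 18:00")],
                "mood": [5],
            }
        )
        mood = interpolate_mood(ema, hourly, noise_seed=0)
        base = int(pd.Timestamp("2020-01-01").timestamp() // 3600)
        assert max(mood["hour_index"]) < base + 18 + 24

    def test_out_of_range_ema_rejected(self):
        hourly = _hourly_frame("P1", "2020-01-01", np.zeros(24))
        ema = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "timestamp": [pd.Timestamp("2020-01-01 18:00")],
                "mood": [12],
            }
        )
        with pytest.raises(ValueError):
            interpolate_mood(ema, hourly)

    def test_short_nap_is_not_a_cycle_anchor(self):
        """A <=2 h sleep run neither ends the fill window nor qualifies as
        the next cycle."""
        day = np.zeros(48)
        day[0:8] = 3600
        day[14] = 3000  # 50-minute nap
        day[23:31] = 3600
        hourly = _hourly_frame("P1", "2020-01-01", day)
        ema = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "timestamp": [pd.Timestamp("2020-01-01 18:00")],
                "mood": [7],
            }
        )
        mood = interpolate_mood(ema, hourly, noise_seed=0)
        base = int(pd.Timestamp("2020-01-01").timestamp() // 3600)
        # still filled through to hour 30 despite the nap before the EMA...
        assert max(mood["hour_index"]) == base + 30
        # ...but the nap moved the start anchor to the nap's end
        assert min(mood["hour_index"]) == base + 15


class TestZeroFilling:
    def test_sleep_without_steps_zero_fills_steps(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "step_count": [np.nan],
                "sleep_seconds": [3600.0],
                "in_bed_seconds": [3600.0],
            }
        )
        out = fill_step_sleep_missing(df)
        assert out.loc[0, "step_count"] == 0

    def test_steps_without_sleep_zero_fills_sleep(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "step_count": [400.0],
                "sleep_seconds": [np.nan],
                "in_bed_seconds": [np.nan],
            }
        )
        out = fill_step_sleep_missing(df)
        assert out.loc[0, "sleep_seconds"] == 0.0
        assert out.loc[0, "in_bed_seconds"] == 0.0

    def test_complete_hour_unchanged(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "step_count": [400.0],
                "sleep_seconds": [100.0],
                "in_bed_seconds": [200.0],
            }
        )
        pd.testing.assert_frame_equal(fill_step_sleep_missing(df), df)

    def test_drop_incomplete_hours_requires_all_five(self):
        rows = pd.DataFrame(
            {
                "participant_id": ["P1"] * 3,
                "step_count": [1.0, 2.0, 3.0],
                "sleep_seconds": [0.0, 0.0, 0.0],
                "in_bed_seconds": [0.0, 0.0, 0.0],
                "mean_heart_rate": [70.0, np.nan, 71.0],
                "mood": [5.0, 5.0, np.nan],
            }
        )
        assert len(drop_incomplete_hours(rows)) == 1


class TestOutlierFilter:
    def _clean_rows(self, rng, n=10000):
        return pd.DataFrame(
            {
                "participant_id": rng.choice([f"P{i}" for i in range(50)], n),
                "step_count": rng.poisson(200, n).astype(float),
                "sleep_seconds": np.where(rng.random(n) < 0.7, 0.0, rng.uniform(0, 3600, n)),
                "in_bed_seconds": np.where(rng.random(n) < 0.7, 0.0, rng.uniform(0, 3600, n)),
                "mean_heart_rate": rng.normal(72, 8, n),
                "mood": rng.uniform(1, 10, n),
            }
        )

    def test_planted_extremes_all_flagged(self, rng):
        clean = self._clean_rows(rng)
        planted = clean.sample(50, random_state=1).copy()
        planted["step_count"] = 50000.0
        planted["participant_id"] = "P_out"
        df = pd.concat([clean, planted], ignore_index=True)
        # extremes isolate in few splits: under the forest's automatic
        # threshold every planted row is flagged
        kept, report = filter_outliers(df, seed=0, contamination="auto")
        assert report.outliers_per_participant.get("P_out", 0) == 50
        assert (kept["step_count"] < 50000).all()
        # the fixed default budget still removes essentially all of them
        kept_d, report_d = filter_outliers(df, seed=0)
        assert report_d.outliers_per_participant.get("P_out", 0) >= 45

    def test_deterministic_given_seed(self, rng):
        df = self._clean_rows(rng, n=5000)
        kept1, rep1 = filter_outliers(df, seed=3)
        kept2, rep2 = filter_outliers(df, seed=3)
        pd.testing.assert_frame_equal(kept1, kept2)
        assert rep1.n_outliers_removed == rep2.n_outliers_removed

    def test_flag_rate_on_anomaly_free_cohort(self, plain_config):
        cohort = syn.simulate_cohort(plain_config)
        _, report = filter_outliers(cohort.hourly, seed=1)
        assert report.n_outliers_removed / report.n_hours_in <= 0.05


class TestParticipantFilter:
    def _records(self, pid, n_bl, n_intern, constant_hr=False):
        n = n_bl + n_intern
        rng = np.random.default_rng(hash(pid) % 2**31)
        return pd.DataFrame(
            {
                "participant_id": pid,
                "period": ["BL"] * n_bl + ["Q1"] * n_intern,
                "step_count": rng.poisson(100, n).astype(float),
                "sleep_seconds": rng.uniform(0, 3600, n),
                "in_bed_seconds": rng.uniform(0, 3600, n),
                "mean_heart_rate": 70.0 if constant_hr else rng.normal(70, 5, n),
                "mood": rng.uniform(1, 10, n),
            }
        )

    def test_eligibility_rules_and_reasons(self):
        df = pd.concat(
            [
                self._records("P_short_bl", 99, 150),
                self._records("P_short_intern", 150, 99),
                self._records("P_flat", 150, 150, constant_hr=True),
                self._records("P_ok", 150, 150),
            ]
        )
        kept, report = filter_participants(df)
        assert set(kept["participant_id"]) == {"P_ok"}
        assert report.dropped_participants["P_short_bl"] == "baseline hours"
        assert report.dropped_participants["P_short_intern"] == "internship hours"
        assert report.dropped_participants["P_flat"] == "zero variance"


class TestPipelineEndToEnd:
    def test_clean_pipeline_produces_complete_hours(self, small_cohort):
        hourly = small_cohort.hourly.drop(columns=["mood"])
        clean, report = clean_pipeline(hourly, small_cohort.ema, seed=0)
        assert not clean[list(FEATURES)].isna().any().any()
        assert report.n_hours_out == len(clean)
        assert clean["mood"].between(1, 10.2).all()

    def test_idempotent_with_refit_disabled(self, small_cohort):
        hourly = small_cohort.hourly.drop(columns=["mood"])
        clean, _ = clean_pipeline(hourly, small_cohort.ema, seed=0)
        again, _ = filter_participants(drop_incomplete_hours(fill_step_sleep_missing(clean)))
        pd.testing.assert_frame_equal(
            again.reset_index(drop=True), clean.reset_index(drop=True)
        )
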