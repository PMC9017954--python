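"""Synthetic-cohort generator: marginal shapes, planted structure, seeding."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from resilsense import synthetic as syn
from resilsense.indicators import FEATURES, ds_table, indicator_table


class TestConfigValidation:
    def test_bad_counts_and_probabilities_are_named(self):
        with pytest.raises(syn.ConfigurationError, match="n_participants"):
            syn.CohortConfig(n_participants=0).validate()
        with pytest.raises(syn.ConfigurationError, match="ema_completion_rate"):
            syn.CohortConfig(ema_completion_rate=1.4).validate()

    def test_mixing_weights_must_sum_to_one(self):
        bad = (syn.TrajectoryClass(0, 1, 0, 0.5), syn.TrajectoryClass(0, 2, 0, 0.4))
        with pytest.raises(syn.ConfigurationError, match="sum to 1"):
            syn.CohortConfig(trajectory_classes=bad).validate()


class TestHourlyInvariants:
    def test_physical_ranges(self, small_cohort):
        h = small_cohort.hourly
        assert (h["in_bed_seconds"] >= h["sleep_seconds"]).all()
        assert (h["sleep_seconds"] >= 0).all()
        assert h["mean_heart_rate"].between(35, 204).all()
        assert (h["step_count"] >= 0).all()
        assert h["mood"].between(1, 10.2).all()

    def test_one_record_per_participant_hour(self, small_cohort):
        dup = small_cohort.hourly.duplicated(["participant_id", "hour_start"])
        assert not dup.any()

    def test_steps_zero_mode_and_sleep_zero_heavy(self, small_cohort):
        h = small_cohort.hourly
        assert 0.3 < (h["step_count"] == 0).mean() < 0.8
        assert (h["sleep_seconds"] == 0).mean() > 0.5

    def test_ema_delivered_at_fixed_evening_hour(self, small_cohort):
        ema = small_cohort.ema.copy()
        ema["hour"] = ema["timestamp"].dt.hour
        per_part = ema.groupby("participant_id")["hour"].agg(["nunique", "min", "max"])
        assert (per_part["nunique"] == 1).all()
        assert per_part["min"].between(17, 22).all()

    def test_determinism(self):
        cfg = syn.CohortConfig(n_participants=20, baseline_weeks=1, days_per_quarter=2, seed=5)
        a = syn.simulate_cohort(cfg)
        b = syn.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.hourly, b.hourly)
        pd.testing.assert_frame_equal(a.ema, b.ema)
        pd.testing.assert_frame_equal(a.phq, b.phq)
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestShiftStructure:
    def test_no_shift_ds_centred_at_zero(self, plain_config):
        """With identical baseline/internship parameters the empirical
        per-feature d_s across participants centres at 0."""
        cohort = syn.simulate_cohort(plain_config)
        ds = ds_table(indicator_table(cohort.hourly))
        for feat in FEATURES:
            assert abs(ds[feat].mean()) < 0.05, feat

    def test_heart_rate_shift_recovered(self, plain_config):
        """A +0.5 within-participant-SD shift of the heart-rate mean yields
        mean empirical d_s within +/-0.1 of 0.5 (law of large numbers)."""
        base = syn.simulate_cohort(plain_config)
        bl = base.hourly[base.hourly["period"] == "BL"]
        sd_within = bl.groupby("participant_id")["mean_heart_rate"].std().mean()
        mu = bl["mean_heart_rate"].mean()
        mult = float((mu + 0.5 * sd_within) / mu)
        shifted_cfg = syn.CohortConfig(
            n_participants=200,
            baseline_weeks=4,
            days_per_quarter=7,
            shift_clusters=(
                syn.ShiftCluster(weight=1.0, mean_mult={"mean_heart_rate": mult}),
            ),
            sleep_lump_prob=0.0,
            shift_jitter_sd=0.0,
            sleep_shift_coupling=0.0,
            mood_pull=0.0,
            hr_pull=0.0,
            steps_pull=0.0,
            seed=11,
        )
        cohort = syn.simulate_cohort(shifted_cfg)
        ds = ds_table(indicator_table(cohort.hourly))
        assert ds["mean_heart_rate"].mean() == pytest.approx(0.5, abs=0.1)

    def test_cluster_proportions_and_separation(self):
        cfg = syn.CohortConfig(n_participants=400, baseline_weeks=3, days_per_quarter=6, seed=3)
        cohort = syn.simulate_cohort(cfg)
        ds = ds_table(indicator_table(cohort.hourly)).merge(
            cohort.truth[["participant_id", "cluster_id"]], on="participant_id"
        )
        by_cluster = ds.groupby("cluster_id")["sleep_seconds"].mean()
        # the disrupted cluster sleeps substantially less
        assert by_cluster[1] < by_cluster[0] - 0.1


class TestPHQSeries:
    def test_baseline_delta_exactly_zero(self):
        series = syn.simulate_phq_series(syn.default_trajectory_classes(), 5, seed=0)
        assert (series.loc[series["t"] == 0, "delta"] == 0).all()

    def test_noise_free_quadratic_is_exact(self):
        cls = [syn.TrajectoryClass(0.0, 2.0, -0.5, 1.0)]
        series = syn.simulate_phq_series(cls, 3, seed=0, residual_sd=0.0, random_intercept_sd=0.0)
        q4 = series[series["t"] == 4]["delta"]
        # 2*4 - 0.5*16 = 0 exactly
        assert (q4 == 0.0).all()
        q2 = series[series["t"] == 2]["delta"]
        assert (q2 == 2.0 * 2 - 0.5 * 4).all()

    def test_single_class_shares_one_label(self):
        series = syn.simulate_phq_series([syn.TrajectoryClass(0, 1, 0, 1.0)], 10, seed=1)
        assert series["class_id"].nunique() == 1

    def test_class_proportions_binomial(self):
        classes = [syn.TrajectoryClass(0, 1, 0, 0.68), syn.TrajectoryClass(0, 4, -1, 0.32)]
        rng = np.random.default_rng(0)
        counts = rng.multinomial(1000, [0.68, 0.32])
        series = syn.simulate_phq_series(classes, counts, seed=2)
        props = (
            series.drop_duplicates("participant_id")["class_id"].value_counts(normalize=True)
        )
        assert props[0] == pytest.approx(0.68, abs=0.05)


class TestMissingness:
    def test_no_missingness_is_identity(self, small_cohort):
        cfg = syn.CohortConfig(
            n_participants=60, baseline_weeks=2, days_per_quarter=4, seed=42,
            dropout_hazard_per_quarter=0.0, ema_completion_rate=1.0,
        )
        thinned = syn.apply_missingness(small_cohort, cfg)
        pd.testing.assert_frame_equal(thinned.hourly, small_cohort.hourly)
        pd.testing.assert_frame_equal(thinned.ema, small_cohort.ema)

    def test_zero_completion_removes_all_ema(self, small_cohort):
        cfg = syn.CohortConfig(
            n_participants=60, baseline_weeks=2, days_per_quarter=4, seed=42,
            ema_completion_rate=0.0,
        )
        thinned = syn.apply_missingness(small_cohort, cfg)
        assert len(thinned.ema) == 0

    def test_geometric_survival_to_q4(self):
        cfg = syn.CohortConfig(
            n_participants=500, baseline_weeks=1, days_per_quarter=2,
            dropout_hazard_per_quarter=0.3, seed=9,
        )
        cohort = syn.simulate_cohort(cfg)
        thinned = syn.apply_missingness(cohort)
        has_q4 = thinned.hourly[thinned.hourly["period"] == "Q4"]["participant_id"].nunique()
        assert has_q4 / 500 == pytest.approx(0.7**3, abs=0.05)

    def test_dropout_is_monotone(self):
        cfg = syn.CohortConfig(
            n_participants=300, baseline_weeks=1, days_per_quarter=2,
            dropout_hazard_per_quarter=0.2, seed=4,
        )
        thinned = syn.apply_missingness(syn.simulate_cohort(cfg))
        counts = [
            thinned.hourly[thinned.hourly["period"] == q]["participant_id"].nunique()
            for q in ("Q1", "Q2", "Q3", "Q4")
        ]
        assert counts == sorted(counts, reverse=True)


class TestPlantedAssociations:
    def test_logistic_recovery_of_planted_log_odds(self):
        """A logistic fit of the resilience labels on the planted indicator
        recovers the configured log-odds within 2 standard errors."""
        cfg = syn.CohortConfig(
            n_participants=775, baseline_weeks=1, days_per_quarter=1,
            indicator_effects=(("planted_mood_ds", 0.5),), seed=21,
        )
        cohort = syn.simulate_cohort(cfg)
        y = cohort.truth["resilient"].astype(float)
        x = sm.add_constant(cohort.truth["planted_mood_ds"].astype(float))
        fit = sm.Logit(y, x).fit(disp=0)
        beta = fit.params["planted_mood_ds"]
        se = fit.bse["planted_mood_ds"]
        assert abs(beta - 0.5) < 2 * se

    def test_indicator_cohort_slope_is_exact_estimand(self):
        table, covars = syn.simulate_indicator_cohort(5000, {"x": 0.8}, seed=3)
        y = covars["resilient"].astype(float)
        x = sm.add_constant(table["x"])
        fit = sm.Logit(y, x).fit(disp=0)
        assert fit.params["x"] == pytest.approx(0.8, abs=3 * fit.bse["x"])

    def test_resilient_class_is_minimal_change(self):
        idx = syn.resilient_class_index(syn.default_trajectory_classes())
        assert idx == 0
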