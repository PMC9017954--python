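"""GEE screening: standardisation, univariate/multivariate fits, pruning,
actual-vs-predicted interaction contrasts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from resilsense import gee
from resilsense import synthetic as syn


@pytest.fixture(scope="module")
def planted():
    table, covars = syn.simulate_indicator_cohort(
        775, {"planted": 0.5}, n_null=2, seed=17
    )
    std = gee.standardize_indicators(table)
    return std, covars["resilient"].astype(float), covars


class TestStandardize:
    def test_hand_z_scores(self):
        out = gee.standardize_indicators(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1, 0, 1])
        assert (out["const"] == 1.0).all()

    def test_idempotent(self, rng):
        df = pd.DataFrame({"x": rng.normal(3, 7, 100)})
        once = gee.standardize_indicators(df)
        twice = gee.standardize_indicators(once[["x"]])
        assert np.allclose(once["x"], twice["x"], atol=1e-12)

    def test_constant_column_dropped(self):
        out = gee.standardize_indicators(pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 4.0]}))
        assert "x" not in out.columns
        assert "y" in out.columns

    def test_ids_pass_through(self):
        out = gee.standardize_indicators(
            pd.DataFrame({"participant_id": ["a", "b", "c"], "x": [1.0, 2.0, 3.0]})
        )
        assert list(out["participant_id"]) == ["a", "b", "c"]


class TestUnivariateGee:
    def test_planted_effect_in_ci(self, planted):
        std, labels, covars = planted
        fit = gee.fit_univariate_gee(std["planted"], labels, covars, name="planted")
        assert fit.ci_lo <= 0.5 <= fit.ci_hi
        assert fit.ci_lo <= fit.beta <= fit.ci_hi

    def test_outcome_flip_flips_sign(self, planted):
        std, labels, covars = planted
        a = gee.fit_univariate_gee(std["planted"], labels, covars, name="planted")
        b = gee.fit_univariate_gee(std["planted"], 1.0 - labels, covars, name="planted")
        assert a.beta == pytest.approx(-b.beta, rel=1e-6)

    def test_beta_scale_free(self, planted):
        """Rescaling the raw indicator before standardisation leaves the
        fitted coefficient unchanged."""
        std, labels, covars = planted
        rescaled = gee.standardize_indicators(
            pd.DataFrame({"planted": std["planted"] * 37.5 + 4})
        )
        a = gee.fit_univariate_gee(std["planted"], labels, covars, name="planted")
        b = gee.fit_univariate_gee(rescaled["planted"], labels, covars, name="planted")
        assert a.beta == pytest.approx(b.beta, abs=1e-8)

    def test_independent_clusters_match_plain_logistic(self):
        """With one participant per specialty cluster the GEE point estimate
        reduces to ordinary logistic regression."""
        table, covars = syn.simulate_indicator_cohort(300, {"x": 0.6}, seed=5)
        covars = covars.copy()
        covars["specialty"] = [f"s{i}" for i in range(len(covars))]
        std = gee.standardize_indicators(table)
        fit = gee.fit_univariate_gee(std["x"], covars["resilient"].astype(float), covars, name="x")
        exog = pd.DataFrame(
            {
                "x": std["x"],
                "sex": (covars["sex"] == "female").astype(float),
                "age": covars["age"].astype(float),
                "const": 1.0,
            }
        )
        logit = sm.Logit(covars["resilient"].astype(float), exog).fit(disp=0)
        assert fit.beta == pytest.approx(logit.params["x"], abs=1e-4)

    def test_complete_separation_raises(self):
        table, covars = syn.simulate_indicator_cohort(100, {"x": 0.1}, seed=6)
        sep = covars["resilient"].astype(float) * 2 - 1  # perfectly separating column
        with pytest.raises(gee.SeparationError):
            gee.fit_univariate_gee(sep, covars["resilient"].astype(float), covars, name="sep")


class TestPruneCollinear:
    def _uni(self, names, pvals):
        return pd.DataFrame(
            {"indicator": names, "p": pvals, "beta": [1.0] * len(names)}
        )

    def test_identical_columns_one_survives(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({"a": x, "b": x})
        kept = gee.prune_collinear(table, self._uni(["a", "b"], [0.01, 0.02]))
        assert kept == ["a"]

    def test_smallest_p_wins_in_correlated_triple(self, rng):
        base = rng.normal(size=500)
        table = pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.2, 500),
                "b": base + rng.normal(0, 0.2, 500),
                "c": base + rng.normal(0, 0.2, 500),
            }
        )
        kept = gee.prune_collinear(table, self._uni(["a", "b", "c"], [0.03, 0.001, 0.02]))
        assert kept == ["b"]

    def test_orthogonal_indicators_all_survive(self, rng):
        table = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        kept = gee.prune_collinear(table, self._uni(["a", "b", "c"], [0.01, 0.02, 0.03]))
        assert set(kept) == {"a", "b", "c"}

    def test_insignificant_indicators_never_enter(self, rng):
        table = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        kept = gee.prune_collinear(table, self._uni(["a", "b"], [0.2, 0.01]))
        assert kept == ["b"]


class TestMultivariateGee:
    def test_single_indicator_equals_univariate(self, planted):
        std, labels, covars = planted
        uni = gee.fit_univariate_gee(std["planted"], labels, covars, name="planted")
        multi = gee.fit_multivariate_gee(std, ["planted"], labels, covars)
        assert multi.loc[0, "beta"] == pytest.approx(uni.beta, abs=1e-6)

    def test_two_independent_effects_recovered_with_signs(self):
        table, covars = syn.simulate_indicator_cohort(
            775, {"up": 0.4, "down": -0.3}, seed=23
        )
        std = gee.standardize_indicators(table)
        multi = gee.fit_multivariate_gee(
            std, ["up", "down"], covars["resilient"].astype(float), covars
        ).set_index("indicator")
        assert multi.loc["up", "beta"] > 0
        assert multi.loc["down", "beta"] < 0

    def test_empty_set_rejected(self, planted):
        std, labels, covars = planted
        with pytest.raises(ValueError):
            gee.fit_multivariate_gee(std, [], labels, covars)


class TestActualVsPredicted:
    def test_self_comparison_interaction_near_zero(self, planted):
        std, labels, covars = planted
        table = std[["participant_id", "planted"]]
        contrasts = gee.compare_actual_vs_predicted(table, table.copy(), labels, covars)
        c = contrasts[0]
        assert abs(c.interaction_beta) < 0.05
        assert not c.significantly_different

    def test_sign_flip_detected(self, planted):
        std, labels, covars = planted
        actual = std[["participant_id", "planted"]]
        flipped = actual.copy()
        flipped["planted"] = -flipped["planted"]
        c = gee.compare_actual_vs_predicted(actual, flipped, labels, covars)[0]
        assert c.significantly_different
        assert c.beta_predicted == pytest.approx(-c.beta_actual, abs=0.05)

    def test_interaction_sign_tracks_strength_change(self, planted):
        """Doubling an indicator's association in the predicted copy yields
        an interaction coefficient in the direction of the change."""
        std, labels, covars = planted
        actual = std[["participant_id", "planted"]]
        # halving the predictor doubles the slope of the logit on it
        stronger = actual.copy()
        stronger["planted"] = stronger["planted"] / 2.0
        c = gee.compare_actual_vs_predicted(actual, stronger, labels, covars)[0]
        assert c.interaction_beta > 0

    def test_mismatched_participants_rejected(self, planted):
        std, labels, covars = planted
        actual = std[["participant_id", "planted"]]
        other = actual.iloc[:-1]
        with pytest.raises(ValueError):
            gee.compare_actual_vs_predicted(actual, other, labels, covars)
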