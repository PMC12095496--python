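"""The activity-score linear model: clipping, fitting, prediction,
penalty decomposition, classification, and feature pruning."""

import numpy as np
import pandas as pd
import pytest

from evascore.activity import (
    EvaActivityModel,
    EvaActivityResults,
    RankDeficiencyError,
    classify_efficiency,
    clip_features,
    fit_eva,
    prune_features,
)
from evascore.simulate import (
    PLANTED_EVA_PARAMS,
    activity_from_features,
    generate_guide_feature_table,
)


def features_frame(**overrides):
    base = {"delta_g": -5.0, "n_ga": 2, "mit_score": 60.0, "g17": False, "c20": False}
    base.update(overrides)
    return pd.DataFrame([base])


class TestClipping:
    def test_above_boundary_values_clipped(self):
        out = clip_features(features_frame(delta_g=0.0, mit_score=100.0))
        assert out.loc[0, "delta_g"] == -3.0
        assert out.loc[0, "mit_score"] == 75.0

    def test_inside_range_unchanged(self):
        out = clip_features(features_frame(delta_g=-7.2, mit_score=40.0))
        assert out.loc[0, "delta_g"] == -7.2
        assert out.loc[0, "mit_score"] == 40.0

    def test_boundaries_are_fixed_points(self):
        out = clip_features(features_frame(delta_g=-3.0, mit_score=75.0))
        assert out.loc[0, "delta_g"] == -3.0
        assert out.loc[0, "mit_score"] == 75.0


class TestFitting:
    def test_recovers_planted_coefficients_exactly(self, rng):
        feats = generate_guide_feature_table(200, rng)
        y = activity_from_features(feats)
        res = fit_eva(feats, y)
        for name, truth in PLANTED_EVA_PARAMS.items():
            assert res.params[name] == pytest.approx(truth, rel=1e-6)

    def test_constant_response_gives_zero_slopes(self, rng):
        feats = generate_guide_feature_table(50, rng)
        res = fit_eva(feats, np.full(50, 42.0))
        assert res.params["intercept"] == pytest.approx(42.0)
        for name in ("delta_g", "n_ga", "mit_score", "g17", "c20"):
            assert res.params[name] == pytest.approx(0.0, abs=1e-9)

    def test_refit_on_own_predictions_reproduces_model(self, rng):
        feats = generate_guide_feature_table(100, rng)
        res = fit_eva(feats, activity_from_features(feats))
        refit = fit_eva(feats, res.predict(feats, clamp=False))
        for name in res.params:
            assert refit.params[name] == pytest.approx(res.params[name], rel=1e-9)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        feats = generate_guide_feature_table(50, rng)
        feats["mit_score"] = 2.0 * feats["delta_g"]  # exactly collinear after clip?
        feats["delta_g"] = -10.0  # constant column, collinear with intercept
        with pytest.raises(RankDeficiencyError, match="delta_g"):
            fit_eva(feats, np.linspace(10, 90, 50))

    def test_requires_ten_guides(self, rng):
        feats = generate_guide_feature_table(9, rng)
        with pytest.raises(ValueError, match="10"):
            EvaActivityModel(np.linspace(0, 90, 9), feats)

    def test_response_outside_percentage_scale_rejected(self, rng):
        feats = generate_guide_feature_table(12, rng)
        with pytest.raises(ValueError):
            EvaActivityModel(np.linspace(0, 120, 12), feats)


class TestPrediction:
    def test_matches_hand_computed_dot_product(self, rng, default_model):
        feats = generate_guide_feature_table(50, rng)
        clipped = clip_features(feats, default_model.clip_dg, default_model.clip_mit)
        p = default_model.params
        by_hand = (
            p["intercept"]
            + p["delta_g"] * clipped["delta_g"]
            + p["n_ga"] * clipped["n_ga"]
            + p["mit_score"] * clipped["mit_score"]
            + p["g17"] * clipped["g17"].astype(float)
            + p["c20"] * clipped["c20"].astype(float)
        ).to_numpy()
        np.testing.assert_allclose(
            default_model.predict(feats, clamp=False), by_hand, rtol=1e-12
        )

    def test_zero_penalty_guide_scores_the_maximum(self, default_model):
        f = features_frame(
            delta_g=0.0, mit_score=100.0, n_ga=default_model.n_ga_ref
        )
        assert default_model.predict(f)[0] == pytest.approx(
            default_model.zero_penalty_score()
        )

    def test_predictions_clamped_to_percentage_scale(self, default_model):
        worst = features_frame(delta_g=-30.0, mit_score=0.0, n_ga=0, g17=True, c20=True)
        assert default_model.predict(worst)[0] == 0.0
        assert default_model.predict(worst, clamp=False)[0] < 0.0

    def test_missing_feature_column_is_named(self, default_model):
        with pytest.raises(KeyError, match="mit_score"):
            default_model.predict(features_frame().drop(columns=["mit_score"]))

    def test_lowering_mit_below_boundary_never_raises_score(self, default_model):
        scores = [
            default_model.predict(features_frame(mit_score=m), clamp=False)[0]
            for m in (75.0, 60.0, 30.0, 0.0)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestPenaltyDecomposition:
    def test_zero_penalty_guide_has_all_zero_penalties(self, default_model):
        f = features_frame(delta_g=-3.0, mit_score=75.0, n_ga=default_model.n_ga_ref)
        pens = default_model.penalty_decomposition(f)
        assert (pens.to_numpy() == 0).all()

    def test_single_feature_deviation_isolated(self, default_model):
        f = features_frame(
            delta_g=-8.0, mit_score=75.0, n_ga=default_model.n_ga_ref
        )
        pens = default_model.penalty_decomposition(f).iloc[0]
        assert pens["penalty_delta_g"] != 0.0
        assert (pens.drop("penalty_delta_g") == 0).all()

    def test_penalties_sum_to_score_deficit(self, rng, default_model):
        feats = generate_guide_feature_table(100, rng)
        pens = default_model.penalty_decomposition(feats)
        deficit = default_model.zero_penalty_score() - default_model.predict(
            feats, clamp=False
        )
        np.testing.assert_allclose(pens.sum(axis=1).to_numpy(), deficit, rtol=1e-10)


class TestClassification:
    @pytest.mark.parametrize(
        "score,expected",
        [(49.9, "inefficient"), (50.0, "efficient"), (100.0, "efficient"), (0.0, "inefficient")],
    )
    def test_threshold_at_50(self, score, expected):
        assert classify_efficiency(score) == expected

    def test_top_quartile_guides_not_flagged_on_well_fit_model(self, rng):
        feats = generate_guide_feature_table(200, rng)
        y = activity_from_features(feats, noise_sd=5.0, rng=rng)
        res = fit_eva(feats, y)
        scores = res.predict(feats)
        top = scores[y >= np.percentile(y, 75)]
        assert np.mean(classify_efficiency(top) == "inefficient") <= 0.02


class TestPruning:
    def test_pure_noise_feature_dropped(self, rng):
        n = 300
        signal = rng.uniform(0, 1, n)
        y = 50 + 30 * signal + rng.normal(0, 2, n)
        cands = pd.DataFrame({"signal": signal, "noise": rng.normal(size=n)})
        assert prune_features(cands, y) == ["signal"]

    def test_duplicate_informative_column_kept_once(self, rng):
        n = 200
        signal = rng.uniform(0, 1, n)
        y = 50 + 30 * signal + rng.normal(0, 2, n)
        cands = pd.DataFrame({"a_copy": signal, "b_copy": signal})
        kept = prune_features(cands, y)
        assert len(kept) == 1

    def test_independent_significant_features_all_retained(self, rng):
        n = 400
        x1, x2, x3 = (rng.normal(size=n) for _ in range(3))
        y = 10 * x1 + 8 * x2 + 6 * x3 + rng.normal(0, 3, n)
        cands = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        assert sorted(prune_features(cands, y)) == ["x1", "x2", "x3"]


class TestConfigRoundTrip:
    def test_to_config_from_config_identity(self, default_model):
        clone = EvaActivityResults.from_config(default_model.to_config())
        assert clone.params == default_model.params
        assert clone.clip_dg == default_model.clip_dg
        assert clone.n_ga_ref == default_model.n_ga_ref

    def test_default_model_respects_sign_conventions(self, default_model):
        p = default_model.params
        assert p["delta_g"] > 0 and p["n_ga"] > 0 and p["mit_score"] > 0
        assert p["g17"] < 0 and p["c20"] < 0

    def test_summary_mentions_provenance_and_clips(self, default_model):
        text = default_model.summary()
        assert "package-default-synthetic" in text
        assert "-3" in text and "75" in text
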