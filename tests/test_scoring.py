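"""Malignancy scoring: printed surfaces, clamping, training, response grids."""

import numpy as np
import pytest

from tissuediff.exceptions import DegenerateLabelsError, InvalidInputError
from tissuediff.regression import build_design
from tissuediff.scoring import (
    VARIANTS,
    CancerProbabilityScorer,
    fit_canp,
    printed_scorers,
    surface_grid,
)

CONTROL_D2 = [1.25, 1.67]          # group-mean diffusivities, scaled units
CANCER_D2 = [0.97, 0.86]
CONTROL_D3 = [1.25, 1.67, 0.48]
CANCER_D3 = [0.97, 0.86, 0.75]


class TestPrintedScorers:
    def test_control_means_score_nonmalignant_diffusion2(self):
        r = printed_scorers()["diffusion2"].score_one(CONTROL_D2)
        assert r.raw_score == pytest.approx(0.3215, abs=1e-3)
        assert r.label == "nonmalignant"

    def test_cancer_means_score_malignant_diffusion3(self):
        r = printed_scorers()["diffusion3"].score_one(CANCER_D3)
        assert r.raw_score == pytest.approx(1.476, abs=1e-3)
        assert r.probability == 1.0
        assert r.label == "malignant"

    def test_group_mean_classification_both_variants(self):
        scorers = printed_scorers()
        assert scorers["diffusion2"].score_one(CONTROL_D2).label == "nonmalignant"
        assert scorers["diffusion2"].score_one(CANCER_D2).label == "malignant"
        assert scorers["diffusion3"].score_one(CONTROL_D3).label == "nonmalignant"
        assert scorers["diffusion3"].score_one(CANCER_D3).label == "malignant"

    def test_negative_raw_score_clamps_to_zero(self):
        r = printed_scorers()["morphology"].score_one(np.zeros(5))
        assert r.raw_score == pytest.approx(-2.18)
        assert r.probability == 0.0

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_matches_term_by_term_oracle(self, variant, rng):
        # independent oracle: explicit sum over design terms
        scorer = printed_scorers()[variant]
        k = len(VARIANTS[variant]["features"])
        X = rng.uniform(0, 3, size=(100, k))
        D = build_design(X, VARIANTS[variant]["design"])
        expected = np.array(
            [sum(c * d for c, d in zip(scorer.model_.coefficients, row)) for row in D]
        )
        np.testing.assert_allclose(scorer.decision_function(X), expected, atol=1e-10)

    def test_suspicious_units_warn(self):
        scorer = printed_scorers()["diffusion2"]
        with pytest.warns(UserWarning, match="scaled units"):
            scorer.score_one([1.25e-9, 1.67e-11])  # SI units leaked in


class TestFitCanp:
    def test_separable_cohort_fully_classified(self, rng):
        # non-overlapping predictor ranges: training specimens all correct
        X0 = rng.uniform([1.2, 1.5], [1.5, 2.0], size=(30, 2))
        X1 = rng.uniform([0.5, 0.4], [0.8, 0.9], size=(30, 2))
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(30), np.ones(30)]
        scorer = fit_canp(X, y, "diffusion2")
        np.testing.assert_array_equal(scorer.predict(X), y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateLabelsError):
            fit_canp(rng.uniform(size=(20, 2)), np.ones(20), "diffusion2")

    def test_refit_recovers_printed_diffusion3_surface(self, rng):
        # responses generated from the transcribed surface + small noise:
        # OLS recovers the 10 coefficients within noise-scaled tolerance.
        # (Continuous response stands in for the 0/1 labels to probe the
        # linear algebra; label fitting is covered above.)
        model = printed_scorers()["diffusion3"].model_
        X = rng.uniform([0.5, 0.4, 0.2], [1.5, 2.0, 0.97], size=(300, 3))
        y = model.evaluate(X) + rng.normal(0, 0.01, size=300)
        from tissuediff.regression import QuadraticSurface

        est = QuadraticSurface(
            design="full_second_order", feature_names=list(model.feature_names)
        ).fit(X, y)
        np.testing.assert_allclose(est.coef_, model.coefficients, atol=0.15)

    def test_zero_noise_label_surface_reproduces_separation(self, rng):
        # labels produced by thresholding a generating surface are
        # reproduced on the training set after refitting
        gen = printed_scorers()["diffusion2"]
        X = rng.uniform([0.5, 0.4], [1.5, 2.0], size=(200, 2))
        y = gen.predict(X)
        refit = fit_canp(X, y.astype(float), "diffusion2")
        assert (refit.predict(X) == y).mean() >= 0.95


class TestSurfaceGrid:
    def test_probabilities_bounded_and_saturated(self):
        scorer = printed_scorers()["diffusion2"]
        _, _, grid = surface_grid(
            scorer, ("D_FDP", 0.5, 1.5), ("D_SDP", 0.4, 4.0), n=40
        )
        assert grid.min() == 0.0 and grid.max() == 1.0  # flat regions at 0 and 1
        assert np.all((grid >= 0) & (grid <= 1))

    def test_axis_order_transposes(self):
        scorer = printed_scorers()["diffusion3"]
        fixed = {"P1": 0.6}
        _, _, g1 = surface_grid(scorer, ("D_FDP", 0.5, 1.5), ("D_SDP", 0.4, 4.0), fixed, n=11)
        _, _, g2 = surface_grid(scorer, ("D_SDP", 0.4, 4.0), ("D_FDP", 0.5, 1.5), fixed, n=11)
        np.testing.assert_allclose(g1, g2.T)

    def test_duplicate_axis_rejected(self):
        scorer = printed_scorers()["diffusion2"]
        with pytest.raises(InvalidInputError):
            surface_grid(scorer, ("D_FDP", 0, 1), ("D_FDP", 0, 1))

    def test_missing_fixed_value_rejected(self):
        scorer = printed_scorers()["diffusion3"]
        with pytest.raises(InvalidInputError):
            surface_grid(scorer, ("D_FDP", 0, 1), ("D_SDP", 0, 1))


class TestVariantContracts:
    def test_wrong_predictor_count_rejected(self):
        with pytest.raises(InvalidInputError):
            printed_scorers()["diffusion2"].score_one([1.0, 1.0, 1.0])

    def test_printed_r_squared_metadata(self):
        s = printed_scorers()
        assert s["morphology"].model_.r_squared == 0.66
        assert s["diffusion2"].model_.r_squared == 0.69
        assert s["diffusion3"].model_.r_squared == 0.85
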