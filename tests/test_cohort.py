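"""Synthetic cohort: marginal fidelity, modes, determinism, round trips."""

import dataclasses

import numpy as np
import pytest

from tissuediff.cohort import (
    CANCER_GROUP,
    CONTROL_GROUP,
    CohortConfig,
    GroupParams,
    VariableParams,
    generate_cohort,
    sample_compartments,
    sample_composition,
    specimen_frame,
)
from tissuediff.exceptions import ConfigError
from tissuediff.fitting import peel_off_fit
from tissuediff.regression import QuadraticSurface, printed_predictors


def _zero_sd(gp: GroupParams) -> GroupParams:
    return GroupParams(
        group=gp.group,
        n=gp.n,
        composition={
            k: dataclasses.replace(v, sd=0.0) for k, v in gp.composition.items()
        },
        diffusion={k: dataclasses.replace(v, sd=0.0) for k, v in gp.diffusion.items()},
    )


class TestSampleComposition:
    def test_zero_sd_returns_group_means(self, rng):
        comp = sample_composition(_zero_sd(CANCER_GROUP), rng)
        np.testing.assert_allclose(
            comp.as_array(), [30.7, 39.9, 11.6, 7.1, 7.5, 3.1]
        )

    def test_cancer_parenchyma_mean_and_ranges(self):
        rng = np.random.default_rng(123)
        draws = np.array(
            [sample_composition(CANCER_GROUP, rng).as_array() for _ in range(10_000)]
        )
        # printed cancer parenchyma: 30.7 +/- 15.7, range (10.3, 56.6)
        assert abs(draws[:, 0].mean() - 30.7) <= 1.5
        assert draws[:, 0].min() >= 10.3 and draws[:, 0].max() <= 56.6

    def test_all_variables_respect_printed_ranges(self):
        rng = np.random.default_rng(5)
        keys = ["p", "st", "at", "pce", "pve", "v"]
        for gp in (CONTROL_GROUP, CANCER_GROUP):
            draws = np.array(
                [sample_composition(gp, rng).as_array() for _ in range(2000)]
            )
            for j, k in enumerate(keys):
                vp = gp.composition[k]
                assert draws[:, j].min() >= vp.min and draws[:, j].max() <= vp.max
                # mean fidelity within the tolerance used for parenchyma
                assert abs(draws[:, j].mean() - vp.mean) <= 1.5

    def test_sum_closure(self, rng):
        for _ in range(200):
            comp = sample_composition(CONTROL_GROUP, rng)
            assert comp.as_array().sum() <= 100.5

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ConfigError):
            VariableParams(10, 1, 20, 5)


class TestSampleCompartments:
    def test_group_parameter_zero_sd_control(self, rng):
        gp = _zero_sd(CONTROL_GROUP)
        vals = sample_compartments(gp, "group_parameter", None, rng)
        assert (vals["d_fast"], vals["d_slow"], vals["p1"]) == (1.25, 1.67, 0.48)

    def test_group_parameter_respects_printed_ranges(self, rng):
        for _ in range(500):
            vals = sample_compartments(CANCER_GROUP, "group_parameter", None, rng)
            for k in ("d_fast", "d_slow", "p1"):
                vp = CANCER_GROUP.diffusion[k]
                assert vp.min <= vals[k] <= vp.max

    def test_equation_driven_zero_residual_on_surface(self, rng):
        comp = sample_composition(CANCER_GROUP, rng)
        vals = sample_compartments(
            CANCER_GROUP, "equation_driven", comp, rng,
            residual_scale={"d_fast": 0.0, "d_slow": 0.0, "p1": 0.0},
        )
        models = printed_predictors()
        x = comp.predictors()
        assert vals["d_fast"] == pytest.approx(models["d_fast"].evaluate(x))
        assert vals["d_slow"] == pytest.approx(models["d_slow"].evaluate(x))
        assert vals["p1"] == pytest.approx(
            float(np.clip(models["p1"].evaluate(x), 0.01, 0.99))
        )

    def test_ordering_always_physical(self, rng):
        for _ in range(300):
            comp = sample_composition(CONTROL_GROUP, rng)
            vals = sample_compartments(CONTROL_GROUP, "equation_driven", comp, rng,
                                       residual_scale={"d_fast": 0.3, "d_slow": 0.5, "p1": 0.1})
            assert vals["d_fast"] * 1e-9 > vals["d_slow"] * 1e-11 > 0
            assert 0 < vals["p1"] < 1


class TestGenerateCohort:
    def test_study_design_sizes_and_labels(self):
        specimens = generate_cohort(CohortConfig(seed=1, with_curves=False))
        assert len(specimens) == 17
        groups = [s.group for s in specimens]
        assert groups.count("control") == 6 and groups.count("cancer") == 11
        tnm = [s.tnm for s in specimens if s.group == "cancer"]
        assert tnm.count("T2N0M0") == 6 and tnm.count("T2N1M0") == 5

    def test_stroma_class_consistency(self):
        for s in generate_cohort(CohortConfig(seed=3, with_curves=False)):
            expected = "ge50" if s.composition.stroma >= 50 else "lt50"
            assert s.stroma_class == expected

    def test_same_seed_identical_table(self):
        cfg = CohortConfig(seed=11, with_curves=False)
        f1 = specimen_frame(generate_cohort(cfg))
        f2 = specimen_frame(generate_cohort(cfg))
        assert f1.to_csv() == f2.to_csv()

    def test_specimen_draws_independent_of_group_ordering(self):
        cfg = CohortConfig(seed=4, with_curves=False)
        swapped = dataclasses.replace(cfg, groups=tuple(reversed(cfg.groups)))
        by_id = {s.specimen_id: s for s in generate_cohort(cfg)}
        for s in generate_cohort(swapped):
            ref = by_id[s.specimen_id]
            assert s.d_fast_1e9 == ref.d_fast_1e9 and s.p1 == ref.p1

    def test_forward_inverse_round_trip(self):
        # fitting the generated curves recovers each specimen's true
        # parameters with ~2% median relative error at amplitude noise 0.005
        cfg = CohortConfig(seed=7, noise_sigma=0.005).resize(n_control=15, n_cancer=15)
        specimens = generate_cohort(cfg)
        rel_errs = []
        for s in specimens:
            res = peel_off_fit(s.curve)
            t = s.true_compartments
            rel_errs.append(
                max(
                    abs(res.fast.d - t.d_fast) / t.d_fast,
                    abs(res.slow.d - t.d_slow) / t.d_slow,
                    abs(res.fast.population - t.p1) / t.p1,
                )
            )
        assert np.median(rel_errs) <= 0.02

    def test_equation_driven_r2_calibration(self):
        # refitting the generating design on an n=200 equation-driven cohort
        # lands near the target determination coefficients
        cfg = CohortConfig(mode="equation_driven", seed=0, with_curves=False).resize(
            n_control=100, n_cancer=100
        )
        df = specimen_frame(generate_cohort(cfg))
        X = df[["p", "st", "at", "pce", "v"]].to_numpy()
        for resp, target in [("d_fast_1e9", 0.92), ("d_slow_1e11", 0.81), ("p1", 0.93)]:
            est = QuadraticSurface().fit(X, df[resp].to_numpy())
            assert est.r_squared_ == pytest.approx(target, abs=0.05)

    def test_equation_driven_sign_structure(self):
        # refit linear terms carry the surface's signs: stroma negative for
        # the fast diffusivity, parenchyma positive for the fast population
        cfg = CohortConfig(mode="equation_driven", seed=2, with_curves=False).resize(
            n_control=150, n_cancer=150
        )
        df = specimen_frame(generate_cohort(cfg))
        X = df[["p", "st", "at", "pce", "v"]].to_numpy()
        est = QuadraticSurface(feature_names=["P", "St", "AT", "PCE", "V"]).fit(
            X, df["d_fast_1e9"].to_numpy()
        )
        assert est.coef_[est.term_names_.index("St")] < 0
        from scipy.stats import spearmanr

        assert spearmanr(df["p"], df["p1"]).statistic > 0

    def test_curves_attached_and_deterministic(self):
        cfg = CohortConfig(seed=9).resize(n_control=2, n_cancer=2)
        s1 = generate_cohort(cfg)
        s2 = generate_cohort(cfg)
        for a, b in zip(s1, s2):
            assert a.curve is not None
            np.testing.assert_array_equal(a.curve.amplitudes, b.curve.amplitudes)
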