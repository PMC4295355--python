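"""Summaries, Wilcoxon rank-sum (exact vs enumeration), Spearman, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tissuediff.exceptions import InvalidInputError, UndefinedStatisticError
from tissuediff.stats import (
    correlation_frame,
    correlation_table,
    group_summary,
    spearman,
    wilcoxon_rank_sum,
)


class TestGroupSummary:
    def test_hand_arithmetic(self):
        s = group_summary([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sd == pytest.approx(1.29099, abs=1e-5)
        assert (s.min, s.max) == (1, 4)
        assert s.ratio_high_low == 4

    def test_singleton_convention(self):
        s = group_summary([5.0])
        assert s.mean == 5.0 and s.sd is None and s.ratio_high_low == 1.0

    def test_constant_values(self):
        s = group_summary([3.0, 3.0, 3.0])
        assert s.sd == 0.0 and s.ratio_high_low == 1.0

    def test_nonpositive_min_flags_ratio(self):
        assert group_summary([0.0, 1.0]).ratio_high_low is None

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            group_summary([])

    @given(
        a=st.lists(st.floats(0.1, 100), min_size=1, max_size=8),
        b=st.lists(st.floats(0.1, 100), min_size=1, max_size=8),
    )
    @settings(derandomize=True, max_examples=50)
    def test_merged_range_contains_part_ranges(self, a, b):
        merged = group_summary(a + b)
        for part in (a, b):
            s = group_summary(part)
            assert merged.min <= s.min and merged.max >= s.max


def brute_force_ranksum_p(a, b):
    """Independent oracle: two-sided permutation p of the rank-sum statistic,
    re-ranking the pooled sample for every split."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    all_w = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n_a)
    ]
    all_w = np.array(all_w)
    center = all_w.mean()  # empirical permutation mean, not the formula
    w_obs = ranks[:n_a].sum()
    return float(np.mean(np.abs(all_w - center) >= abs(w_obs - center) - 1e-9))


class TestWilcoxon:
    def test_fully_separated_triples(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_two_sided == pytest.approx(0.1)  # 2 of 20 splits as extreme

    def test_identical_samples_give_p_one(self):
        r = wilcoxon_rank_sum([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert r.p_two_sided == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (6, 6), (5, 7)])
    def test_exact_matches_brute_force_enumeration(self, n_a, n_b, rng):
        for _ in range(5):
            a = np.round(rng.normal(size=n_a), 1)  # rounding induces ties
            b = np.round(rng.normal(size=n_b), 1)
            r = wilcoxon_rank_sum(a, b)
            assert r.method == "exact"
            assert r.p_two_sided == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_exact_agrees_with_scipy_on_tie_free_data(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        r = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_two_sided == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_close_to_normal_approximation(self, rng):
        # at n = 10 per group the two p-value routes agree to ~0.02
        diffs = []
        for _ in range(100):
            a, b = rng.normal(size=10), rng.normal(size=10)
            exact = wilcoxon_rank_sum(a, b).p_two_sided
            approx = wilcoxon_rank_sum(a, b, max_exact=0).p_two_sided
            diffs.append(abs(exact - approx))
        assert max(diffs) <= 0.02

    def test_switches_to_normal_approx_for_large_groups(self, rng):
        r = wilcoxon_rank_sum(rng.normal(size=11), rng.normal(size=11))
        assert r.method == "normal_approx"


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho, _ = spearman(x, [2.0, 4.0, 6.0, 8.0])
        assert rho == 1.0
        rho, _ = spearman(x, [8.0, 6.0, 4.0, 2.0])
        assert rho == -1.0

    @given(st.permutations(list(range(8))))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_monotone_transform(self, y):
        x = np.arange(8.0)
        y = np.asarray(y, dtype=float)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x / 3), y**3 + 5)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_t_approximation_close_to_exhaustive_permutation(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_t = spearman(x, y, method="t")
            _, p_perm = spearman(x, y, method="permutation")  # 720 permutations
            assert abs(p_t - p_perm) <= 0.05

    def test_zero_rank_variance_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _cohort_frame(n_per_group, rng):
    """Tiny specimen table with all three subgroups populated."""
    rows = []
    for group in ("control", "cancer"):
        for i in range(n_per_group):
            st_pct = rng.uniform(30, 70)
            pce = rng.uniform(0, 15)
            rows.append(
                dict(
                    group=group,
                    st=st_pct,
                    p=rng.uniform(5, 50),
                    at=rng.uniform(0, 40),
                    pce=pce,
                    pve=rng.uniform(0, 20),
                    v=rng.uniform(0, 10),
                    d_fast_1e9=rng.uniform(0.6, 1.4),
                    d_slow_1e11=2.0 + 0.1 * pce,  # noiseless increasing in PCE
                    p1=rng.uniform(0.3, 0.9),
                    adc_1e9=rng.uniform(0.4, 3.0),
                )
            )
    return pd.DataFrame(rows)


class TestCorrelationTable:
    def test_cardinality_four_params_six_constituents_three_subgroups(self, rng):
        df = _cohort_frame(12, rng)
        entries = correlation_table(df)
        assert len(entries) == 4 * 6 * 3

    def test_noiseless_functional_dependence_gives_rho_one(self, rng):
        df = _cohort_frame(12, rng)
        for e in correlation_table(df):
            if e.diffusion_param == "D_SDP" and e.constituent == "PCE":
                assert e.rho == pytest.approx(1.0)

    def test_undersized_subgroup_skipped_with_warning(self, rng):
        df = _cohort_frame(8, rng)
        df = df[df["st"] < 50]  # empty >= 50% stroma class
        with pytest.warns(UserWarning, match="stroma_ge50"):
            entries = correlation_table(df)
        assert {e.subgroup for e in entries} == {"control", "stroma_lt50"}

    def test_frame_layout(self, rng):
        frame = correlation_frame(correlation_table(_cohort_frame(10, rng)))
        assert list(frame.columns) == [
            "diffusion_param", "constituent", "subgroup", "n", "rho", "p_value",
        ]
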