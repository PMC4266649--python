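"""Cohort moments, CV, Kruskal–Wallis and Bonferroni correction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dtithresh.stats import (
    bonferroni_alpha,
    cohort_moments,
    compare_conditions,
    kruskal_h,
    kruskal_wallis,
    pairwise_adjacent,
)


def make_table(values_by_condition, region="R", hemi="left"):
    rows = []
    for cond, vals in values_by_condition.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "subject": f"sub-{i:03d}",
                    "region": region,
                    "hemisphere": hemi,
                    "condition": cond,
                    "percent_volume": v,
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


def exhaustive_kw_p(groups):
    """Exact permutation tail probability by enumerating all assignments."""
    pooled = list(itertools.chain.from_iterable(groups))
    sizes = [len(g) for g in groups]
    h_obs, _ = kruskal_h([np.asarray(g, float) for g in groups])
    n_ge = 0
    n_all = 0
    for perm in itertools.permutations(pooled):
        split, start = [], 0
        for s in sizes:
            split.append(np.asarray(perm[start : start + s], float))
            start += s
        h, _ = kruskal_h(split)
        n_all += 1
        if h >= h_obs - 1e-12:
            n_ge += 1
    return h_obs, n_ge / n_all


class TestCohortMoments:
    def test_constant_values_collapse(self):
        table = make_table({"base": [10.0, 10.0, 10.0]})
        m = cohort_moments(table, "percent_volume").iloc[0]
        assert m["mean"] == 10.0
        assert m["sd"] == 0.0
        assert m["cv"] == 0.0
        assert m["ci95_lo"] == m["ci95_hi"] == 10.0

    def test_two_values_hand_computed(self):
        table = make_table({"base": [8.0, 12.0]})
        m = cohort_moments(table, "percent_volume").iloc[0]
        assert m["mean"] == pytest.approx(10.0)
        assert m["sd"] == pytest.approx(math.sqrt(8.0))  # 2.828…
        assert m["cv"] == pytest.approx(math.sqrt(8.0) / 10.0)  # 0.283
        # Student-t CI with 1 df: 10 ± 12.706·2.828/√2
        half = sps.t.ppf(0.975, 1) * math.sqrt(8.0) / math.sqrt(2)
        assert m["ci95_lo"] == pytest.approx(10 - half)
        assert m["ci95_hi"] == pytest.approx(10 + half)

    def test_single_subject_reports_mean_only(self):
        table = make_table({"base": [42.0]})
        m = cohort_moments(table, "percent_volume").iloc[0]
        assert m["mean"] == 42.0
        assert np.isnan(m["sd"]) and np.isnan(m["cv"])
        assert m["ci95_lo"] == m["ci95_hi"] == 42.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1.0, 100.0, rng.integers(2, 12))
        table = make_table({"base": list(vals)})
        m = cohort_moments(table, "percent_volume").iloc[0]
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        assert abs(m["mean"] - mean) < 1e-12
        assert abs(m["sd"] - sd) < 1e-12
        assert abs(m["cv"] - sd / mean) < 1e-12
        assert m["ci95_lo"] <= m["mean"] <= m["ci95_hi"]

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.01, 1000.0, allow_nan=False, allow_infinity=False),
    )
    @settings(max_examples=20, deadline=None)
    def test_cv_is_scale_invariant(self, seed, c):
        rng = np.random.default_rng(seed)
        vals = list(rng.uniform(1.0, 100.0, 6))
        cv1 = cohort_moments(make_table({"base": vals}), "percent_volume").iloc[
            0
        ]["cv"]
        cv2 = cohort_moments(
            make_table({"base": [c * v for v in vals]}), "percent_volume"
        ).iloc[0]["cv"]
        assert cv2 == pytest.approx(cv1, rel=1e-9)


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5], [5, 5]])
        assert res.h == 0.0
        assert res.p_chi2 == 1.0
        assert res.df == 3

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            groups = [
                rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 9))
                for _ in range(rng.integers(2, 5))
            ]
            h, df = kruskal_h(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            res = kruskal_wallis(groups, permutation_n_max=0)
            assert res.p_chi2 == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_exhaustive_permutation_distribution(self):
        h_obs, p_exact = exhaustive_kw_p([[1, 2, 3], [4, 5, 6]])
        # ranks 1-6 split into extremes: only 2 of C(6,3)=20 splits as extreme
        assert p_exact == pytest.approx(0.1)
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]], seed=0, n_resamples=20_000)
        assert res.h == pytest.approx(h_obs)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert res.p_permutation == pytest.approx(p_exact, abs=4 * mc_se)

    def test_tie_correction_raises_h(self):
        groups = [[1, 1, 1, 2], [1, 2, 2, 2]]
        h_corr, _ = kruskal_h(groups)
        # uncorrected H: recompute without dividing by the tie factor
        pooled = np.asarray([1, 1, 1, 2, 1, 2, 2, 2], float)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        r1, r2 = ranks[:4].sum(), ranks[4:].sum()
        h_raw = 12 / (n * (n + 1)) * (r1**2 / 4 + r2**2 / 4) - 3 * (n + 1)
        assert h_corr > h_raw

    def test_all_values_tied_is_degenerate_zero(self):
        h, df = kruskal_h([[3, 3], [3, 3, 3]])
        assert h == 0.0 and df == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            kruskal_wallis([[1, 2], []])

    def test_chi2_p_within_3_mc_se_of_permutation_p(self):
        # the chi-square approximation should track the permutation tail
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(20):
            groups = [
                list(rng.normal(rng.uniform(-0.5, 0.5), 1.0, 5))
                for _ in range(4)
            ]
            res = kruskal_wallis(groups, seed=rng, n_resamples=10_000)
            assert res.p_permutation is not None
            se = math.sqrt(
                res.p_permutation * (1 - res.p_permutation) / 10_000
            )
            # 3 MC standard errors plus approximation slack for chi2 at n=20
            assert abs(res.p_chi2 - res.p_permutation) < max(3 * se, 0.06)
            checked += 1
        assert checked == 20


class TestBonferroni:
    def test_twelve_regions_at_alpha_05(self):
        corrected = bonferroni_alpha(0.05, 12)
        assert corrected == pytest.approx(0.05 / 12)
        assert f"{corrected:.3g}" == "0.00417"

    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_simple_families(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPairwiseAndComparisons:
    def test_identical_adjacent_groups_not_significant(self):
        flags = pairwise_adjacent(
            [[1, 2, 3], [1, 2, 3]], ["a", "b"], alpha=0.05
        )
        assert len(flags) == 1
        assert not flags[0]["significant"]

    def test_shifted_groups_significant(self):
        flags = pairwise_adjacent(
            [list(range(1, 11)), list(range(11, 21))], ["a", "b"], alpha=0.05
        )
        assert flags[0]["significant"]
        # cross-check with scipy's rank-sum (KW with 2 groups is equivalent)
        ref = sps.kruskal(list(range(1, 11)), list(range(11, 21)))
        assert flags[0]["h"] == pytest.approx(ref.statistic)

    def test_compare_conditions_flags_shifted_low_fa_region(self):
        rng = np.random.default_rng(5)
        conds = ["base", "FA>0.15", "FA>0.2", "FA>0.25"]
        shifted = {
            c: list(rng.normal(10 + 5 * i, 0.5, 12))
            for i, c in enumerate(conds)
        }
        flat = {c: list(rng.normal(10, 0.5, 12)) for c in conds}
        table = pd.concat(
            [
                make_table(shifted, region="LOW"),
                make_table(flat, region="HIGH"),
            ],
            ignore_index=True,
        )
        res = compare_conditions(
            table, "percent_volume", conds, family_alpha=0.05, family_size=12
        ).set_index("region")
        assert res.loc["LOW", "significant"]
        assert not res.loc["HIGH", "significant"]
        assert res.loc["LOW", "df"] == 3
        n_sig_low = sum(
            f["significant"] for f in res.loc["LOW", "pairwise"]
        )
        n_sig_high = sum(
            f["significant"] for f in res.loc["HIGH", "pairwise"]
        )
        assert n_sig_low > n_sig_high

    def test_empty_condition_reported_as_skipped(self):
        table = make_table({"base": [1.0, 2.0], "FA>0.15": [1.5, 2.5]})
        res = compare_conditions(
            table, "percent_volume", ["base", "FA>0.15", "FA>0.2"]
        )
        assert res.iloc[0]["skipped_reason"].startswith("empty condition")
        assert not res.iloc[0]["significant"]
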