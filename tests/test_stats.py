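"""Statistical engine: routed tests, CIs, brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import villimorph.cohortsim as cs
from villimorph.stats import (
    ComparisonResult,
    fisher_exact_2x2,
    kruskal_wallis,
    median_difference,
    paired_tests,
    percent_difference,
    route_and_compare,
    select_conservative,
    shapiro_wilk,
    spearman_matrix,
    two_sample_t,
    two_sample_t_from_summary,
    vc_ratio,
)


class TestShapiroWilk:
    def test_gaussian_calibration(self):
        ok = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=500)
            ok += shapiro_wilk(x)[2]
        assert ok >= 90

    def test_lognormal_power(self):
        flagged = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).normal(0, 1, size=500))
            flagged += not shapiro_wilk(x)[2]
        assert flagged >= 99

    def test_degenerate_inputs_explicit(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestTwoSampleT:
    def test_published_baseline_age_comparison(self):
        # mean (SD) age 41.8 (10.5) n=20 vs 35.8 (11.0) n=18 -> P = 0.1
        res = two_sample_t_from_summary(41.8, 10.5, 20, 35.8, 11.0, 18)
        assert round(res.p_value, 1) == 0.1

    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_ci_matches_hand_computed_t_quantile_formula(self):
        a, b = np.array([1.0, 4.0, 7.0]), np.array([2.0, 2.0, 5.0])
        res = two_sample_t(a, b)
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        se = math.sqrt(sp2 * (2 / 3))
        tq = sps.t.ppf(0.975, 4)
        diff = a.mean() - b.mean()
        assert res.ci95[0] == pytest.approx(diff - tq * se)
        assert res.ci95[1] == pytest.approx(diff + tq * se)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([2.0, 2.0], [2.0, 2.0])

    def test_ci_p_coherence(self, rng):
        """95% CI excludes 0 exactly when p < 0.05."""
        for _ in range(200):
            a = rng.normal(rng.uniform(-1, 1), 1, size=rng.integers(3, 15))
            b = rng.normal(0, 1, size=rng.integers(3, 15))
            res = two_sample_t(a, b)
            excludes = res.ci95[0] > 0 or res.ci95[1] < 0
            assert excludes == (res.p_value < 0.05)

    def test_welch_option(self):
        res = two_sample_t([1.0, 2, 3, 9], [1.1, 2.1, 2.9], welch=True)
        assert res.test_name == "Welch t test"


class TestKruskalWallis:
    def test_h_matches_direct_rank_computation(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        h, p = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        r1, r2 = ranks[:3], ranks[3:]
        n = len(pooled)
        h_direct = 12 / (n * (n + 1)) * (
            3 * (r1.mean() - (n + 1) / 2) ** 2 + 3 * (r2.mean() - (n + 1) / 2) ** 2
        )
        assert h == pytest.approx(h_direct)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1.0, 2.0], [1.0, 2.0]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_tied_reports_p_one(self):
        assert kruskal_wallis([[5.0, 5.0], [5.0, 5.0]]) == (0.0, 1.0)

    def test_two_groups_consistent_with_mann_whitney(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 10)
        _, p_kw = kruskal_wallis([a, b])
        p_mw = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_mw, rel=1e-6)


class TestMedianDifference:
    def test_enumerable_example(self):
        est, _ = median_difference([1, 2, 3], [0])
        assert est == 2.0

    def test_shift_equivariance(self, rng):
        b = rng.normal(0, 1, 9)
        est, _ = median_difference(b + 3.25, b)
        assert est == pytest.approx(3.25)

    @given(
        a=st.lists(st.integers(-50, 50), min_size=1, max_size=20),
        b=st.lists(st.integers(-50, 50), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_hodges_lehmann_equals_brute_force(self, a, b):
        est, _ = median_difference(a, b)
        brute = float(np.median([x - y for x in a for y in b]))
        assert est == pytest.approx(brute)

    def test_ci_brackets_true_shift_usually(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(1.0, 1, 15)
            b = rng.normal(0.0, 1, 15)
            _, (lo, hi) = median_difference(a, b)
            hits += lo <= 1.0 <= hi
        assert hits >= 85  # nominal 95%, Monte-Carlo slack

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_difference([], [1.0])


class TestPairedTests:
    def test_identical_pre_post_guarded_to_p_one(self):
        t_res, w_res = paired_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t_res.p_value == 1.0
        assert w_res.p_value == 1.0

    def test_wilcoxon_matches_exhaustive_sign_flip_null(self):
        """Exact p equals enumeration of all 2^6 sign assignments."""
        diffs = np.array([3.0, -1.0, 4.0, 2.0, -5.0, 6.0])
        pre = np.zeros(6)
        _, w_res = paired_tests(pre, diffs)
        ranks = sps.rankdata(np.abs(diffs))
        w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            w = ranks[np.array(signs) > 0].sum()
            w = min(w, ranks.sum() - w)
            if w <= w_obs:
                count += 1
        assert w_res.p_value == pytest.approx(count / 2**6)

    def test_null_vaccination_effect_calibration(self):
        """Paired t on simulated null pre/post rejects at ~5%."""
        rng = np.random.default_rng(15)
        rejections = 0
        reps = 200
        for _ in range(reps):
            pre = rng.normal(250, 36, 14)
            post = pre + rng.normal(0, 12, 14)
            t_res, _ = paired_tests(pre, post)
            rejections += t_res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.04)


class TestSpearman:
    def test_closed_form_no_ties(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        df = pd.DataFrame({"A": x, "B": y, "C": np.arange(5.0),
                           "D": np.arange(5.0), "E": np.arange(5.0)})
        table = spearman_matrix(df, variables=("A", "B", "C", "D", "E"))
        d2 = sum((sps.rankdata(x) - sps.rankdata(y)) ** 2)
        rho_hand = 1 - 6 * d2 / (5 * 24)
        assert table.rho[0, 1] == pytest.approx(rho_hand)

    def test_monotone_transform_gives_rho_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3])
        df = pd.DataFrame({"A": x, "B": np.exp(x), "C": x + 1, "D": x * 2, "E": -x})
        table = spearman_matrix(df, variables=("A", "B", "C", "D", "E"))
        assert table.rho[0, 1] == pytest.approx(1.0)
        assert table.rho[0, 4] == pytest.approx(-1.0)

    def test_recovers_simulator_correlation_target(self):
        """ρ(VP, VA) near the 0.796 HIV-negative target at large n."""
        import dataclasses

        spec = dataclasses.replace(
            cs.paper_scenario(seed=21), n_per_letter=2500,
            attrition_rate=0.0, post_biopsy_fraction=0.0, hiv_prevalence=0.0,
        )
        cohort = cs.simulate_cohort(spec)
        data = cohort.data[cohort.data["letter"].isin(["A", "B"])]
        table = spearman_matrix(data, variables=cs.MEASURES)
        i, j = cs.MEASURES.index("VP_per100"), cs.MEASURES.index("VA_per100")
        assert table.rho[i, j] == pytest.approx(0.796, abs=0.05)

    def test_flags_and_text_rendering(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=60)
        df = pd.DataFrame({
            "A": base, "B": base + rng.normal(0, 0.3, 60),
            "C": rng.normal(size=60), "D": rng.normal(size=60),
            "E": -base + rng.normal(0, 0.5, 60),
        })
        table = spearman_matrix(df, variables=("A", "B", "C", "D", "E"))
        assert table.flags()[0, 1] == "**"
        text = table.to_text()
        assert "1.000" in text and "**" in text

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({m: [1.0, 2.0, 3.0] for m in cs.MEASURES})
        with pytest.raises(ValueError):
            spearman_matrix(df)


class TestFisherExact:
    def test_published_hiv_balance(self):
        assert fisher_exact_2x2([[9, 11], [6, 12]]) == pytest.approx(0.52, abs=0.005)

    def test_published_sex_balance_at_printed_precision(self):
        # printed as 0.28; exact two-sided p is 0.2877
        assert abs(fisher_exact_2x2([[16, 4], [11, 7]]) - 0.28) < 0.01

    def test_diagonal_2x2_enumeration(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_empty_margin_p_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_invariance_under_transpose_and_row_col_swap(self, a, b, c, d):
        t = [[a, b], [c, d]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-9)


class TestPercentDifferenceAndRatio:
    def test_published_percent_differences(self):
        assert percent_difference(293.3, 236.6) == 24.0
        assert percent_difference(27623, 21650) == 27.6
        assert percent_difference(355.0, 273.7) == 29.7

    def test_zero_for_equal_values_and_zero_control_rejected(self):
        assert percent_difference(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    def test_asymmetry_documented_property(self):
        p1 = percent_difference(293.3, 236.6)
        p2 = percent_difference(236.6, 293.3)
        assert (1 + p1 / 100) * (1 + p2 / 100) != 1.0
        assert (1 + 0.0 / 100) * (1 + 0.0 / 100) == 1.0

    def test_vc_ratio_consistent_with_printed_group_ratio(self):
        assert np.round(vc_ratio([293.3], [160.3])[0], 2) == 1.83

    def test_vc_ratio_excludes_zero_crypt_depth(self):
        with pytest.warns(UserWarning, match="zero crypt depth"):
            ratios = vc_ratio([100.0, 200.0], [100.0, 0.0])
        assert len(ratios) == 1

    def test_vc_ratio_group_comparison(self, rng):
        vh = np.r_[rng.normal(290, 30, 12), rng.normal(235, 30, 12)]
        cd = rng.normal(155, 20, 24)
        groups = ["MM"] * 12 + ["placebo"] * 12
        ratios, cmp = vc_ratio(vh, cd, groups)
        assert len(ratios) == 24
        assert cmp.test_name.endswith("t test")


def _routed_cohort(seed, n_per_letter=75):
    import dataclasses

    spec = dataclasses.replace(
        cs.paper_scenario(seed=seed), n_per_letter=n_per_letter
    )
    cohort = cs.simulate_cohort(spec)
    cohort.lock()
    return cs.unblind(cohort).data


class TestRouting:
    def test_default_cohort_routes_by_marginal_family(self):
        """Gaussian measures go parametric, log-normal ones to rank tests."""
        data = _routed_cohort(seed=4)
        results = route_and_compare(data)
        routes = {(r.variable, r.stratum): r.test_name for r in results}
        for stratum in ("negative", "positive"):
            for var in ("VH", "CD", "VA_per100"):
                assert routes[(var, stratum)] == "2-tailed t test"
            for var in ("VP_per100", "VW"):
                assert routes[(var, stratum)] == "Kruskal-Wallis"

    def test_requires_unblinded_data(self):
        cohort = cs.simulate_cohort(cs.paper_scenario(seed=1))
        with pytest.raises(ValueError, match="unblind"):
            route_and_compare(cohort.data)

    def test_sparse_stratum_skipped_with_notice(self):
        data = _routed_cohort(seed=5, n_per_letter=10)
        drop = data[(data["hiv"] == "positive") & (data["arm"] == "MM")]
        data = data.drop(drop.index)
        with pytest.warns(UserWarning, match="positive"):
            results = route_and_compare(data)
        assert all(r.stratum == "negative" for r in results)

    def test_comparison_result_invariants(self):
        data = _routed_cohort(seed=6, n_per_letter=20)
        for r in route_and_compare(data):
            assert 0 < r.p_value <= 1
            if r.test_name.endswith("t test"):
                assert r.ci95[0] <= r.estimate <= r.ci95[1]


class TestSelectConservative:
    def _mk(self, p_vh, tag):
        mk = lambda var, p: ComparisonResult(
            var, "negative", "2-tailed t test", 1.0, (0.5, 1.5), 2.0, p, (10, 10)
        )
        return [mk("VH", p_vh), mk("CD", 0.5 if tag == "pre" else 0.6)]

    def test_larger_primary_p_selected_en_bloc(self):
        pre = self._mk(0.006, "pre")
        post = self._mk(0.001, "post")
        chosen, label = select_conservative(pre, post)
        assert label == "pre" and chosen is pre

    def test_tie_breaks_to_pre(self):
        pre = self._mk(0.01, "pre")
        post = self._mk(0.01, "post")
        _, label = select_conservative(pre, post)
        assert label == "pre"

    def test_mismatched_sets_rejected(self):
        pre = self._mk(0.01, "pre")
        post = [pre[0]]
        with pytest.raises(ValueError, match="different comparisons"):
            select_conservative(pre, post)
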