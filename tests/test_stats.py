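"""ICC, two-sample tests, FDR, KS machinery, normality and PCA screens."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hippoferro.core import REGIONS
from hippoferro.stats import (SubfieldMatrix, bh_adjust, coherence_compare,
                              covariate_split, cv_summary, hedges_g,
                              hedges_g_from_summary, icc_2_1, jarque_bera,
                              ks_p_asymptotic, ks_p_exact, ks_two_sample_D,
                              pca_scores, pooled_t_from_summary,
                              welch_from_summary, welch_t_test,
                              group_test_table)
from hippoferro.synthetic import HC_DEFAULTS, MCI_DEFAULTS, generate_cohort


def simulated_matrix(seed: int, hc=HC_DEFAULTS, mci=MCI_DEFAULTS) -> SubfieldMatrix:
    records = generate_cohort(hc, mci, seed=seed)
    values = pd.DataFrame(
        [{r: rec.bilateral_chi(r) for r in REGIONS} for rec in records],
        index=[rec.subject_id for rec in records])[list(REGIONS)]
    return SubfieldMatrix(
        values=values,
        groups=pd.Series([r.group_label for r in records], index=values.index),
        ages=pd.Series([r.age for r in records], index=values.index),
        sexes=pd.Series([r.sex for r in records], index=values.index),
    )


class TestICC:
    def test_identical_raters_distinct_targets_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        m = np.column_stack([col, col, col])
        assert icc_2_1(m).icc == pytest.approx(1.0)

    def test_three_by_three_anova_oracle(self):
        """Hand ANOVA of [[1,2,3],[4,5,6],[7,8,9]]: MSR=27, MSC=3, MSE=0
        -> ICC = 27/30 = 0.9."""
        res = icc_2_1([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.icc == pytest.approx(0.9)
        assert (res.msr, res.msc, res.mse) == pytest.approx((27.0, 3.0, 0.0))

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 12))
        long = pd.DataFrame(
            [{"target": i, "rater": j, "score": x[i, j]}
             for i in range(8) for j in range(12)])
        ref = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                       ratings="score")
        # absolute-agreement, single measurement: ICC(A,1) a.k.a. ICC(2,1)
        icc2 = float(ref.loc[ref.Type.str.contains("A,1"), "ICC"].iloc[0])
        assert icc_2_1(x).icc == pytest.approx(icc2, abs=1e-9)

    def test_analytic_large_rater_limit(self):
        """For independent Normal(mu_r, sigma_r) columns the ICC approaches
        Var(mu)/(Var(mu) + mean sigma^2) as the number of raters grows."""
        mu = np.array([v for v in HC_DEFAULTS.region_chi_mean.values()])
        sd = np.array([v for v in HC_DEFAULTS.region_chi_sd.values()])
        rng = np.random.default_rng(42)
        k = 2000
        x = mu[:, None] + sd[:, None] * rng.standard_normal((8, k))
        limit = np.var(mu, ddof=1) / (np.var(mu, ddof=1) + np.mean(sd**2))
        assert icc_2_1(x).icc == pytest.approx(limit, abs=0.02)

    def test_mean_icc_recovery_by_group(self):
        """Cohorts simulated from the published group moments recover the
        published coherence coefficients (0.61 all / 0.58 HC / 0.69 MCI)."""
        res = {"all": [], "HC": [], "MCI": []}
        for s in range(200):
            m = simulated_matrix(10_000 + s)
            res["all"].append(icc_2_1(m.values.to_numpy().T).icc)
            res["HC"].append(icc_2_1(m.group_values("HC").to_numpy().T).icc)
            res["MCI"].append(icc_2_1(m.group_values("MCI").to_numpy().T).icc)
        assert np.mean(res["all"]) == pytest.approx(0.61, abs=0.05)
        assert np.mean(res["HC"]) == pytest.approx(0.58, abs=0.05)
        assert np.mean(res["MCI"]) == pytest.approx(0.69, abs=0.05)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_2_1(np.ones((4, 4)))


class TestWelch:
    def test_published_age_comparison(self):
        res = welch_from_summary(73.9, 8.30, 12, 67.2, 6.11, 28)
        assert round(res.p, 2) == 0.02

    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    @pytest.mark.parametrize("a,b", [
        ([0.1, 1.4, 2.2], [2.8, 3.9, 5.1]),
        ([1.1, 2.3, 3.2], [1.9, 3.1, 4.4]),
        ([0.0, 0.5, 1.0], [0.2, 0.7, 1.3]),
    ])
    def test_agrees_with_exhaustive_permutation(self, a, b):
        """Two-sided Welch p tracks the exhaustive label-permutation p at
        n=3+3 within the permutation distribution's discreteness (1/C(6,3));
        agreement presumes samples without extreme outliers, where the t
        reference distribution is a meaningful null."""
        obs = abs(welch_t_test(a, b).t)
        pooled = a + b
        count = 0
        total = 0
        for comb in itertools.combinations(range(6), 3):
            aa = [pooled[i] for i in comb]
            bb = [pooled[i] for i in range(6) if i not in comb]
            total += 1
            if abs(welch_t_test(aa, bb).t) >= obs - 1e-12:
                count += 1
        p_perm = count / total
        p_welch = welch_t_test(a, b).p
        assert abs(p_welch - p_perm) <= 2.0 / total + 0.05


class TestHedges:
    def test_published_volume_effects(self, volume_table):
        g = hedges_g_from_summary(222.8, 32.7, 28, 201.7, 20.5, 12)
        assert round(g, 2) == 0.70  # CA4

    def test_equal_means_zero(self):
        assert hedges_g([1.0, 2.0, 3.0], [2.5, 2.0, 1.5]) == pytest.approx(0.0)

    def test_small_sample_correction_vanishes_with_n(self):
        """g / uncorrected d rises monotonically to 1 as n grows."""
        ratios = []
        for n in (4, 8, 16, 64, 256, 1024):
            g = hedges_g_from_summary(1.0, 1.0, n, 0.0, 1.0, n)
            d_uncorrected = (1.0 - 0.0) / 1.0  # pooled SD is 1 by construction
            ratios.append(g / d_uncorrected)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_group_swap_flips_sign(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_zero_pooled_sd_error(self):
        with pytest.raises(ValueError, match="pooled"):
            hedges_g_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestBH:
    def _oracle(self, p):
        """Direct min-formula: p~(i) = min_{j>=i} p_(j) * m / j."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out

    def test_published_fdr_column(self, volume_table):
        adj = bh_adjust(volume_table["p_raw"].to_numpy())
        assert np.round(adj, 2).tolist() == [0.67, 0.11, 0.04, 0.04, 0.31, 0.04,
                                             0.04, 0.86]

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equals_min_formula_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_rank_monotone(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestKS:
    def test_published_profile_distance(self, chi_table):
        D = ks_two_sample_D(chi_table["mci_mean"], chi_table["hc_mean"])
        assert D == pytest.approx(0.625)

    def test_identical_and_disjoint_samples(self):
        assert ks_two_sample_D([1, 2, 3], [1, 2, 3]) == 0.0
        assert ks_two_sample_D([1, 2], [5, 6]) == 1.0

    def test_matches_scipy_statistic(self):
        from scipy import stats as sps
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            assert ks_two_sample_D(a, b) == pytest.approx(
                sps.ks_2samp(a, b).statistic, abs=1e-12)

    def test_statistic_is_lattice_valued_without_ties(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=8), rng.normal(size=12)
        D = ks_two_sample_D(a, b)
        lcm = math.lcm(8, 12)
        assert (D * lcm) == pytest.approx(round(D * lcm), abs=1e-9)

    def test_asymptotic_published_value(self):
        assert ks_p_asymptotic(0.625, 8, 8) == pytest.approx(0.0497, abs=5e-5)

    def test_asymptotic_boundaries_and_monotone_in_D(self):
        assert ks_p_asymptotic(0.0, 10, 10) == 1.0
        grid = np.linspace(0.01, 0.99, 50)
        ps = [ks_p_asymptotic(d, 12, 15) for d in grid]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_exact_small_sample_enumeration(self):
        assert ks_p_exact(1.0, 2, 2) == pytest.approx(1 / 3)
        assert ks_p_exact(0.0, 5, 7) == 1.0

    def test_exact_differs_from_asymptotic_at_published_point(self):
        """The printed p = 0.0497 is the asymptotic value; the exact null
        probability of D >= 5/8 at n=8 vs 8 is distinctly larger."""
        exact = ks_p_exact(0.625, 8, 8)
        assert exact == pytest.approx(0.08702, abs=1e-4)
        assert abs(exact - ks_p_asymptotic(0.625, 8, 8)) > 0.03

    def test_exact_monotone_in_D(self):
        ps = [ks_p_exact(d, 9, 11) for d in np.linspace(0, 1, 30)]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))


class TestJarqueBera:
    def test_constructed_mesokurtic_sample_gives_zero(self):
        """Symmetric n=8 sample built with exactly zero skewness and zero
        excess kurtosis: JB = 0, p = 1."""
        a, b = 1.0, math.sqrt(2) - 1
        sample = [-a, -b, 0, 0, 0, 0, b, a]
        stat, p = jarque_bera(sample)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_simulated_volume_cohorts_look_normal(self):
        """Within-group bilateral volumes drawn from the published moments
        pass the normality screen (p > 0.1) in at least 90% of cohorts per
        region.  Within a group the draws are exactly Gaussian; the pooled
        two-group sample is a normal mixture and is *expected* to trip the
        test occasionally where the group SDs differ strongly (EC)."""
        counts = {r: 0 for r in REGIONS}
        n_rep = 200
        for s in range(n_rep):
            records = generate_cohort(seed=30_000 + s)
            for r in REGIONS:
                vols = [rec.bilateral_vol(r) for rec in records
                        if rec.group_label == "HC"]
                if jarque_bera(vols)[1] > 0.1:
                    counts[r] += 1
        for r, c in counts.items():
            assert c / n_rep >= 0.9, f"{r}: only {c}/{n_rep} cohorts normal"

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(100):
            sample = rng.standard_t(df=2, size=500)
            if jarque_bera(sample)[1] < 0.01:
                detected += 1
        assert detected >= 95

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            jarque_bera([3.0] * 10)


class TestCV:
    def test_published_summary(self, volume_table):
        cv = cv_summary(volume_table["all_mean"].to_dict(),
                        volume_table["all_sd"].to_dict())
        assert round(cv["min"], 1) == 11.2
        assert round(cv["max"], 1) == 20.3
        assert round(cv["mean"], 1) == 15.9
        assert round(cv["per_region"]["CA1"], 1) == 11.2

    def test_zero_sd_zero_cv(self):
        cv = cv_summary({"CA1": 100.0}, {"CA1": 0.0})
        assert cv["per_region"]["CA1"] == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cv_summary({"CA1": 0.0}, {"CA1": 1.0})


class TestCoherence:
    def test_identical_groups_no_difference(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(6, 8))
        values = pd.DataFrame(np.vstack([block, block]), columns=list(REGIONS))
        values.index = [f"s{i}" for i in range(12)]
        m = SubfieldMatrix(values=values,
                           groups=pd.Series(["A"] * 6 + ["B"] * 6, index=values.index))
        _, ks = coherence_compare(m)
        assert ks.D == 0.0
        assert ks.p_asymptotic == 1.0

    def test_simulated_groups_show_profile_shift(self):
        """Median KS distance between the simulated group profiles stays at
        or above 0.5 over 200 cohorts."""
        ds = []
        for s in range(200):
            _, ks = coherence_compare(simulated_matrix(50_000 + s))
            ds.append(ks.D)
        assert np.median(ds) >= 0.5

    def test_more_than_two_groups_rejected(self):
        m = simulated_matrix(0)
        grouping = pd.Series(["A", "B", "C"] * 13 + ["A"], index=m.values.index)
        with pytest.raises(ValueError, match="exactly 2"):
            coherence_compare(m, grouping=grouping)


class TestCovariateSplit:
    def test_even_distinct_ages_split_in_half(self):
        m = simulated_matrix(3)
        iccs, ks = covariate_split(m, "age_median")
        ns = sorted(v.k_raters for v in iccs.values())
        assert abs(ns[0] - ns[1]) <= 1 and sum(ns) == 40

    def test_median_ties_go_low(self):
        m = simulated_matrix(4)
        ages = m.ages.copy()
        med = float(np.median(ages))
        ages.iloc[:3] = med  # force ties at the median
        m2 = SubfieldMatrix(values=m.values, groups=m.groups, ages=ages,
                            sexes=m.sexes)
        iccs, _ = covariate_split(m2, "age_median")
        low_n = iccs["low_age"].k_raters
        assert low_n == int((ages <= med).sum())

    @pytest.mark.parametrize("covariate", ["age_median", "sex"])
    def test_outputs_in_range_across_seeds(self, covariate):
        for s in range(50):
            iccs, ks = covariate_split(simulated_matrix(70_000 + s), covariate)
            for res in iccs.values():
                assert res.icc <= 1.0
            assert 0.0 <= ks.p_asymptotic <= 1.0
            assert 0.0 <= ks.D <= 1.0


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.outer([1, 2, 3, 4.0], [1, 0.5, -0.5, 1, 2, 0, 1, 3.0])
        scores, explained = pca_scores(u + 1.0, n_components=1)
        assert explained[0] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="rank"):
            pca_scores(u, n_components=2)

    def test_orthogonal_two_block_variance_ratio(self):
        rng = np.random.default_rng(0)
        n = 200
        s1 = rng.standard_normal(n) * 2.0
        s2 = rng.standard_normal(n) * 1.0
        x = np.zeros((n, 8))
        x[:, 0] = s1
        x[:, 1] = s2
        scores, explained = pca_scores(x, n_components=2)
        assert explained[0] / explained[1] == pytest.approx(
            np.var(s1) / np.var(s2), rel=0.05)

    def test_explained_variance_permutation_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 8))
        _, e1 = pca_scores(x, 3)
        _, e2 = pca_scores(x[rng.permutation(20)], 3)
        np.testing.assert_allclose(e1, e2, atol=1e-12)


class TestGroupTable:
    def test_fdr_dominates_raw_and_swap_flips_effects(self):
        m = simulated_matrix(9)
        tab = group_test_table(m, "MCI", "HC", effect_sign="a_minus_b")
        assert (tab["p_fdr"] >= tab["p"] - 1e-15).all()
        flipped = group_test_table(m, "MCI", "HC", effect_sign="b_minus_a")
        np.testing.assert_allclose(tab["hedges_g"], -flipped["hedges_g"])
        np.testing.assert_allclose(tab["p"], flipped["p"])
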