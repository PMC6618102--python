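import itertools

import numpy as np
import pytest
from scipy import stats

from burstcount.inference import (
    chauvenet,
    cluster_permutation,
    jzs_bf_from_t,
    rm_anova_2x12,
    within_subject_ancova,
)


def riemann_jzs_bf10(t, n, scale):
    """Independent dense-grid oracle for the JZS integral."""
    nu = n - 1
    g = np.exp(np.linspace(np.log(1e-6), np.log(1e6), 400_001))
    c = 1 + n * g * scale ** 2
    num = (c ** -0.5 * (1 + t * t / (c * nu)) ** (-(nu + 1) / 2)
           * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)))
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return np.trapezoid(num, g) / den


class TestJZS:
    @pytest.mark.parametrize("t,n", [(0.0, 20), (1.3, 10), (-2.5, 30), (3.2, 19)])
    def test_matches_dense_grid_oracle(self, t, n):
        scale = np.sqrt(0.5)
        assert jzs_bf_from_t(t, n, scale).bf10 == pytest.approx(
            riemann_jzs_bf10(t, n, scale), rel=1e-4)

    @pytest.mark.parametrize("t,n", [(0.5, 12), (2.0, 20), (4.0, 25)])
    def test_matches_pingouin(self, t, n):
        pingouin = pytest.importorskip("pingouin")
        ours = jzs_bf_from_t(t, n, np.sqrt(0.5)).bf10
        theirs = float(pingouin.bayesfactor_ttest(t, n, paired=True,
                                                  r=np.sqrt(0.5)))
        assert ours == pytest.approx(theirs, rel=1e-3)

    def test_monotone_in_abs_t_and_symmetric(self):
        ts = [0.0, 0.5, 1.0, 2.0, 4.0]
        bfs = [jzs_bf_from_t(t, 20).bf10 for t in ts]
        assert all(a < b for a, b in zip(bfs, bfs[1:]))
        assert jzs_bf_from_t(-2.0, 20).bf10 == pytest.approx(
            jzs_bf_from_t(2.0, 20).bf10, rel=1e-9)
        assert bfs[0] < 1.0  # t = 0 favours the null

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf_from_t(np.nan, 20)
        with pytest.raises(ValueError):
            jzs_bf_from_t(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf_from_t(1.0, 20, scale=0.0)


class TestChauvenet:
    def test_single_outlier_excluded(self):
        values = np.array([0.0] * 9 + [10.0])
        mask = chauvenet(values)
        assert mask.sum() == 9 and not mask[-1]

    def test_moderate_spread_kept(self):
        assert chauvenet(np.array([1.0, 1.5, 2.0])).all()

    def test_zero_variance_guard(self):
        assert chauvenet(np.full(8, 3.3)).all()

    def test_matches_expected_count_definition(self, rng):
        values = rng.standard_normal(25)
        mask = chauvenet(values, criterion=0.5)
        z = np.abs(values - values.mean()) / values.std(ddof=1)
        expected = 25 * 2 * stats.norm.sf(z)
        np.testing.assert_array_equal(mask, expected >= 0.5)


class TestAncova:
    def _make(self, n_sub=20, n_pts=12, slope=1.0, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, (n_sub, n_pts))
        y = slope * x + rng.normal(0, noise, x.shape)
        labels = np.repeat(np.arange(n_sub), n_pts)
        return x.ravel(), y.ravel(), labels

    def test_df_arithmetic_20x12(self):
        x, y, lab = self._make()
        res = within_subject_ancova(x, y, lab)
        assert res.slope_df == (1, 219)
        assert res.intercept_df == 19
        assert res.participant_df == (19, 219)

    def test_exact_identity_relation(self):
        x, y, lab = self._make(noise=0.0)
        res = within_subject_ancova(x, y, lab)
        assert res.slope == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        np.testing.assert_allclose(res.intercepts, 0.0, atol=1e-10)

    def test_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        import pandas as pd
        x, y, lab = self._make(n_sub=6, n_pts=8, noise=0.3, seed=3)
        res = within_subject_ancova(x, y, lab)
        df = pd.DataFrame({"x": x, "y": y, "s": lab.astype(str)})
        fit = smf.ols("y ~ C(s) + x", data=df).fit()
        assert res.slope == pytest.approx(fit.params["x"], rel=1e-9)
        assert res.slope_t == pytest.approx(fit.tvalues["x"], rel=1e-9)
        assert res.slope_df[1] == int(fit.df_resid)

    def test_single_participant_degrades_to_regression(self):
        x, y, lab = self._make(n_sub=1, n_pts=12, noise=0.05)
        res = within_subject_ancova(x, y, lab)
        assert res.slope_df == (1, 10)
        assert res.participant_f == 0.0

    def test_null_slope_p_uniform(self):
        """Under independence the slope p-value is U(0,1)."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(1000):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            lab = np.repeat(np.arange(5), 12)
            pvals.append(within_subject_ancova(x, y, lab).slope_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficiency_raises(self):
        x = np.zeros(36)
        y = np.random.default_rng(0).standard_normal(36)
        with pytest.raises(ValueError):
            within_subject_ancova(x, y, np.repeat(np.arange(3), 12))


class TestRmAnova:
    def test_df_for_19_participants(self, rng):
        table = rng.standard_normal((19, 2, 12))
        res = rm_anova_2x12(table)
        assert res.df_main == (1, 18)
        assert res.df_interaction == (11, 198)

    def test_duplicated_conditions_give_zero_f(self, rng):
        half = rng.standard_normal((10, 1, 12))
        res = rm_anova_2x12(np.concatenate([half, half], axis=1))
        assert res.f_main == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        table = rng.standard_normal((9, 2, 4)) + np.array([0.4, 0.0])[None, :, None]
        res = rm_anova_2x12(table)
        rows = [(s, c, f, table[s, c, f]) for s, c, f in
                itertools.product(range(9), range(2), range(4))]
        df = pd.DataFrame(rows, columns=["s", "cond", "freq", "y"])
        aov = pingouin.rm_anova(data=df, dv="y", within=["cond", "freq"],
                                subject="s", detailed=True)
        f_cond = float(aov.loc[aov["Source"] == "cond", "F"].iloc[0])
        f_inter = float(aov.loc[aov["Source"].str.contains("\\*"), "F"].iloc[0])
        assert res.f_main == pytest.approx(f_cond, rel=1e-6)
        assert res.f_interaction == pytest.approx(f_inter, rel=1e-6)

    def test_missing_cells_raise(self, rng):
        table = rng.standard_normal((8, 2, 12))
        table[3, 1, 5] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x12(table)

    def test_power_at_one_sd_offset(self):
        """A constant matched-unmatched offset of 1 SD is detected >90%."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(500):
            table = rng.standard_normal((19, 2, 12))
            table[:, 0, :] += 1.0
            if rm_anova_2x12(table).p_main < 0.05:
                hits += 1
        assert hits / 500 > 0.9


class TestClusterPermutation:
    def test_diagonal_bins_form_one_cluster_under_8way(self, rng):
        maps = rng.standard_normal((12, 5, 6)) * 0.1
        maps[:, 1, 1] += 5.0
        maps[:, 2, 2] += 5.0
        res = cluster_permutation(maps, None, "paired_t", n_permutations=200,
                                  seed=0, chauvenet_criterion=None)
        big = [c for c in res.clusters if {(1, 1), (2, 2)} <= set(c.bins)]
        assert len(big) == 1
        res4 = cluster_permutation(maps, None, "paired_t", n_permutations=200,
                                   seed=0, connectivity=4,
                                   chauvenet_criterion=None)
        assert not any({(1, 1), (2, 2)} <= set(c.bins) for c in res4.clusters)

    def test_p_values_match_exact_enumeration(self, rng):
        """With n=5 the sign-flip null is fully enumerable."""
        maps = rng.standard_normal((5, 2, 3))
        maps[:, 0, :] += 1.2
        res = cluster_permutation(maps, None, "paired_t", n_permutations=4999,
                                  seed=1, chauvenet_criterion=None)
        flat = maps.reshape(5, -1)
        thresh = stats.t.ppf(0.975, 4)

        def max_mass(signs):
            d = flat * np.asarray(signs)[:, None]
            t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(5))
            t = t.reshape(2, 3)
            best = 0.0
            from scipy import ndimage
            for sign in (1, -1):
                lab, k = ndimage.label(sign * t > thresh, structure=np.ones((3, 3)))
                for i in range(1, k + 1):
                    best = max(best, abs(t[lab == i].sum()))
            return best

        null = sorted(max_mass(s) for s in itertools.product([1, -1], repeat=5))
        for c in res.clusters:
            exact_p = np.mean([m >= abs(c.mass) for m in null])
            assert c.p_value == pytest.approx(exact_p, abs=0.05)

    def test_mass_equals_sum_of_member_statistics(self, rng):
        maps = rng.standard_normal((10, 8, 8))
        maps[:, 2:4, 2:5] += 1.5
        res = cluster_permutation(maps, None, "paired_t", n_permutations=100,
                                  seed=2)
        total_supra = int((np.abs(res.stat_map) > res.threshold_map).sum())
        assert total_supra == sum(c.n_bins for c in res.clusters)
        for c in res.clusters:
            member_sum = sum(res.stat_map[fi, ti] for fi, ti in c.bins)
            assert c.mass == pytest.approx(member_sum)

    def test_rectangular_effect_recovery(self):
        """An injected gamma-band prestimulus rectangle is recovered with
        >= 80 percent median overlap."""
        freqs = np.arange(60, 81)
        times = np.linspace(-0.5, 0.5, 26)
        f_in = (freqs >= 66) & (freqs <= 73)
        t_in = (times >= -0.3) & (times <= 0.0)
        region = np.outer(f_in, t_in)
        rng = np.random.default_rng(7)
        overlaps = []
        for _ in range(50):
            maps = rng.standard_normal((20, freqs.size, times.size))
            maps[:, region] += 1.5
            res = cluster_permutation(maps, None, "paired_t",
                                      n_permutations=200, seed=int(rng.integers(2**31)))
            found = np.zeros_like(region, dtype=bool)
            for c in res.significant(0.05):
                for fi, ti in c.bins:
                    found[fi, ti] = True
            overlaps.append((found & region).sum() / region.sum())
        assert np.median(overlaps) >= 0.8

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation(rng.standard_normal((5, 4, 4)),
                                rng.standard_normal((5, 4, 5)), "paired_t")

    def test_watson_u2_statistic_detects_phase_shift(self, rng):
        a = rng.vonmises(0.0, 4.0, (20, 6, 10))
        b = rng.vonmises(0.0, 4.0, (20, 6, 10))
        b[:, 2:4, 3:7] = rng.vonmises(np.pi, 4.0, (20, 2, 4))
        res = cluster_permutation(a, b, "watson_u2", n_permutations=300, seed=3)
        sig = res.significant(0.05)
        assert sig, "phase-shifted region should yield a significant cluster"
        hit = {(fi, ti) for c in sig for fi, ti in c.bins}
        expected = {(fi, ti) for fi in (2, 3) for ti in range(3, 7)}
        assert len(hit & expected) / len(expected) > 0.5
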