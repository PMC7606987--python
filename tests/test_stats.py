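"""Normality rule, ANOVA, Tukey HSD, t-tests, and star annotation."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from cerevasc.stats import (
    GroupTable,
    normality_battery,
    one_way_anova,
    star_annotation,
    tukey_hsd,
    two_way_anova,
    unpaired_t,
)


def exact_moment_sample(mean, sd, n, rng=None):
    """A sample whose mean and sample SD are *exactly* the requested values."""
    base = np.linspace(-1.0, 1.0, n) if rng is None else rng.normal(size=n)
    base = base - base.mean()
    base = base / base.std(ddof=1)
    return mean + sd * base


def summary_stat_anova(means, sds, ns):
    """Closed-form one-way ANOVA from group summary statistics."""
    means, sds, ns = map(np.asarray, (means, sds, ns))
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_b = (ns * (means - grand) ** 2).sum()
    ss_w = ((ns - 1) * sds**2).sum()
    k = len(means)
    f = (ss_b / (k - 1)) / (ss_w / (n_total - k))
    p = sps.f.sf(f, k - 1, n_total - k)
    return f, p


class TestNormality:
    def test_gaussian_sample_judged_normal(self):
        x = np.random.default_rng(1).normal(size=200)
        verdict = normality_battery(x)
        assert verdict.normal
        assert verdict.n_tests == 3

    def test_exponential_sample_judged_not_normal(self):
        x = np.random.default_rng(2).exponential(size=200)
        assert not normality_battery(x).normal

    def test_two_of_three_rule(self):
        x = np.random.default_rng(3).normal(size=200)
        verdict = normality_battery(x)
        assert verdict.normal == (sum(verdict.passes.values()) >= 2)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_battery(np.ones(20))

    def test_small_sample_degrades_battery(self):
        x = np.random.default_rng(4).normal(size=6)
        verdict = normality_battery(x)
        assert verdict.n_tests == 2
        assert "dagostino_pearson" not in verdict.p_values


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        table = GroupTable.from_dict({"a": x, "b": x, "c": x})
        res = one_way_anova(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_summary_statistic_oracle(self):
        # groups reconstructed with exact first two moments from the aging
        # aCBV whole-brain summary (means, SDs, ns)
        means, sds, ns = (1.64, 1.37, 1.24), (0.18, 0.25, 0.29), (14, 12, 8)
        samples = {
            f"g{i}": exact_moment_sample(m, s, n)
            for i, (m, s, n) in enumerate(zip(means, sds, ns))
        }
        res = one_way_anova(GroupTable.from_dict(samples))
        f_ref, p_ref = summary_stat_anova(means, sds, ns)
        assert res.statistic == pytest.approx(f_ref, rel=1e-9)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_matches_scipy(self, rng):
        a, b, c = rng.normal(size=(3, 9))
        res = one_way_anova(GroupTable.from_dict({"a": a, "b": b, "c": c}))
        ref = sps.f_oneway(a, b, c)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=(2, 12))
        f_res = one_way_anova(GroupTable.from_dict({"x": x, "y": y}))
        t_res = unpaired_t(x, y)
        assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert f_res.p == pytest.approx(t_res.p, rel=1e-10)

    def test_affine_invariance(self, rng):
        a, b = rng.normal(size=(2, 10))
        f1 = one_way_anova(GroupTable.from_dict({"a": a, "b": b})).statistic
        f2 = one_way_anova(GroupTable.from_dict({"a": 5 * a + 3, "b": 5 * b + 3})).statistic
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_zero_within_variance_flagged(self):
        table = GroupTable.from_dict({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        res = one_way_anova(table)
        assert "zero_within_group_variance" in res.flags
        assert res.p == 0.0


class TestTukey:
    def test_identical_groups_adjusted_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = tukey_hsd(GroupTable.from_dict({"a": x, "b": x, "c": x}))
        assert all(r.p == pytest.approx(1.0, abs=1e-9) for r in out.values())

    def test_two_groups_equal_pooled_t(self, rng):
        x, y = rng.normal(size=(2, 10))
        tk = tukey_hsd(GroupTable.from_dict({"x": x, "y": y}))
        t = unpaired_t(x, y)
        assert list(tk.values())[0].p == pytest.approx(t.p, rel=1e-6)

    def test_matches_statsmodels_reference(self, rng):
        groups = {g: rng.normal(loc, 1.0, size=n) for g, loc, n in
                  [("a", 0.0, 14), ("b", 0.6, 12), ("c", 1.0, 8)]}
        ours = tukey_hsd(GroupTable.from_dict(groups))
        values = np.concatenate(list(groups.values()))
        labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
        ref = pairwise_tukeyhsd(values, labels)
        ref_p = dict(zip([tuple(r) for r in ref.summary().data[1:]], ref.pvalues))
        for (pair, res), p_ref in zip(ours.items(), ref.pvalues):
            assert res.p == pytest.approx(p_ref, abs=1e-4)

    def test_adjusted_p_not_below_pairwise_p(self, rng):
        groups = {g: rng.normal(size=8) for g in "abc"}
        out = tukey_hsd(GroupTable.from_dict(groups))
        for (a, b), res in out.items():
            raw = unpaired_t(groups[a], groups[b]).p
            assert res.p >= raw - 1e-9

    def test_monotone_in_mean_difference(self):
        base = exact_moment_sample(0.0, 1.0, 10)
        ps = []
        for delta in (0.2, 0.6, 1.2, 2.0):
            out = tukey_hsd(
                GroupTable.from_dict({"a": base, "b": base + delta})
            )
            ps.append(list(out.values())[0].p)
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestTwoWayAnova:
    @staticmethod
    def balanced_table(rng, effect_b=0.0, reps=4):
        ages = ("young", "mid", "old")
        bins = ("small", "medium", "large")
        values, fa, fb = [], [], []
        for a in ages:
            for i, b in enumerate(bins):
                v = rng.normal(size=reps) + effect_b * i
                values.append(v)
                fa += [a] * reps
                fb += [b] * reps
        return GroupTable(np.concatenate(values), np.array(fa), factor2=np.array(fb))

    def test_shift_in_factor_b_only(self, rng):
        table = self.balanced_table(rng, effect_b=2.0)
        out = two_way_anova(table)
        assert out["B"].p < 1e-6
        assert out["A"].p > 0.01
        assert "A:B" in out

    def test_collapsing_to_one_level_reproduces_one_way(self, rng):
        values = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        table2 = GroupTable(values, groups, factor2=np.array(["only"] * 12))
        out = two_way_anova(table2)
        ref = one_way_anova(GroupTable(values, groups))
        assert out["A"].statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert out["A"].p == pytest.approx(ref.p, rel=1e-9)

    def test_unbalanced_rejected(self, rng):
        table = self.balanced_table(rng)
        values = np.append(table.values, 1.0)
        groups = np.append(table.groups, "young")
        f2 = np.append(table.factor2, "small")
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova(GroupTable(values, groups, factor2=f2))

    def test_missing_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            two_way_anova(GroupTable(rng.normal(size=4), np.array(["a", "a", "b", "b"])))


class TestUnpairedT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = unpaired_t(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computable_fixture(self):
        res = unpaired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == (4.0,)

    def test_zero_pooled_variance_flagged(self):
        res = unpaired_t([1.0, 1.0], [1.0, 1.0])
        assert "zero_pooled_variance" in res.flags


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.049, "*"),
            (0.0099, "**"),
            (0.0009, "***"),
            (0.00009, "****"),
            (0.05, ""),
            (0.5, ""),
            (0.01, "*"),
            (0.001, "**"),
            (0.0001, "***"),
        ],
    )
    def test_strict_thresholds(self, p, stars):
        assert star_annotation(p) == stars

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            star_annotation(1.5)


class TestCalibrationUnderNull:
    """Type-I error of each test stays near alpha under seeded nulls."""

    def test_anova_and_t_rejection_rates(self):
        rng = np.random.default_rng(99)
        n_rep = 500
        rej_f = rej_t = 0
        for _ in range(n_rep):
            a, b, c = rng.normal(size=(3, 8))
            if one_way_anova(GroupTable.from_dict({"a": a, "b": b, "c": c})).p < 0.05:
                rej_f += 1
            if unpaired_t(a, b).p < 0.05:
                rej_t += 1
        # 3.3 SE band around 0.05 at 500 replicates
        band = 3.3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej_f / n_rep - 0.05) < band
        assert abs(rej_t / n_rep - 0.05) < band
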