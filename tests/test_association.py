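"""Arcsine square-root transform, one-way ANOVA, Fisher's LSD and CLD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sproutscreen.association import (
    arcsin_sqrt,
    associate,
    compact_letter_display,
    f_critical,
    group_summaries,
    lsd_test,
    one_way_anova,
    reverse_transform,
)


class TestTransform:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4)]
    )
    def test_known_points(self, x, expected):
        assert arcsin_sqrt(x) == pytest.approx(expected)

    @pytest.mark.parametrize("m,expected", [(0.57, 0.29), (0.83, 0.54)])
    def test_back_transform_reported_to_two_decimals(self, m, expected):
        assert round(reverse_transform(m), 2) == expected

    @given(x=st.floats(0, 1))
    def test_round_trip_identity(self, x):
        assert reverse_transform(arcsin_sqrt(x)) == pytest.approx(x, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            arcsin_sqrt(1.2)
        with pytest.raises(ValueError):
            reverse_transform(2.0)

    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    def test_monotone(self, x, y):
        if x <= y:
            assert arcsin_sqrt(x) <= arcsin_sqrt(y)


class TestGroupSummaries:
    def test_collection_gi_by_haplotype(self, collection):
        sub = collection[collection["thvp1"] != "hg"]
        by_group = {s.group: s for s in group_summaries(sub["gi"], sub["thvp1"])}
        d = by_group["ThVp-1d"]
        assert (d.n, round(d.mean, 2), round(d.sd, 2)) == (13, 0.64, 0.20)
        assert (round(d.min, 2), round(d.max, 2)) == (0.15, 0.95)
        a = by_group["ThVp-1a"]
        assert (a.n, round(a.mean, 2)) == (36, 0.78)

    def test_constant_group(self):
        (s,) = group_summaries([0.5, 0.5], ["g", "g"])
        assert (s.mean, s.sd) == (0.5, 0.0)


class TestAnova:
    def test_two_identical_groups_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert res.f_observed == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_agrees_with_scipy_f_oneway(self, rng):
        values = rng.normal(size=40)
        groups = rng.choice(list("abcd"), size=40)
        res = one_way_anova(values, groups)
        f_ref, p_ref = stats.f_oneway(*(values[groups == g] for g in "abcd"))
        assert res.f_observed == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    @given(
        a=st.floats(0.1, 5),
        b=st.floats(-3, 3),
    )
    def test_f_invariant_under_affine_transform(self, a, b):
        rng = np.random.default_rng(7)
        values = rng.normal(size=30)
        groups = np.repeat(list("abc"), 10)
        f0 = one_way_anova(values, groups).f_observed
        f1 = one_way_anova(a * values + b, groups).f_observed
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_two_groups_f_equals_squared_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        res = one_way_anova(np.r_[x, y], ["x"] * 12 + ["y"] * 9)
        t, p = stats.ttest_ind(x, y, equal_var=True)
        assert res.f_observed == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_zero_within_variance_flagged(self):
        res = one_way_anova([1, 1, 2, 2], list("aabb"))
        assert res.infinite_f and res.f_observed == np.inf and res.p_value == 0.0

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2], ["a", "a"])


class TestFCritical:
    def test_published_quantiles(self):
        assert f_critical(0.05, 3, 81) == pytest.approx(2.717, abs=5e-4)
        assert f_critical(0.05, 3, 68) == pytest.approx(2.740, abs=5e-3)

    def test_large_df2_limit_is_chi2(self):
        assert f_critical(0.05, 4, 10**7) == pytest.approx(
            stats.chi2.ppf(0.95, 4) / 4, rel=1e-3
        )

    def test_invalid_dfs(self):
        with pytest.raises(ValueError):
            f_critical(0.05, 0, 10)


class TestLsd:
    def test_collection_gi_pairs(self, collection):
        sub = collection[collection["thvp1"] != "hg"]
        anova = one_way_anova(sub["gi"], sub["thvp1"])
        lsd = lsd_test(sub["gi"], sub["thvp1"], anova)
        sig = lsd.significant
        assert sig.loc["ThVp-1d", "ThVp-1a"]
        assert sig.loc["ThVp-1d", "ThVp-1c"]
        assert not sig.loc["ThVp-1d", "ThVp-1b"]
        assert lsd.letters == {
            "ThVp-1a": "b",
            "ThVp-1b": "ab",
            "ThVp-1c": "b",
            "ThVp-1d": "a",
        }

    def test_collection_ss_pairs_dormant_group_lower(self, collection):
        sub = collection[(collection["thvp1"] != "hg")].dropna(subset=["ss"])
        y = arcsin_sqrt(sub["ss"].to_numpy())
        anova = one_way_anova(y, sub["thvp1"])
        lsd = lsd_test(y, sub["thvp1"], anova)
        assert lsd.significant.loc["ThVp-1d", "ThVp-1b"]
        assert lsd.significant.loc["ThVp-1d", "ThVp-1c"]
        assert not lsd.significant.loc["ThVp-1d", "ThVp-1a"]

    def test_two_group_lsd_equals_pooled_t_test(self, rng):
        for shift in (0.0, 0.4, 1.2):
            x, y = rng.normal(0, 1, 15), rng.normal(shift, 1, 11)
            values = np.r_[x, y]
            groups = np.array(["x"] * 15 + ["y"] * 11)
            anova = one_way_anova(values, groups)
            lsd = lsd_test(values, groups, anova)
            _, p = stats.ttest_ind(x, y, equal_var=True)
            assert lsd.significant.loc["x", "y"] == (p < 0.05)

    def test_single_group_empty_result(self):
        anova_like = one_way_anova([1, 2, 3, 4], list("aabb"))
        lsd = lsd_test([1.0, 2.0], ["g", "g"], anova_like)
        assert lsd.letters == {"g": "a"}
        assert not lsd.significant.to_numpy().any()


class TestCompactLetterDisplay:
    @given(seed=st.integers(0, 200))
    def test_letters_encode_pairwise_matrix_exactly(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        groups = [f"g{i}" for i in range(k)]
        means = {g: float(rng.normal()) for g in groups}
        # random symmetric significance pattern
        sig = pd.DataFrame(False, index=groups, columns=groups)
        for i in range(k):
            for j in range(i + 1, k):
                s = bool(rng.random() < 0.4)
                sig.iloc[i, j] = sig.iloc[j, i] = s
        letters = compact_letter_display(groups, sig, means)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
                assert share == (not sig.iloc[i, j]), (letters, sig)

    def test_lowest_mean_group_gets_letter_a(self):
        groups = ["hi", "lo"]
        sig = pd.DataFrame(
            [[False, True], [True, False]], index=groups, columns=groups
        )
        letters = compact_letter_display(groups, sig, {"hi": 0.9, "lo": 0.1})
        assert letters == {"lo": "a", "hi": "b"}


class TestAssociate:
    def test_exclusion_accounting_on_the_collection(self, collection):
        gi_hap = associate(collection["gi"], collection["thvp1"], "gi")
        assert (gi_hap.n_used, gi_hap.n_excluded_factor) == (85, 2)
        ss_hap = associate(
            collection["ss"], collection["thvp1"], "ss", transform="arcsin_sqrt"
        )
        assert (ss_hap.n_used, ss_hap.n_excluded_missing) == (72, 13)
        assert [s.n for s in ss_hap.summaries] == [28, 11, 21, 12]
        gi_allele = associate(collection["gi"], collection["tavp1b"], "gi")
        assert (gi_allele.n_used, gi_allele.n_excluded_factor) == (71, 16)
        ss_allele = associate(
            collection["ss"], collection["tavp1b"], "ss", transform="arcsin_sqrt"
        )
        assert ss_allele.n_used == 63

    def test_morphology_factors_show_no_association(self, collection):
        for factor in ("awns", "glume_color", "grain_color"):
            levels = collection[factor].dropna()
            report = associate(
                collection.loc[levels.index, "gi"], levels, "gi", exclude_levels=()
            )
            assert report.anova.p_value > 0.05

    def test_back_transformed_means_only_when_transformed(self, collection):
        plain = associate(collection["gi"], collection["thvp1"], "gi")
        assert all(s.mean_back_transformed is None for s in plain.summaries)
        trans = associate(
            collection["ss"], collection["thvp1"], "ss", transform="arcsin_sqrt"
        )
        for s in trans.summaries:
            assert s.mean_back_transformed == pytest.approx(
                reverse_transform(s.mean)
            )
            assert 0 <= s.raw_min <= s.raw_max <= 1

    def test_shuffled_factor_rejects_at_nominal_rate(self, collection, rng):
        sub = collection[collection["thvp1"] != "hg"]
        labels = sub["thvp1"].to_numpy().copy()
        rejections = 0
        n_shuffles = 200
        for _ in range(n_shuffles):
            rng.shuffle(labels)
            res = one_way_anova(sub["gi"], labels)
            rejections += res.p_value < 0.05
        assert 0.01 <= rejections / n_shuffles <= 0.11

    def test_fewer_than_two_levels_rejected(self, collection):
        with pytest.raises(ValueError, match="two usable factor levels"):
            associate(
                collection["gi"], pd.Series(["x"] * len(collection)), "gi"
            )

    def test_unknown_transform_rejected(self, collection):
        with pytest.raises(ValueError):
            associate(collection["gi"], collection["thvp1"], transform="logit")
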