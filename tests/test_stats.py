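import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from tgi_cutoff.io import validate_cohort
from tgi_cutoff.stats import (
    GEARY_NULL,
    geary_test,
    one_way_anova,
    stratified_summary,
    tukey_hsd,
    two_sample_t,
)

from conftest import make_subject


class TestGeary:
    def test_normal_sample_near_null(self, rng):
        a, z, p = geary_test(rng.normal(size=200_0))
        assert a == pytest.approx(GEARY_NULL, abs=0.02)
        assert abs(z) < 3

    def test_uniform_sample_matches_closed_form(self, rng):
        # uniform: mean |dev| = range/4, sd = range/sqrt(12) -> a = sqrt(12)/4
        a, z, _ = geary_test(rng.uniform(size=200_0))
        assert a == pytest.approx(math.sqrt(12) / 4, abs=0.02)
        assert z > 3  # platykurtic: flagged as non-normal

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            geary_test([3.0] * 20)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            geary_test([1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        shift=st.floats(min_value=-100, max_value=100),
        scale=st.floats(min_value=0.01, max_value=100),
    )
    def test_location_scale_invariance(self, shift, scale):
        x = np.arange(20.0) ** 1.5
        a1, _, _ = geary_test(x)
        a2, _, _ = geary_test(shift + scale * x)
        assert a2 == pytest.approx(a1, rel=1e-9)


class TestTTest:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_example(self):
        # pooled sd = 1, mean difference -3, se = sqrt(2/3)
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_constant_groups(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = two_sample_t([1.0, 1.0], [3.0, 3.0])
        assert t == -math.inf and p == 0.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestAnova:
    def test_identical_groups_f_zero(self):
        f, p = one_way_anova([[1, 2, 3]] * 3)
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # groups with means 2,3,4: SSB=6 (df 2), SSW=6 (df 6) -> F=3
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        assert p == pytest.approx(0.125, abs=1e-3)

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=9)
        f, p_f = one_way_anova([a, b])
        t, p_t = two_sample_t(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_undersized_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2, 3], [4, 5]])


class TestTukey:
    def test_identical_groups_p_near_one(self):
        table = tukey_hsd([[1, 2, 3]] * 3)
        assert (table["p"] > 0.999).all()

    def test_extreme_pair_smallest_p(self):
        table = tukey_hsd(
            [[0.0, 0.1, -0.1], [5.0, 5.1, 4.9], [10.0, 10.1, 9.9]],
            labels=["low", "mid", "high"],
        )
        row = table.set_index(["group_a", "group_b"])
        assert row.loc[("low", "high"), "p"] == table["p"].min()

    def test_matches_statsmodels(self, rng):
        groups = [rng.normal(m, 1, size=15) for m in (0.0, 0.6, 1.5)]
        ours = tukey_hsd(groups, labels=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [len(g) for g in groups])
        sm = pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            ours["p"].to_numpy(), np.asarray(sm.pvalues), atol=1e-6
        )


class TestStratifiedSummary:
    @staticmethod
    def cohort_with_sex_shift(rng, shift, n=150):
        rows = []
        for i in range(n):
            male = i % 2 == 0
            tgi_mean = 4.5 + (shift if male else 0.0)
            tag = math.exp(2 * (tgi_mean + rng.normal(0, 0.3)) - math.log(90.0))
            rows.append(
                make_subject(
                    f"S{i}",
                    sex="male" if male else "female",
                    glucose=90.0,
                    triglycerides=round(tag, 2),
                    age=int(rng.integers(18, 70)),
                )
            )
        from tgi_cutoff.indices import add_derived_indices

        table = validate_cohort(pd.DataFrame(rows))
        return add_derived_indices(table.data)

    def test_two_levels_dispatch_to_t(self, rng):
        df = self.cohort_with_sex_shift(rng, shift=0.2)
        cells, omnibus = stratified_summary(df, "tgi", "sex")
        assert omnibus["test"] == "student_t"
        assert {c.stratum for c in cells} == {"female", "male"}
        assert sum(c.n for c in cells) == len(df)

    def test_three_levels_dispatch_to_anova(self, rng):
        df = self.cohort_with_sex_shift(rng, shift=0.0)
        df["band"] = np.random.default_rng(0).choice(["a", "b", "c"], len(df))
        cells, omnibus = stratified_summary(df, "tgi", "band")
        assert omnibus["test"] == "anova"
        assert len(omnibus["tukey"]) == 3

    def test_generator_shift_recovered(self, rng):
        shift = 0.10
        df = self.cohort_with_sex_shift(rng, shift=shift, n=2000)
        cells, _ = stratified_summary(df, "tgi", "sex")
        by = {c.stratum: c for c in cells}
        diff = by["male"].mean - by["female"].mean
        se = math.hypot(
            by["male"].sd / math.sqrt(by["male"].n),
            by["female"].sd / math.sqrt(by["female"].n),
        )
        assert diff == pytest.approx(shift, abs=3 * se)

    def test_single_level_rejected(self, rng):
        df = self.cohort_with_sex_shift(rng, 0.0, n=10)
        df["const"] = "x"
        with pytest.raises(ValueError):
            stratified_summary(df, "tgi", "const")
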