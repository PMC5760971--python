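import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from tgi_cutoff.roc import (
    auc_rank,
    auc_trapezoid,
    cutoff_analysis,
    delong_test,
    delong_variance,
    empirical_roc,
    likelihood_ratios,
    roc_distance,
    select_optimal_cutoff,
    youden,
)
from tgi_cutoff.simulate import generate_binormal_scores


def brute_force_delong(scores, states):
    """Independent O(m*n) placement-value oracle for the DeLong variance."""
    scores = np.asarray(scores, float)
    states = np.asarray(states, bool)
    pos, neg = scores[states], scores[~states]
    m, n = len(pos), len(neg)
    psi = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            psi[i, j] = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    auc = psi.mean()
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return auc, math.sqrt(var)


# strategy: small score vectors with heavy tying, at least one of each class
small_instance = st.tuples(
    st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=12),
    st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=12),
)


class TestEmpiricalRoc:
    def test_four_subject_enumeration(self):
        curve = empirical_roc([1, 2, 3, 4], [0, 0, 1, 1])
        i = list(curve.thresholds).index(3.0)
        assert curve.sensitivity[i] == 1.0
        assert curve.specificity[i] == 1.0

    def test_single_positive_between_negatives(self):
        curve = empirical_roc([2, 1, 3], [1, 0, 0])
        i = list(curve.thresholds).index(2.0)
        assert curve.sensitivity[i] == 1.0
        assert curve.specificity[i] == 0.5

    def test_endpoints_present(self):
        curve = empirical_roc([1.0, 2.0], [0, 1])
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(small_instance)
    def test_curve_monotonicity(self, instance):
        neg, pos = instance
        scores = np.array(neg + pos, float)
        states = np.array([0] * len(neg) + [1] * len(pos))
        curve = empirical_roc(scores, states)
        assert np.all(np.diff(curve.thresholds) < 0)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)


class TestAuc:
    def test_perfect_separation(self):
        curve = empirical_roc([1, 2, 10, 11], [0, 0, 1, 1])
        assert auc_trapezoid(curve) == 1.0

    def test_all_tied_is_chance(self):
        curve = empirical_roc([5, 5, 5, 5], [0, 0, 1, 1])
        assert auc_trapezoid(curve) == 0.5

    def test_interleaved_toy(self):
        # positives {2}, negatives {1,3}: one concordant, one discordant pair
        assert auc_rank([2, 1, 3], [1, 0, 0]) == 0.5

    def test_tied_pair_enumeration(self):
        # positives {2,3}, negatives {1,3}: pairs 2>1, 2<3, 3>1, 3==3
        assert auc_rank([2, 3, 1, 3], [1, 1, 0, 0]) == (1 + 0 + 1 + 0.5) / 4

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(small_instance)
    def test_trapezoid_equals_rank_exactly(self, instance):
        neg, pos = instance
        scores = np.array(neg + pos, float)
        states = np.array([0] * len(neg) + [1] * len(pos))
        assert auc_trapezoid(empirical_roc(scores, states)) == auc_rank(scores, states)

    def test_matches_sklearn_on_random_data(self, rng):
        scores = rng.normal(size=200)
        states = rng.random(200) < 0.4
        states[:2] = [True, False]
        assert auc_rank(scores, states) == pytest.approx(
            roc_auc_score(states, scores), abs=1e-12
        )


class TestDelong:
    def test_perfect_separation_zero_se(self):
        est = delong_variance([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert est.auc == 1.0
        assert est.se == 0.0

    @pytest.mark.parametrize("n_neg, n_pos, seed", [(3, 3, 0), (10, 7, 1), (25, 25, 2), (30, 20, 3)])
    def test_matches_brute_force_oracle(self, n_neg, n_pos, seed):
        scores, states = generate_binormal_scores(n_neg, n_pos, 0, 1, 0.8, 1.2, seed=seed)
        # inject ties to exercise the midrank path
        scores = np.round(scores, 1)
        est = delong_variance(scores, states)
        auc_bf, se_bf = brute_force_delong(scores, states)
        assert est.auc == pytest.approx(auc_bf, abs=1e-14)
        assert est.se == pytest.approx(se_bf, abs=1e-14)

    def test_se_shrinks_with_sample_size(self):
        # quadrupling both classes should roughly halve the standard error
        ses = []
        for n in (50, 200):
            vals = [
                delong_variance(*generate_binormal_scores(n, n, 0, 1, 1, 1, seed=s)).se
                for s in range(40)
            ]
            ses.append(np.mean(vals))
        assert ses[1] == pytest.approx(ses[0] / 2, rel=0.15)

    def test_degenerate_class_sizes_rejected(self):
        with pytest.raises(ValueError):
            delong_variance([1, 2, 3], [0, 0, 1])

    def test_identical_groups_z_zero(self):
        s, y = generate_binormal_scores(20, 20, 0, 1, 1, 1, seed=0)
        z, p = delong_test((s, y), (s, y))
        assert z == 0.0
        assert p == 1.0

    def test_unpaired_z_matches_hand_ratio(self):
        sa, ya = generate_binormal_scores(15, 15, 0, 1, 1, 1, seed=1)
        sb, yb = generate_binormal_scores(18, 12, 0, 1, 0.5, 1, seed=2)
        ea = delong_variance(sa, ya)
        eb = delong_variance(sb, yb)
        z, p = delong_test((sa, ya), (sb, yb))
        assert z == pytest.approx((ea.auc - eb.auc) / math.hypot(ea.se, eb.se))
        assert 0.0 <= p <= 1.0

    def test_paired_requires_same_subjects(self):
        sa, ya = generate_binormal_scores(10, 10, 0, 1, 1, 1, seed=3)
        sb, yb = generate_binormal_scores(10, 9, 0, 1, 1, 1, seed=4)
        with pytest.raises(ValueError):
            delong_test((sa, ya), (sb, yb), paired=True)

    def test_paired_less_variable_than_unpaired_for_correlated_scores(self, rng):
        base, y = generate_binormal_scores(60, 60, 0, 1, 1.2, 1, seed=5)
        other = base + rng.normal(0, 0.3, len(base))
        z_paired, _ = delong_test((base, y), (other, y), paired=True)
        z_unpaired, _ = delong_test((base, y), (other, y), paired=False)
        assert abs(z_paired) >= abs(z_unpaired)


class TestCutoffIndices:
    @pytest.mark.parametrize(
        "se, sp, expected",
        [(0.826, 0.821, 0.647), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0)],
    )
    def test_youden(self, se, sp, expected):
        assert youden(se, sp) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "se, sp, expected",
        [(0.803, 0.806, 0.27649), (1.0, 1.0, 0.0), (0.865, 0.667, 0.35932)],
    )
    def test_roc_distance(self, se, sp, expected):
        assert roc_distance(se, sp) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "se, sp, lr_pos",
        [(0.826, 0.821, 4.6145), (0.5, 0.5, 1.0), (0.803, 0.806, 4.1392)],
    )
    def test_lr_positive(self, se, sp, lr_pos):
        lrp, lrn = likelihood_ratios(se, sp)
        assert lrp == pytest.approx(lr_pos, abs=1e-3)
        assert lrn >= 0

    def test_uninformative_test_has_unit_ratios(self):
        assert likelihood_ratios(0.5, 0.5) == (1.0, 1.0)

    def test_lr_unbounded_at_full_specificity(self):
        lrp, _ = likelihood_ratios(0.9, 1.0)
        assert math.isinf(lrp)

    @pytest.mark.parametrize("fn", [youden, roc_distance, likelihood_ratios])
    def test_out_of_range_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.2, 0.5)


class TestOptimalCutoff:
    @staticmethod
    def brute_force_best(curve, key):
        best, best_key = None, None
        for t, se, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            k = key(se, sp)
            if best_key is None or k > best_key:
                best, best_key = t, k
        return best

    def test_max_youden_matches_exhaustive_search(self):
        scores, states = generate_binormal_scores(20, 20, 0, 1, 1, 1, seed=6)
        curve = empirical_roc(scores, states)
        report = select_optimal_cutoff(curve, policy="max_youden")
        assert report.indices.youden_j == pytest.approx(
            max(se + sp - 1 for se, sp in zip(curve.sensitivity, curve.specificity))
        )

    def test_min_distance_matches_exhaustive_search(self):
        scores, states = generate_binormal_scores(20, 20, 0, 1, 1, 1, seed=7)
        curve = empirical_roc(scores, states)
        report = select_optimal_cutoff(curve, policy="min_distance")
        assert report.indices.roc_distance == pytest.approx(
            min(
                math.hypot(1 - se, 1 - sp)
                for se, sp in zip(curve.sensitivity, curve.specificity)
            )
        )

    def test_perfect_separation_reports_corner(self):
        scores = [1, 2, 3, 10, 11, 12]
        states = [0, 0, 0, 1, 1, 1]
        report = cutoff_analysis(scores, states)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        assert 3 < report.threshold <= 10

    def test_binormal_midpoint_recovery(self):
        # with equal SDs the Youden-optimal threshold is the midpoint of the means
        cuts = [
            select_optimal_cutoff(
                empirical_roc(*generate_binormal_scores(400, 400, 0, 1, 2, 1, seed=s)),
                policy="max_youden",
            ).threshold
            for s in range(30)
        ]
        assert np.mean(cuts) == pytest.approx(1.0, abs=0.1)

    def test_invariant_under_monotone_transform(self):
        scores, states = generate_binormal_scores(30, 30, 0, 1, 1, 1, seed=8)
        rep1 = cutoff_analysis(scores, states)
        rep2 = cutoff_analysis(np.exp(scores), states)
        assert rep2.threshold == pytest.approx(math.exp(rep1.threshold))
        assert rep2.sensitivity == rep1.sensitivity
        assert rep2.specificity == rep1.specificity
        assert rep2.indices.youden_j == pytest.approx(rep1.indices.youden_j)
        assert rep2.auc.auc == pytest.approx(rep1.auc.auc)

    def test_unknown_policy_rejected(self):
        curve = empirical_roc([1, 2], [0, 1])
        with pytest.raises(ValueError):
            select_optimal_cutoff(curve, policy="bogus")
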