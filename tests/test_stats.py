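"""Tests for the nonparametric statistics engine.

Each procedure is checked against an independent oracle: pairwise counting
and label enumeration for Mann–Whitney, explicit pair counting for AUC,
and scipy's ranking/correlation for Spearman.
"""

import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from bkarisk import (
    CapabilityError,
    CorrelationBand,
    ValidationError,
    interpret_correlation,
    mann_whitney,
    roc_auc,
    spearman,
)
from bkarisk.stats import midranks

from conftest import (
    auc_pair_counting,
    mw_exact_p_bruteforce,
    mw_u_pairwise,
    spearman_r_oracle,
)


class TestMannWhitney:
    def test_separated_pairs_exact_p(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3, abs=1e-15)

    def test_all_tied_is_symmetric(self):
        res = mann_whitney([5, 5], [5, 5])
        assert res.u_statistic == 2  # n1*n2/2
        assert res.p_value == 1.0
        assert res.z_statistic == 0.0

    def test_interleaved_matches_bruteforce(self):
        a, b = [1, 3, 5], [2, 4, 6]
        res = mann_whitney(a, b, method="exact")
        assert res.u_statistic == mw_u_pairwise(a, b)
        assert res.p_value == pytest.approx(mw_exact_p_bruteforce(a, b),
                                            abs=1e-12)

    def test_exact_p_matches_enumeration_on_random_tied_data(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 7))
            a = rng.integers(0, 5, size=n1).tolist()
            b = rng.integers(0, 5, size=n2).tolist()
            res = mann_whitney(a, b, method="exact")
            assert res.u_statistic == pytest.approx(mw_u_pairwise(a, b))
            assert res.p_value == pytest.approx(
                mw_exact_p_bruteforce(a, b), abs=1e-12
            ), (a, b)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.permutation(20)[: rng.integers(2, 7)].tolist()
            b = [x + 0.5 for x in rng.permutation(20)[: rng.integers(2, 7)]]
            ours = mann_whitney(a, b, method="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_agrees_with_scipy(self):
        rng = np.random.default_rng(13)
        a = rng.integers(0, 8, size=25).tolist()
        b = (rng.integers(0, 8, size=30) + 1).tolist()
        ours = mann_whitney(a, b, method="normal_approx")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_group_swap_symmetry(self, data):
        a = data.draw(st.lists(st.integers(0, 6), min_size=1, max_size=6))
        b = data.draw(st.lists(st.integers(0, 6), min_size=1, max_size=6))
        ab = mann_whitney(a, b, method="exact")
        ba = mann_whitney(b, a, method="exact")
        assert ab.u_statistic + ba.u_statistic == len(a) * len(b)
        assert ab.z_statistic == pytest.approx(-ba.z_statistic, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_auto_switches_to_normal_for_large_samples(self):
        rng = np.random.default_rng(3)
        res = mann_whitney(rng.normal(size=40), rng.normal(size=40))
        assert res.method == "normal_approx"

    def test_exact_beyond_limit_is_a_capability_error(self):
        with pytest.raises(CapabilityError):
            mann_whitney(list(range(40)), list(range(40)), method="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([3, 4, 1, 2], [True, True, False, False])
        assert res.auc == 1.0
        assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)

    def test_all_scores_tied_gives_half(self):
        assert roc_auc([7, 7, 7, 7], [1, 0, 1, 0]).auc == 0.5

    def test_hand_counted_tied_example(self):
        # positives {1,2,3} vs negatives {2,3,4}: 2 wins + 2 half-ties of 9
        res = roc_auc([1, 2, 3, 2, 3, 4], [1, 1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(2 / 9, abs=1e-15)

    def test_direction_flip_is_exact_complement(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            s = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            hi = roc_auc(s, y, direction="higher_score_positive")
            lo = roc_auc(s, y, direction="lower_score_positive")
            assert lo.auc == 1.0 - hi.auc  # bitwise complement

    def test_auc_equals_pair_counting_and_curve_area(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            s = rng.integers(0, 7, size=n).astype(float)
            y = rng.integers(0, 2, size=n).astype(bool)
            if y.all() or not y.any():
                continue
            res = roc_auc(s, y)
            assert res.auc == pytest.approx(
                auc_pair_counting(s.tolist(), y.tolist()), abs=1e-12
            )
            xs = [p[0] for p in res.points]
            ys = [p[1] for p in res.points]
            assert np.trapezoid(ys, xs) == pytest.approx(res.auc, abs=1e-12)
            assert all(np.diff(xs) >= 0) and all(np.diff(ys) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2], [True])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).r == 1.0
        assert spearman([1, 2, 3], [30, 20, 10]).r == -1.0

    def test_tied_example_matches_midrank_pearson(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        res = spearman(x, y)
        assert res.r == pytest.approx(spearman_r_oracle(x, y), abs=1e-12)

    def test_r_matches_scipy_on_random_tied_data(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            n = int(rng.integers(3, 25))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ours = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert ours.r == pytest.approx(float(ref.statistic), abs=1e-12)
            if n > 8:  # same t-approximation regime
                assert ours.p_value == pytest.approx(float(ref.pvalue),
                                                     rel=1e-9)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(29)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3) == spearman(x, y)
        assert spearman(3 * x + 1, np.arctan(y)).r == pytest.approx(
            base, abs=1e-12
        )

    def test_exact_permutation_p_is_symmetric_in_arguments(self):
        x, y = [1, 2, 2, 4, 5], [3, 1, 4, 4, 2]
        assert spearman(x, y).p_value == spearman(y, x).p_value

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [3, 4])


class TestInterpretCorrelation:
    @pytest.mark.parametrize(
        "r, band",
        [
            (-0.757, CorrelationBand.STRONG),
            (0.05, CorrelationBand.NEGLIGIBLE),
            (0.40, CorrelationBand.MODERATE),
            (0.0, CorrelationBand.NEGLIGIBLE),
            (0.10, CorrelationBand.WEAK),
            (-0.39, CorrelationBand.WEAK),
            (0.69, CorrelationBand.MODERATE),
            (0.70, CorrelationBand.STRONG),
            (-0.89, CorrelationBand.STRONG),
            (0.90, CorrelationBand.VERY_STRONG),
            (-1.0, CorrelationBand.VERY_STRONG),
        ],
    )
    def test_band_boundaries(self, r, band):
        assert interpret_correlation(r) is band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            interpret_correlation(1.01)


def test_midranks_average_tied_positions():
    assert midranks([10, 20, 20, 30]).tolist() == [1.0, 2.5, 2.5, 4.0]
    assert midranks([5, 5, 5]).tolist() == [2.0, 2.0, 2.0]
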