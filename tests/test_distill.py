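import math

import numpy as np
import pytest

from dualdistill.distill import (
    DistillConfig,
    LossBreakdown,
    combine_teacher_soft_labels,
    compute_distill_loss,
    cross_entropy,
    js_divergence,
    kl_divergence,
    max_out,
    temperature_softmax,
)
from dualdistill.schedules import ScheduleParams

from conftest import js_oracle, kl_oracle, random_distribution_pairs

LN2 = math.log(2.0)


class TestTemperatureSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(temperature_softmax([0.0, 0.0], 2.0), [0.5, 0.5])

    def test_closed_form(self):
        np.testing.assert_allclose(
            temperature_softmax([math.log(2.0), 0.0], 1.0), [2 / 3, 1 / 3]
        )

    def test_sharpening_at_low_temperature(self):
        # softmax((1,0)/0.5) == softmax((2,0))
        expect = np.exp([2.0, 0.0]) / np.exp([2.0, 0.0]).sum()
        np.testing.assert_allclose(
            temperature_softmax([1.0, 0.0], 0.5), expect, atol=1e-12
        )
        assert temperature_softmax([1.0, 0.0], 0.5)[0] == pytest.approx(0.88080, abs=1e-5)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            temperature_softmax([1.0, 0.0], 0.0)
        with pytest.raises(ValueError):
            temperature_softmax([], 1.0)
        with pytest.raises(ValueError):
            temperature_softmax([np.inf, 0.0], 1.0)

    def test_shift_stability_with_huge_logits(self):
        p = temperature_softmax([1000.0, 999.0], 1.0)
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)


class TestMaxOut:
    def test_idempotence(self):
        p = np.array([0.3, 0.3, 0.4])
        np.testing.assert_array_equal(max_out(p, p), p)

    def test_elementwise(self):
        np.testing.assert_allclose(
            max_out([0.7, 0.2, 0.1], [0.1, 0.2, 0.7]), [0.7, 0.2, 0.7]
        )

    def test_degenerate_one_hots(self):
        np.testing.assert_array_equal(max_out([1.0, 0.0], [0.0, 1.0]), [1.0, 1.0])

    def test_dominates_both_inputs_and_sum_at_least_one(self):
        for p, q in random_distribution_pairs(200, 6, seed=11):
            m = max_out(p, q)
            assert np.all(m >= p) and np.all(m >= q)
            assert m.sum() >= 1.0 - 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            max_out([0.5, 0.5], [0.2, 0.3, 0.5])


class TestCombineTeacherSoftLabels:
    def test_identical_teachers_reduce_to_single_teacher(self):
        # dual-teacher fusion of one duplicated teacher is classical KD
        logits = np.array([2.0, 0.5, -1.0])
        for T in (0.5, 1.0, 3.0):
            np.testing.assert_allclose(
                combine_teacher_soft_labels(logits, logits, T),
                temperature_softmax(logits, T),
                atol=1e-12,
            )

    def test_renormalized_max_example(self):
        fused = combine_teacher_soft_labels(
            np.log([0.7, 0.2, 0.1]), np.log([0.1, 0.2, 0.7]), 1.0
        )
        np.testing.assert_allclose(fused, [0.4375, 0.125, 0.4375], atol=1e-9)

    def test_disagreeing_confident_teachers_yield_uniform_pair(self):
        t1 = np.array([50.0, 0.0, 0.0, 0.0])
        t2 = np.array([0.0, 50.0, 0.0, 0.0])
        fused = combine_teacher_soft_labels(t1, t2, 1.0)
        np.testing.assert_allclose(fused, [0.5, 0.5, 0.0, 0.0], atol=1e-9)

    def test_raw_mode_is_unnormalized(self):
        cfg = DistillConfig(renormalize_soft_label=False)
        fused = combine_teacher_soft_labels(
            np.log([0.7, 0.2, 0.1]), np.log([0.1, 0.2, 0.7]), 1.0, cfg
        )
        assert fused.sum() == pytest.approx(1.6, abs=1e-9)

    def test_output_is_distribution_on_random_logits(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            z1, z2 = rng.normal(size=(2, 8)) * 3
            fused = combine_teacher_soft_labels(z1, z2, rng.uniform(0.1, 3.0))
            assert fused.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(fused >= 0)


class TestDivergences:
    def test_kl_identity_is_zero(self):
        for p, _ in random_distribution_pairs(50, 5, seed=3):
            assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_kl_closed_form(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(LN2, abs=1e-12)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            kl_oracle([0.5, 0.5], [0.25, 0.75]), abs=1e-12
        )
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.14384, abs=1e-5)

    def test_kl_nonnegative_and_matches_oracle_on_random_pairs(self):
        for p, q in random_distribution_pairs(1000, 7, seed=21):
            v = kl_divergence(p, q)
            assert v >= 0.0
            assert v == pytest.approx(kl_oracle(p, q), abs=1e-10)

    def test_kl_zero_iff_equal(self):
        for p, q in random_distribution_pairs(100, 4, seed=9):
            assert kl_divergence(p, q) > 1e-8  # Dirichlet pairs a.s. distinct

    def test_js_identity_symmetry_bounds_against_oracle(self):
        for p, q in random_distribution_pairs(1000, 6, seed=31):
            v = js_divergence(p, q)
            assert v == pytest.approx(js_oracle(p, q), abs=1e-10)
            assert v == pytest.approx(js_divergence(q, p), abs=1e-12)
            assert -1e-12 <= v <= LN2 + 1e-12
        assert js_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_js_maximal_disagreement(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(LN2, abs=1e-9)

    def test_js_example(self):
        assert js_divergence([0.8, 0.2], [0.2, 0.8]) == pytest.approx(0.19274, abs=1e-5)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero_within_clamp(self):
        assert cross_entropy([0.0, 1.0, 0.0], [0.0, 1.0, 0.0]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_examples(self):
        assert cross_entropy([0.0, 1.0, 0.0], [0.1, 0.8, 0.1]) == pytest.approx(
            -math.log(0.8), abs=1e-12
        )
        assert cross_entropy([1.0, 0.0], [0.5, 0.5]) == pytest.approx(LN2, abs=1e-12)

    def test_rejects_soft_labels(self):
        with pytest.raises(ValueError):
            cross_entropy([0.5, 0.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            cross_entropy([1.0, 1.0], [0.5, 0.5])


class TestComposedLoss:
    T1, T2 = np.log([0.7, 0.2, 0.1]), np.log([0.1, 0.2, 0.7])
    HARD = np.array([1.0, 0.0, 0.0])

    def test_identical_student_and_teachers_with_no_hard_weight(self):
        z = np.array([1.0, -0.5, 0.3])
        lb = compute_distill_loss(z, z, z, self.HARD, x=0.5, lam_override=0.0)
        assert lb.total == pytest.approx(0.0, abs=1e-12)

    def test_hard_only_endpoint(self):
        z = np.array([0.2, 0.1, -0.3])
        lb = compute_distill_loss(z, self.T1, self.T2, self.HARD, x=0.2, lam_override=1.0)
        assert lb.total == pytest.approx(lb.l_hard, abs=1e-12)

    def test_three_class_hand_composed_example(self):
        # scale=2 makes T(0.5)=1 exactly; lambda(0.5)=0.5
        params = ScheduleParams(scale=2.0)
        lb = compute_distill_loss(
            np.zeros(3), self.T1, self.T2, self.HARD, x=0.5, params=params
        )
        expected_soft = js_oracle([0.4375, 0.125, 0.4375], [1 / 3, 1 / 3, 1 / 3])
        assert lb.T == pytest.approx(1.0, abs=1e-12)
        assert lb.l_soft == pytest.approx(expected_soft, abs=1e-10)
        assert lb.l_hard == pytest.approx(math.log(3.0), abs=1e-12)
        assert lb.total == pytest.approx(
            0.5 * expected_soft + 0.5 * math.log(3.0), abs=1e-10
        )

    def test_total_is_convex_combination(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            z, z1, z2 = rng.normal(size=(3, 5)) * 2
            hard = np.zeros(5)
            hard[rng.integers(5)] = 1.0
            lb = compute_distill_loss(z, z1, z2, hard, x=rng.uniform(0, 1))
            lo, hi = sorted((lb.l_soft, lb.l_hard))
            assert lo - 1e-12 <= lb.total <= hi + 1e-12

    def test_t_squared_scaling_flag(self):
        z = np.array([0.4, -0.2, 0.0])
        plain = compute_distill_loss(z, self.T1, self.T2, self.HARD, x=0.8)
        scaled = compute_distill_loss(
            z, self.T1, self.T2, self.HARD, x=0.8, config=DistillConfig(t_squared_scaling=True)
        )
        assert scaled.l_soft == pytest.approx(plain.l_soft * plain.T**2, rel=1e-9)

    def test_literal_division_mode_raises(self):
        with pytest.raises(ValueError, match="not distributions"):
            compute_distill_loss(
                np.zeros(3), self.T1, self.T2, self.HARD, x=0.5,
                config=DistillConfig(literal_division_mode=True),
            )

    def test_breakdown_invariant_enforced(self):
        with pytest.raises(ValueError):
            LossBreakdown(T=1.0, lam=0.5, l_soft=1.0, l_hard=1.0, total=0.3)
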