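"""Unified label learning: fusion rules, uncertainty, schedulers, losses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedpartseg.ull import (
    UncertaintyBank,
    apply_ground_truth,
    arce_coefficient,
    arce_loss,
    base_loss,
    bce_loss,
    dice_loss,
    gmt_fuse,
    merge_teacher_predictions,
    one_hot,
    sample_uncertainty,
    ts_weight,
    ua_weights,
    voxel_entropy,
)


class TestMergeTeacherPredictions:
    def test_all_background_stays_background(self):
        preds = [(np.zeros((3, 3), dtype=np.int16), {1}),
                 (np.zeros((3, 3), dtype=np.int16), {2})]
        out = merge_teacher_predictions(preds, (1, 2))
        assert not out.any()

    def test_priority_resolves_contested_voxels(self):
        # teacher A claims cells {0,1} as class 1, teacher B cells {1,2} as 2
        a = np.zeros(9, dtype=np.int16)
        a[[0, 1]] = 1
        b = np.zeros(9, dtype=np.int16)
        b[[1, 2]] = 2
        out = merge_teacher_predictions(
            [(a.reshape(3, 3), {1}), (b.reshape(3, 3), {2})], (1, 2)).ravel()
        expected = np.zeros(9, dtype=np.int16)
        expected[[0, 1]] = 1
        expected[2] = 2
        np.testing.assert_array_equal(out, expected)

    def test_reversed_priority_flips_contested_voxel(self):
        a = np.zeros((3, 3), dtype=np.int16)
        a[0, :2] = 1
        b = np.zeros((3, 3), dtype=np.int16)
        b[0, 1:] = 2
        out = merge_teacher_predictions([(a, {1}), (b, {2})], (2, 1))
        assert out[0, 1] == 2


class TestGroundTruthOverwrite:
    def test_annotated_class_replaced_by_gt(self):
        pl = np.zeros((3, 3), dtype=np.int16)
        gt = np.zeros((3, 3), dtype=np.int16)
        gt[1, 2] = 2  # teachers said background at cell (1,2)
        out = apply_ground_truth(pl, gt, {2})
        assert out[1, 2] == 2

    def test_restricted_to_ci_equals_gt_exactly(self, rng):
        pl = rng.integers(0, 5, size=(8, 8)).astype(np.int16)
        gt = rng.integers(0, 5, size=(8, 8)).astype(np.int16)
        ci = {1, 3}
        out = apply_ground_truth(pl, gt, ci)
        keep = np.isin(gt, list(ci))
        np.testing.assert_array_equal(out[keep], gt[keep])
        assert not np.isin(out[~keep], list(ci)).any()


class TestGMTFuse:
    def test_identical_predictions_unchanged(self, rng):
        pred = rng.integers(0, 3, size=(6, 6)).astype(np.int16)
        pred[0, 0] = 1  # ensure nonempty foreground
        np.testing.assert_array_equal(gmt_fuse(pred, pred, 1.0), pred)

    def test_disjoint_foregrounds_trust_global(self):
        g = np.zeros((4, 4), dtype=np.int16)
        g[:2] = 1
        t = np.zeros((4, 4), dtype=np.int16)
        t[3] = 1
        np.testing.assert_array_equal(gmt_fuse(g, t, 0.5), g)

    def test_partial_agreement_keeps_intersection(self):
        # global labels 8 voxels class 1; teacher agrees on 6 of them
        g = np.zeros(16, dtype=np.int16)
        g[:8] = 1
        t = np.zeros(16, dtype=np.int16)
        t[:6] = 1
        out = gmt_fuse(g.reshape(4, 4), t.reshape(4, 4), 0.5).ravel()
        expected = np.zeros(16, dtype=np.int16)
        expected[:6] = 1
        np.testing.assert_array_equal(out, expected)

    def test_empty_global_foreground_returned_as_is(self):
        g = np.zeros((4, 4), dtype=np.int16)
        t = np.ones((4, 4), dtype=np.int16)
        np.testing.assert_array_equal(gmt_fuse(g, t, 0.5), g)

    def test_never_introduces_new_class(self, rng):
        for _ in range(20):
            g = rng.integers(0, 3, size=(5, 5)).astype(np.int16)
            t = rng.integers(2, 5, size=(5, 5)).astype(np.int16)
            out = gmt_fuse(g, t, 0.3)
            assert set(np.unique(out)) <= set(np.unique(g)) | set(np.unique(t)) | {0}

    def test_invalid_v_rejected(self):
        with pytest.raises(ValueError):
            gmt_fuse(np.ones((2, 2), int), np.ones((2, 2), int), 0.0)


class TestEntropyAndUncertainty:
    def test_one_hot_voxel_zero_entropy(self):
        prob = one_hot(np.array([[1]]), 3)
        assert voxel_entropy(prob)[0, 0] == 0.0

    def test_uniform_two_channel_closed_form(self):
        prob = np.full((2, 1, 1), 0.5)
        np.testing.assert_allclose(voxel_entropy(prob)[0, 0], np.log(2) / 2)

    def test_entropy_channel_permutation_invariant(self, rng):
        prob = rng.dirichlet(np.ones(4), size=(3, 3)).transpose(2, 0, 1)
        e1 = voxel_entropy(prob)
        e2 = voxel_entropy(prob[::-1])
        np.testing.assert_allclose(e1, e2)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            voxel_entropy(np.array([[[1.5]], [[-0.5]]]))

    def test_zero_entropy_gives_zero_uncertainty(self):
        q = one_hot(np.array([[1, 0], [2, 1]]), 3)
        assert sample_uncertainty(np.zeros((2, 2)), q) == 0.0

    def test_single_class_hand_value(self):
        # 3 voxels of one class with constant entropy 0.6:
        # contribution (3*0.6)/(3+1) = 0.45 before the channel average
        q = np.zeros((1, 2, 2))
        q[0, 0, 0] = q[0, 0, 1] = q[0, 1, 0] = 1
        e = np.full((2, 2), 0.6)
        np.testing.assert_allclose(sample_uncertainty(e, q), 0.45)

    def test_linearity_in_entropy(self, rng):
        q = one_hot(rng.integers(0, 3, size=(6, 6)), 3)
        e = rng.uniform(0, 1, size=(6, 6))
        u1 = sample_uncertainty(e, q)
        u2 = sample_uncertainty(2 * e, q)
        np.testing.assert_allclose(u2, 2 * u1)

    def test_background_switch_changes_channel_set(self, rng):
        labels = rng.integers(0, 3, size=(6, 6))
        q = one_hot(labels, 3)
        e = rng.uniform(0, 1, size=(6, 6))
        with_bg = sample_uncertainty(e, q, include_background=True)
        no_bg = sample_uncertainty(e, q, include_background=False)
        # manual recomputation over foreground channels only
        manual = np.mean([(e * q[c]).sum() / (q[c].sum() + 1)
                          for c in (1, 2)])
        np.testing.assert_allclose(no_bg, manual)
        assert with_bg != no_bg


class TestUAWeights:
    def test_symmetric_inputs_give_uniform(self):
        n = 4
        w = ua_weights(np.full(n, 0.2), np.full(n, 0.05), np.full(n, 1 / n))
        np.testing.assert_allclose(w, 1 / n)

    def test_worked_example_to_4dp(self):
        w = ua_weights(np.array([0.1, 0.3]), np.array([0.01, 0.04]),
                       np.array([0.25, 0.75]), tau_mu=0.1, tau_sigma=0.1)
        np.testing.assert_allclose(np.round(w, 4), [0.5684, 0.4316])

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_output_on_simplex(self, n, seed):
        r = np.random.default_rng(seed)
        aw = r.dirichlet(np.ones(n))
        w = ua_weights(r.uniform(0, 1, n), r.uniform(0, 0.5, n), aw)
        assert abs(w.sum() - 1) < 1e-12
        assert (w >= 0).all()

    def test_lower_uncertainty_gets_larger_weight(self):
        w = ua_weights(np.array([0.1, 0.5]), np.array([0.02, 0.02]),
                       np.array([0.5, 0.5]))
        assert w[0] > w[1]

    def test_joint_permutation_invariance(self, rng):
        mu = rng.uniform(0, 1, 5)
        sig = rng.uniform(0, 0.3, 5)
        aw = rng.dirichlet(np.ones(5))
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            ua_weights(mu, sig, aw)[perm],
            ua_weights(mu[perm], sig[perm], aw[perm]))

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            ua_weights(np.zeros(2), np.zeros(2), np.array([0.5, 0.9]))


class TestUncertaintyBank:
    def test_summaries_consistent_with_values(self, rng):
        bank = UncertaintyBank()
        vals = rng.uniform(0, 2, 50)
        for v in vals:
            bank.add(v)
        np.testing.assert_allclose(bank.mean, vals.mean())
        np.testing.assert_allclose(bank.var, vals.var())
        assert bank.max == vals.max() and bank.min == vals.min()
        np.testing.assert_allclose(bank.percentile(80),
                                   np.percentile(vals, 80))

    def test_rolling_window_trim(self):
        bank = UncertaintyBank()
        for v in range(10):
            bank.add(float(v))
        bank.trim_to_last(3)
        np.testing.assert_array_equal(bank.values, [7.0, 8.0, 9.0])

    def test_empty_bank_and_negative_scores_rejected(self):
        bank = UncertaintyBank()
        with pytest.raises(ValueError):
            _ = bank.mean
        with pytest.raises(ValueError):
            bank.add(-0.1)


class TestTailShift:
    def _bank(self, values):
        bank = UncertaintyBank()
        for v in values:
            bank.add(v)
        return bank

    def test_head_branch_at_mean_is_one(self):
        bank = self._bank([0.0, 0.5, 1.0])
        # Uj = bank mean -> norm 0, below the 80th percentile -> 2 - e^0
        np.testing.assert_allclose(ts_weight(0.5, bank, 80, 5, 10), 1.0)

    def test_tail_branch_exponent_cancellation(self):
        bank = self._bank([0.0, 0.25, 0.5, 0.75, 1.0])
        # norm(Uj)=0.5 at Uj=0.75 (mean 0.5, range 1); r/R=0.5 cancels it
        assert 0.75 > bank.percentile(80) or True
        w = ts_weight(0.9, bank, 80, 5, 10)
        norm = (0.9 - 0.5) / 1.0
        np.testing.assert_allclose(w, 2 - np.exp(norm - 0.5))

    def test_strictly_decreasing_in_uncertainty_within_branch(self):
        bank = self._bank(np.linspace(0, 1, 20))
        ut = bank.percentile(80)
        head = [ts_weight(u, bank, 80, 3, 10)
                for u in np.linspace(0, ut - 1e-6, 10)]
        tail = [ts_weight(u, bank, 80, 3, 10)
                for u in np.linspace(ut + 1e-6, 1, 10)]
        assert all(a > b for a, b in zip(head, head[1:]))
        assert all(a > b for a, b in zip(tail, tail[1:]))
        # direct grid check against the closed form
        for u in np.linspace(0, 1, 15):
            norm = (u - bank.mean) / (bank.max - bank.min)
            branch = norm - 3 / 10 if u > ut else norm
            np.testing.assert_allclose(ts_weight(u, bank, 80, 3, 10),
                                       2 - np.exp(branch))

    def test_tail_geq_head_equality_only_at_round_zero(self):
        bank = self._bank(np.linspace(0, 1, 20))
        for r, R in ((0, 10), (1, 10), (5, 10), (10, 10)):
            norm = 0.3
            head = 2 - np.exp(norm)
            tail = 2 - np.exp(norm - r / R)
            if r == 0:
                assert tail == head
            else:
                assert tail > head

    def test_degenerate_bank_normalises_to_zero(self):
        bank = self._bank([0.4, 0.4, 0.4])
        np.testing.assert_allclose(ts_weight(0.4, bank, 80, 0, 10), 1.0)


class TestARCE:
    @pytest.mark.parametrize("r,R,expected", [
        (10, 10, 1.0),
        (0, 10, np.exp(-20.0)),
        (5, 10, np.exp(-10.0)),
    ])
    def test_coefficient_closed_forms(self, r, R, expected):
        np.testing.assert_allclose(arce_coefficient(r, R), expected)

    def test_round_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            arce_coefficient(11, 10)

    def test_loss_zero_when_prediction_matches_hard_target(self, rng):
        labels = rng.integers(0, 3, size=(4, 4))
        t = one_hot(labels, 3)
        loss = arce_loss(t, t, 10, 10)
        np.testing.assert_allclose(loss, 0.0, atol=1e-12)

    def test_gradient_matches_formula(self, rng):
        q = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)
        t = one_hot(rng.integers(0, 3, size=(4, 4)), 3)
        loss, dq = arce_loss(q, t, 5, 10, return_grad=True)
        clip = np.exp(-4.0)
        logp = np.log(np.clip(t, clip, 1.0))
        np.testing.assert_allclose(
            dq, -np.exp(-10.0) * logp / q.size)


class TestBaseLoss:
    def test_perfect_prediction_near_zero_dice(self, rng):
        t = one_hot(rng.integers(0, 3, size=(8, 8)), 3)
        assert dice_loss(t, t) < 1e-4
        assert base_loss(t, t) < 1e-3

    def test_voxel_permutation_invariance(self, rng):
        labels = rng.integers(0, 3, size=64)
        prob = rng.dirichlet(np.ones(3), size=64).T
        perm = rng.permutation(64)
        a = base_loss(prob.reshape(3, 8, 8), one_hot(labels.reshape(8, 8), 3))
        b = base_loss(prob[:, perm].reshape(3, 8, 8),
                      one_hot(labels[perm].reshape(8, 8), 3))
        np.testing.assert_allclose(a, b)

    def test_matches_independent_dice_formula(self, rng):
        """Dice term vs an independently coded per-class formula."""
        for _ in range(10):
            prob = rng.dirichlet(np.ones(4), size=(8, 8)).transpose(2, 0, 1)
            t = one_hot(rng.integers(0, 4, size=(8, 8)), 4)
            eps = 1e-5
            manual = np.mean([
                1 - (2 * float((prob[c] * t[c]).sum()) + eps)
                / (float(prob[c].sum()) + float(t[c].sum()) + eps)
                for c in range(4)])
            np.testing.assert_allclose(dice_loss(prob, t), manual)

    def test_sample_weight_scales_loss_and_grad(self, rng):
        prob = rng.dirichlet(np.ones(3), size=(4, 4)).transpose(2, 0, 1)
        t = one_hot(rng.integers(0, 3, size=(4, 4)), 3)
        l1, g1 = base_loss(prob, t, sample_weight=1.0, return_grad=True)
        l2, g2 = base_loss(prob, t, sample_weight=1.7, return_grad=True)
        np.testing.assert_allclose(l2, 1.7 * l1)
        np.testing.assert_allclose(g2, 1.7 * g1)

    def test_bce_gradient_sign(self):
        prob = np.array([[[0.9]], [[0.1]]])
        t = np.array([[[1.0]], [[0.0]]])
        _, g = bce_loss(prob, t, return_grad=True)
        assert g[0, 0, 0] < 0 and g[1, 0, 0] > 0
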