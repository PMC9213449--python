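"""The masked multi-task cost function and its weighting schemes."""

import math

import numpy as np
import pytest

from mtppi.loss import (
    LossWeights,
    batch_loss,
    task_loss,
    total_loss,
    weight_scheme,
)


def _random_instance(rng, n=100):
    """Random predictions/targets/masks for all five tasks."""
    preds, targets, masks = {}, {}, {}
    for t, k in (("IF", 2), ("BU", 2), ("S3", 3), ("S8", 8)):
        p = rng.random((n, k)) + 0.05
        preds[t] = p / p.sum(axis=1, keepdims=True)
        targets[t] = rng.integers(0, k, size=n)
        masks[t] = rng.random(n) < 0.7
    preds["SA"] = rng.random(n)
    targets["SA"] = rng.random(n)
    masks["SA"] = rng.random(n) < 0.7
    return preds, targets, masks


def _scalar_loop_loss(pred, target, mask, kind, w_pos=1.0):
    """Independent per-residue loop oracle."""
    total, n = 0.0, 0
    for i in range(len(mask)):
        if not mask[i]:
            continue
        n += 1
        if kind == "SA":
            total += (pred[i] - target[i]) ** 2
        else:
            ce = -math.log(pred[i][int(target[i])])
            if kind == "IF" and int(target[i]) == 1:
                ce *= w_pos
            total += ce
    return total / n if n else 0.0


class TestTaskLoss:
    def test_all_masked_returns_zero(self):
        p = np.full((4, 2), 0.5)
        assert task_loss(p, np.zeros(4), np.zeros(4, bool), "IF") == 0.0

    def test_uniform_binary_prediction_gives_ln2(self):
        p = np.full((2, 2), 0.5)
        out = task_loss(p, np.array([0, 1]), np.ones(2, bool), "BU")
        assert out == pytest.approx(math.log(2.0))

    def test_exact_sa_prediction_gives_zero(self):
        t = np.array([0.1, 0.5, 0.9])
        assert task_loss(t.copy(), t, np.ones(3, bool), "SA") == 0.0

    def test_masked_positions_never_affect_loss(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            preds, targets, masks = _random_instance(rng, n=50)
            for t in preds:
                base = task_loss(preds[t], targets[t], masks[t], t,
                                 if_positive_class_weight=6.37)
                perturbed = np.array(preds[t], dtype=float)
                hidden = ~masks[t]
                if t == "SA":
                    perturbed[hidden] = rng.random(hidden.sum()) * 100
                else:
                    p = rng.random((int(hidden.sum()), perturbed.shape[1])) + 0.01
                    perturbed[hidden] = p / p.sum(axis=1, keepdims=True)
                after = task_loss(perturbed, targets[t], masks[t], t,
                                  if_positive_class_weight=6.37)
                assert after == base  # exact, not approximate

    @pytest.mark.parametrize("kind", ["IF", "BU", "S3", "S8", "SA"])
    def test_vectorized_equals_scalar_loop_oracle(self, kind):
        rng = np.random.default_rng(1)
        preds, targets, masks = _random_instance(rng, n=100)
        got = task_loss(preds[kind], targets[kind], masks[kind], kind,
                        if_positive_class_weight=3.5)
        want = _scalar_loop_loss(preds[kind], targets[kind], masks[kind],
                                 kind, w_pos=3.5)
        assert got == pytest.approx(want, abs=1e-10)

    def test_class_weight_scales_positive_terms_exactly(self):
        rng = np.random.default_rng(2)
        p = rng.random((40, 2)) + 0.05
        p /= p.sum(axis=1, keepdims=True)
        y = rng.integers(0, 2, size=40)
        m = np.ones(40, bool)
        w = 6.37
        base_pos = task_loss(p, y, m & (y == 1), "IF")
        base_neg = task_loss(p, y, m & (y == 0), "IF")
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        weighted = task_loss(p, y, m, "IF", if_positive_class_weight=w)
        expected = (w * base_pos * n_pos + base_neg * n_neg) / 40
        assert weighted == pytest.approx(expected, abs=1e-12)

    def test_all_negative_labels_unaffected_by_class_weight(self):
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        y = np.zeros(2, dtype=int)
        m = np.ones(2, bool)
        assert task_loss(p, y, m, "IF", if_positive_class_weight=9.0) == \
            task_loss(p, y, m, "IF")

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            task_loss(np.array([[1.2, -0.2]]), np.array([0]),
                      np.ones(1, bool), "IF")
        with pytest.raises(ValueError):
            task_loss(np.array([[np.nan, 1.0]]), np.array([0]),
                      np.ones(1, bool), "IF")


class TestTotalLoss:
    def test_weighted_sum_recomputed_independently(self):
        rng = np.random.default_rng(3)
        preds, targets, masks = _random_instance(rng)
        w = LossWeights(alpha=0.4, beta=0.2, gamma=0.15, delta=0.15,
                        epsilon=0.1, if_positive_class_weight=6.37)
        report = batch_loss(preds, targets, masks, w)
        manual = sum(
            w[t] * task_loss(preds[t], targets[t], masks[t], t,
                             if_positive_class_weight=6.37)
            for t in ("IF", "BU", "S3", "S8", "SA")
        )
        assert report.total == pytest.approx(manual, abs=1e-12)

    def test_if_fully_masked_leaves_related_tasks_only(self):
        rng = np.random.default_rng(4)
        preds, targets, masks = _random_instance(rng)
        masks["IF"][:] = False
        w = weight_scheme("A", ("IF", "BU", "S3", "S8", "SA"))
        report = batch_loss(preds, targets, masks, w)
        related = sum(w[t] * report.losses[t] for t in ("BU", "S3", "S8", "SA"))
        assert report.losses["IF"] == 0.0
        assert report.counts["IF"] == 0
        assert report.total == pytest.approx(related, abs=1e-15)

    def test_single_task_reduction(self):
        rng = np.random.default_rng(5)
        preds, targets, masks = _random_instance(rng)
        w = LossWeights(alpha=1.0)
        out = total_loss(
            {"IF": task_loss(preds["IF"], targets["IF"], masks["IF"], "IF")},
            w,
        )
        assert out == task_loss(preds["IF"], targets["IF"], masks["IF"], "IF")

    def test_linearity_in_weights(self):
        losses = {"IF": 0.7, "BU": 0.3}
        w1 = LossWeights(alpha=0.25, beta=0.25)
        w2 = LossWeights(alpha=0.5, beta=0.5)
        assert total_loss(losses, w2) == pytest.approx(
            2.0 * total_loss(losses, w1)
        )

    def test_inactive_task_loss_rejected(self):
        w = LossWeights(alpha=1.0)
        with pytest.raises(ValueError, match="inactive"):
            total_loss({"IF": 0.5, "BU": 0.1}, w)


class TestWeightSchemes:
    def test_method_a_equal_weights(self):
        w = weight_scheme("A", ("IF", "BU", "S3", "SA"))
        assert [w[t] for t in ("IF", "BU", "S3", "SA")] == [0.25] * 4
        assert w["S8"] == 0.0

    def test_method_c_four_tasks(self):
        w = weight_scheme("C", ("IF", "BU", "S3", "SA"))
        assert w["IF"] == pytest.approx(0.5)
        for t in ("BU", "S3", "SA"):
            assert w[t] == pytest.approx(1.0 / 6.0)

    def test_method_c_interface_carries_half_of_total(self):
        w = weight_scheme("C", ("IF", "BU", "S3", "S8", "SA"))
        others = [w[t] for t in ("BU", "S3", "S8", "SA")]
        assert w["IF"] == pytest.approx(sum(others))
        assert len(set(round(v, 12) for v in others)) == 1

    @pytest.mark.parametrize("pairing", ["prose", "equation"])
    def test_method_b_grouping_constraints(self, pairing):
        """Each similarity group shares one task's weight, however paired."""
        w = weight_scheme("B", ("IF", "BU", "S3", "S8", "SA"),
                          method_b_pairing=pairing)
        groups = {
            "prose": (("S3", "S8"), ("BU", "SA")),
            "equation": (("BU", "S3"), ("S8", "SA")),
        }[pairing]
        for g in groups:
            assert sum(w[t] for t in g) == pytest.approx(w["IF"])
            assert w[g[0]] == pytest.approx(w[g[1]])

    def test_method_b_singleton_group_keeps_full_weight(self):
        w = weight_scheme("B", ("IF", "BU", "S3"))
        # S3's partner S8 is absent; BU's partner SA is absent
        assert w["S3"] == pytest.approx(w["IF"])
        assert w["BU"] == pytest.approx(w["IF"])

    def test_weights_normalized_to_one(self):
        for method in ("A", "B", "C"):
            w = weight_scheme(method, ("IF", "BU", "S3", "S8", "SA"))
            assert sum(w[t] for t in ("IF", "BU", "S3", "S8", "SA")) == \
                pytest.approx(1.0)

    def test_if_required_and_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="IF"):
            weight_scheme("A", ("BU", "S3"))
        with pytest.raises(ValueError, match="method"):
            weight_scheme("D", ("IF", "BU"))

    def test_negative_or_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)
        with pytest.raises(ValueError):
            LossWeights()
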