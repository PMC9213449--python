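"""Learning-rate schedule, early stopping and the training loop."""

import itertools

import numpy as np
import pytest

from mtppi.loss import batch_loss, weight_scheme
from mtppi.model import build_model, pad_batch, tiny_config
from mtppi.training import (
    TrainingConfig,
    count_decreases,
    early_stop,
    evaluate_model,
    load_checkpoint,
    lr_step,
    masked_training_loss,
    predict_records,
    repeat_protocol,
    save_checkpoint,
    train,
)


class TestSchedule:
    def test_no_decrease_keeps_lr(self):
        assert lr_step([0.70, 0.72], 2.5e-4) == 2.5e-4

    def test_decrease_halves_lr(self):
        assert lr_step([0.72, 0.71], 2.5e-4) == 1.25e-4

    def test_tie_is_not_a_decrease(self):
        assert lr_step([0.72, 0.72], 2.5e-4) == 2.5e-4
        assert not early_stop([0.7, 0.7, 0.7, 0.7, 0.7])

    def test_scripted_sequence_stops_at_fourth_decrease(self):
        seq = [0.70, 0.69, 0.71, 0.70, 0.72, 0.71, 0.73, 0.72]
        assert not early_stop(seq[:-1])
        assert early_stop(seq)

    def test_monotone_sequence_never_stops(self):
        assert not early_stop(list(np.linspace(0.5, 0.9, 50)))

    def test_four_consecutive_decreases(self):
        assert early_stop([0.70, 0.69, 0.68, 0.67, 0.66])

    def test_exhaustive_updown_patterns_against_counting_oracle(self):
        """All 2^10 up/down patterns of length 10: the stop flag fires at
        exactly the 4th strict decrease and lr = initial / 2^decreases."""
        initial = 2.5e-4
        for bits in itertools.product([1, -1], repeat=9):
            aucs = [0.5]
            for b in bits:
                aucs.append(aucs[-1] + 0.01 * b)
            # oracle: explicit scan
            oracle_decreases = sum(
                1 for i in range(1, len(aucs)) if aucs[i] < aucs[i - 1]
            )
            assert count_decreases(aucs) == oracle_decreases
            assert early_stop(aucs) == (oracle_decreases >= 4)
            lr = initial
            for i in range(2, len(aucs) + 1):
                lr = lr_step(aucs[:i], lr)
            assert lr == pytest.approx(
                initial / 2 ** oracle_decreases, rel=1e-12
            )

    def test_best_so_far_monitor_variant(self):
        seq = [0.7, 0.8, 0.75, 0.78]
        assert count_decreases(seq, monitor="previous") == 1
        assert count_decreases(seq, monitor="best-so-far") == 2


class TestTrainingLossConsistency:
    def test_tensor_loss_equals_numpy_batch_loss(self, small_dataset):
        """The differentiable loss agrees with the reference numpy loss on
        softmax probabilities of the same logits."""
        records = small_dataset[:6]
        model = build_model(tiny_config(("IF", "BU", "S3", "S8", "SA")),
                            seed=1)
        feats, lengths, targets, masks = pad_batch(records)
        logits = model.forward(feats, lengths)
        w = weight_scheme("A", ("IF", "BU", "S3", "S8", "SA"),
                          if_positive_class_weight=6.37)
        total, parts = masked_training_loss(logits, targets, masks, w)

        preds, flat_t, flat_m = {}, {}, {}
        for t, lg in logits.items():
            if t == "SA":
                preds[t] = lg.data[:, :, 0].reshape(-1)
            else:
                z = lg.data - lg.data.max(axis=-1, keepdims=True)
                e = np.exp(z)
                preds[t] = (e / e.sum(axis=-1, keepdims=True)).reshape(
                    -1, lg.data.shape[-1]
                )
            flat_t[t] = targets[t].reshape(-1)
            flat_m[t] = masks[t].reshape(-1)
        report = batch_loss(preds, flat_t, flat_m, w)
        assert float(total.data) == pytest.approx(report.total, abs=1e-10)
        for t in parts:
            assert parts[t] == pytest.approx(report.losses[t], abs=1e-10)

    def test_weights_for_absent_head_rejected(self, small_dataset):
        model = build_model(tiny_config(("IF",)))
        w = weight_scheme("A", ("IF", "BU"))
        with pytest.raises(ValueError, match="absent"):
            train(model, small_dataset[:4], small_dataset[4:8], w,
                  TrainingConfig(max_epochs=1))


@pytest.fixture(scope="module")
def trained(small_dataset):
    annotated = [r for r in small_dataset if r.is_ppi_annotated]
    train_recs, val_recs = annotated[:14], annotated[14:20]
    model = build_model(tiny_config(("IF", "BU")), seed=0)
    w = weight_scheme("A", ("IF", "BU"), if_positive_class_weight=6.0)
    cfg = TrainingConfig(initial_lr=2e-3, batch_size=8, max_epochs=2, seed=3)
    model, history = train(model, train_recs, val_recs, w, cfg)
    return model, history, train_recs, val_recs, w, cfg


class TestTrainLoop:
    def test_history_lengths_and_metrics(self, trained):
        _, history, *_ = trained
        assert len(history.val_if_auc) == 2
        assert len(history.lr) == 2
        assert history.best_val_if_auc == max(history.val_if_auc)
        assert history.decrease_count == sorted(history.decrease_count)

    def test_lr_never_increases(self, trained):
        _, history, *_ = trained
        assert all(a >= b for a, b in zip(history.lr, history.lr[1:]))

    def test_rerun_same_seed_is_identical(self, trained, small_dataset):
        _, history, train_recs, val_recs, w, cfg = trained
        model2 = build_model(tiny_config(("IF", "BU")), seed=0)
        _, history2 = train(model2, train_recs, val_recs, w, cfg)
        assert history2.train_loss == history.train_loss
        assert history2.val_if_auc == history.val_if_auc

    def test_predictions_cover_all_records(self, trained):
        model, _, train_recs, val_recs, *_ = trained
        preds = predict_records(model, val_recs)
        assert set(preds) == {r.protein_id for r in val_recs}
        for rec in val_recs:
            assert preds[rec.protein_id]["IF"].shape == (rec.length,)

    def test_evaluate_model_reports_active_tasks(self, trained):
        model, _, _, val_recs, *_ = trained
        report = evaluate_model(model, val_recs)
        assert set(report.metrics) == {"IF", "BU"}
        assert 0.0 <= report.metrics["IF"]["auc_roc"] <= 1.0

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        model, _, _, val_recs, *_ = trained
        path = tmp_path / "model.npz"
        save_checkpoint(model, str(path))
        loaded = load_checkpoint(str(path))
        feats, lengths, _, _ = pad_batch(val_recs[:2])
        np.testing.assert_allclose(
            loaded.predict(feats, lengths)["IF"],
            model.predict(feats, lengths)["IF"],
            atol=1e-12,
        )


class TestRepeatProtocol:
    def test_mean_and_sd_against_two_pass_oracle(self):
        values = {0: 0.74, 1: 0.75, 2: 0.76, 3: 0.75}
        out = repeat_protocol(lambda s: {"auc": values[s]}, n_repeats=4,
                              base_seed=0)
        mean, sd = out["auc"]
        vals = np.array(list(values.values()))
        # independent two-pass variance computation
        m = vals.sum() / 4
        var = ((vals - m) ** 2).sum() / 3
        assert mean == pytest.approx(0.75)
        assert sd == pytest.approx(np.sqrt(var), abs=1e-15)

    def test_identical_seeds_warn_and_give_zero_sd(self):
        with pytest.warns(UserWarning, match="not unique"):
            out = repeat_protocol(lambda s: {"auc": 0.7 + 0.001 * s},
                                  n_repeats=3, seeds=[5, 5, 5])
        assert out["auc"][1] == 0.0

    def test_fewer_than_two_repeats_rejected(self):
        with pytest.raises(ValueError):
            repeat_protocol(lambda s: {"a": 1.0}, n_repeats=1)


class TestLearnability:
    def test_multitask_training_loss_decreases(self, medium_dataset):
        """On synthetic data the tiny model's training loss falls over the
        first three epochs."""
        annotated = [r for r in medium_dataset if r.is_ppi_annotated]
        model = build_model(tiny_config(("IF", "BU", "S3", "SA")), seed=2)
        w = weight_scheme("A", ("IF", "BU", "S3", "SA"),
                          if_positive_class_weight=6.37)
        cfg = TrainingConfig(initial_lr=2e-3, batch_size=16, max_epochs=3,
                             seed=2)
        _, history = train(model, annotated[:48], annotated[48:60], w, cfg)
        assert history.train_loss[2] < history.train_loss[0]
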