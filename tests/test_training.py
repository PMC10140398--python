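"""Sequence windowing, fold splitting, learning schedule, early stopping
and the cross-validation driver."""

import numpy as np
import pytest

from somnoseq.nn.model import ModelConfig, SleepStager
from somnoseq.pipeline import prepare_cohort
from somnoseq.simulate import generate_cohort
from somnoseq.stages import Hypnogram
from somnoseq.training import (
    FoldPlan,
    LrSweepError,
    TrainingConfig,
    find_lr_range,
    lr_at,
    make_sequences,
    run_cross_validation,
    sequence_count,
    split_folds,
    train_fold,
)

from conftest import SEED


def dummy_epochs(n, samples=60, channels=3, seed=SEED):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, channels, samples)).astype(np.float32)


tiny_model_config = ModelConfig(
    conv_filters=(4, 4, 6, 6, 8, 8), conv_kernels=(5, 5, 3, 3, 3, 3),
    conv_strides=(1, 1, 1, 1, 1, 1), pool_sizes=(2, 2), pool_strides=(2, 2),
    lstm_units=4, dropout_rate=0.1, seq_len=4, samples_per_epoch=60)


class TestMakeSequences:
    def test_no_overlap_counts(self):
        x, y, m = make_sequences(dummy_epochs(400), np.zeros(400, int), 100, 0.0)
        assert x.shape[0] == 4 and m.all()

    def test_75pct_overlap_count_by_hand(self):
        # (400 - 100) / 25 + 1 = 13
        x, y, m = make_sequences(dummy_epochs(400), np.zeros(400, int), 100, 0.75)
        assert x.shape[0] == 13

    def test_multiplication_factor_rounds_to_four(self):
        n = 12_000
        ratio = (sequence_count(n, 100, 0.75) / sequence_count(n, 100, 0.0))
        assert round(ratio) == 4

    def test_factor_approaches_inverse_of_one_minus_overlap(self):
        for overlap in (0.0, 0.5, 0.75, 0.9):
            n = 100_000
            ratio = (sequence_count(n, 100, overlap)
                     / sequence_count(n, 100, 0.0))
            assert ratio == pytest.approx(1.0 / (1.0 - overlap), rel=0.01)

    def test_short_recording_padded_with_mask(self):
        labels = np.array([0, 1, 2])
        x, y, m = make_sequences(dummy_epochs(3), labels, 5, 0.0)
        assert x.shape == (1, 5, 60, 3)
        assert list(y[0]) == [0, 1, 2, 2, 2]   # final epoch repeated
        assert list(m[0]) == [True, True, True, False, False]

    def test_window_content_matches_source(self):
        ep = dummy_epochs(10)
        labels = np.arange(10) % 5
        x, y, _ = make_sequences(ep, labels, 4, 0.5)
        # stride 2: starts 0,2,4,6
        assert np.array_equal(y[1], labels[2:6])
        assert np.array_equal(x[1], np.transpose(ep[2:6], (0, 2, 1)))

    def test_non_integral_stride_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            make_sequences(dummy_epochs(100), np.zeros(100, int), 10, 0.75)

    def test_grid_sweep_matches_closed_form(self):
        for n in (50, 101, 250, 999):
            for seq_len, overlap in ((10, 0.0), (10, 0.5), (20, 0.75), (50, 0.9)):
                x, _, _ = make_sequences(
                    dummy_epochs(n, samples=4, channels=1),
                    np.zeros(n, int), seq_len, overlap)
                assert x.shape[0] == sequence_count(n, seq_len, overlap)


class TestSplitFolds:
    def test_105_recordings_fold_size_pattern(self):
        ids = [f"r{i}" for i in range(105)]
        plan = split_folds(ids, k=10, seed=SEED)
        sizes = sorted(len(f["test"]) for f in plan.folds)
        assert sizes == [10] * 5 + [11] * 5

    def test_same_seed_identical_plan(self):
        ids = [f"r{i}" for i in range(20)]
        assert split_folds(ids, 4, SEED).folds == split_folds(ids, 4, SEED).folds

    def test_partition_and_leakage_guard(self):
        ids = [f"r{i}" for i in range(23)]
        plan = split_folds(ids, k=5, seed=SEED)
        plan.validate(ids)
        tests = [rid for f in plan.folds for rid in f["test"]]
        assert sorted(tests) == sorted(ids)
        for f in plan.folds:
            assert len(f["val"]) == max(1, round(0.1 * (len(ids) - len(f["test"]))))
            assert not (set(f["train"]) & set(f["val"]))

    def test_too_few_recordings_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            split_folds(["a", "b"], k=3, seed=SEED)

    def test_json_round_trip(self, tmp_path):
        plan = split_folds([f"r{i}" for i in range(12)], 3, SEED)
        plan.to_json(tmp_path / "plan.json")
        back = FoldPlan.from_json(tmp_path / "plan.json")
        assert back.folds == plan.folds and back.seed == plan.seed


class TestLrSchedule:
    cfg = TrainingConfig(seq_len=100, restart_period_T0=10, restart_mult_Tmult=2)

    def test_cycle_start_is_lr_max(self):
        assert lr_at(0, self.cfg) == pytest.approx(1e-3)

    def test_cycle_end_is_lr_min(self):
        assert lr_at(10, self.cfg) == pytest.approx(1e-5)

    def test_cycle_midpoint_is_arithmetic_mean(self):
        assert lr_at(5, self.cfg) == pytest.approx((1e-3 + 1e-5) / 2)

    def test_restart_returns_to_lr_max_with_doubled_period(self):
        assert lr_at(11, self.cfg) == pytest.approx(1e-3)   # new cycle, T_i = 20
        assert lr_at(11 + 20, self.cfg) == pytest.approx(1e-5)
        assert lr_at(11 + 10, self.cfg) == pytest.approx((1e-3 + 1e-5) / 2)

    def test_monotone_decrease_within_cycle(self):
        vals = [lr_at(t, self.cfg) for t in range(11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(lr_min=1e-2, lr_max=1e-3)
        with pytest.raises(ValueError):
            TrainingConfig(seq_len=10, train_overlap=0.75)


class TestLrFinder:
    def quadratic_step(self, curvature=100.0, inner=5):
        """Toy probe: fresh 5-step gradient descent on loss = 0.5*a*w^2
        from w=1 at each queried rate; diverges for lr > 2/a."""

        def step(lr):
            w = 1.0
            for _ in range(inner):
                w = w - lr * curvature * w
            return 0.5 * curvature * w * w

        return step

    def test_suggestion_within_decade_of_analytic_optimum(self):
        # fastest stable per-step contraction at lr = 1/a; unstable > 2/a
        a = 100.0
        lr_min, lr_max, curve = find_lr_range(
            self.quadratic_step(a), n_steps=200, lr_lo=1e-6, lr_hi=1.0)
        assert (1 / a) / 10 <= lr_max <= (1 / a) * 10
        assert lr_max <= 2 / a
        assert lr_min == pytest.approx(lr_max / 100)

    def test_flat_loss_flagged(self):
        with pytest.raises(LrSweepError, match="flat"):
            find_lr_range(lambda lr: 1.0, n_steps=60)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="50"):
            find_lr_range(lambda lr: 1.0, n_steps=10)

    def test_deterministic_curve(self):
        _, _, c1 = find_lr_range(self.quadratic_step(), n_steps=100)
        _, _, c2 = find_lr_range(self.quadratic_step(), n_steps=100)
        assert c1 == c2


def labelled_windows(n_windows, seq_len=4, samples=60, seed=SEED):
    """Trivially separable windows: class = sign pattern of channel 0."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 5, (n_windows, seq_len))
    x = rng.standard_normal((n_windows, seq_len, samples, 3)).astype(np.float32)
    x[..., 0] += (y[..., None] - 2) * 3.0    # strong class-dependent offset
    m = np.ones((n_windows, seq_len), dtype=bool)
    return x.astype(np.float32), y, m


class TestTrainFold:
    def test_patience_zero_stops_on_first_worsening(self):
        x, y, m = labelled_windows(6)
        cfg = TrainingConfig(seq_len=4, max_epochs=50, patience=0,
                             batch_size=4, seed=SEED)
        model = SleepStager(tiny_model_config, seed=SEED)
        model, hist = train_fold(model, (x, y, m), (x, y, m), cfg)
        worsened = [i for i in range(1, len(hist.val_loss))
                    if hist.val_loss[i] >= min(hist.val_loss[:i])]
        assert hist.stopped_epoch == (worsened[0] + 1 if worsened else 50)

    def test_strictly_improving_runs_to_cap(self):
        x, y, m = labelled_windows(8)
        cfg = TrainingConfig(seq_len=4, max_epochs=3, patience=20,
                             batch_size=4, seed=SEED)
        model = SleepStager(tiny_model_config, seed=SEED)
        model, hist = train_fold(model, (x, y, m), (x, y, m), cfg)
        assert hist.stopped_epoch == 3
        assert len(hist.train_loss) == 3

    def test_best_weights_restored(self):
        from somnoseq.training import evaluate_loss

        x, y, m = labelled_windows(6)
        xv, yv, mv = labelled_windows(4, seed=SEED + 1)
        cfg = TrainingConfig(seq_len=4, max_epochs=6, patience=2,
                             batch_size=4, seed=SEED)
        model = SleepStager(tiny_model_config, seed=SEED)
        model, hist = train_fold(model, (x, y, m), (xv, yv, mv), cfg)
        final_val = evaluate_loss(model, xv, yv, mv)
        assert final_val == pytest.approx(min(hist.val_loss), abs=1e-6)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_learning_beats_majority_class(self):
        x, y, m = labelled_windows(24)
        xv, yv, mv = labelled_windows(8, seed=SEED + 1)
        cfg = TrainingConfig(seq_len=4, max_epochs=20, patience=20,
                             batch_size=8, seed=SEED)
        model = SleepStager(tiny_model_config, seed=SEED)
        model, _ = train_fold(model, (x, y, m), (xv, yv, mv), cfg)
        probs = model.forward(xv)
        acc = np.mean(probs.argmax(-1) == yv)
        majority = max(np.bincount(yv.ravel(), minlength=5)) / yv.size
        assert acc > majority


@pytest.fixture(scope="module")
def cv_result():
    cohort = generate_cohort(4, 24, seed=SEED, rate=100.0)
    triples = prepare_cohort(cohort)
    cfg = ModelConfig(
        conv_filters=(4, 4, 6, 6, 8, 8), conv_kernels=(5, 5, 3, 3, 3, 3),
        conv_strides=(2, 1, 2, 1, 1, 1), pool_sizes=(4, 4),
        pool_strides=(4, 4), lstm_units=4, dropout_rate=0.1, seq_len=8,
        samples_per_epoch=3000)
    tcfg = TrainingConfig(seq_len=8, max_epochs=2, patience=20,
                          batch_size=4, seed=SEED)
    return triples, cfg, tcfg, run_cross_validation(triples, cfg, tcfg, k=2)


class TestCrossValidation:

    def test_every_recording_predicted_once(self, cv_result):
        triples, _, _, result = cv_result
        assert set(result.predictions) == {t[2]["id"] for t in triples}
        for _, hyp, meta in triples:
            assert len(result.predictions[meta["id"]]) == len(hyp)

    def test_pooled_matrix_conserves_epochs(self, cv_result):
        triples, _, _, result = cv_result
        assert result.pooled_confusion.total == sum(len(h) for _, h, _ in triples)

    def test_pooled_equals_sum_of_folds(self, cv_result):
        _, _, _, result = cv_result
        fold_sum = sum(r.confusion.counts.sum() for r in result.per_fold_reports)
        assert fold_sum == result.pooled_confusion.total

    def test_cohort_order_invariance_at_fixed_plan(self, cv_result):
        triples, cfg, tcfg, result = cv_result
        shuffled = [triples[i] for i in (2, 0, 3, 1)]
        again = run_cross_validation(shuffled, cfg, tcfg, k=2,
                                     plan=result.plan)
        assert np.array_equal(again.pooled_confusion.counts,
                              result.pooled_confusion.counts)

    def test_group_reports_present(self, cv_result):
        _, _, _, result = cv_result
        assert "SDB" in result.group_reports and "control" in result.group_reports
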