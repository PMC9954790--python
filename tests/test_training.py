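import numpy as np
import pytest

from eegshapes import (
    EarlyStopping,
    MotorImageryCNN,
    TrainConfig,
    TrialSet,
    build_model,
    run_subject_experiment,
    split_train_val,
    train_model,
)
from eegshapes.training import _eval  # noqa: PLC2701 - internal eval helper


def balanced_ts(n_per_class=10, T=16, C=3, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    return TrialSet(
        trials=rng.standard_normal((n, T, C)).astype(np.float32),
        labels=np.tile(np.arange(n_classes), n_per_class),
        class_names=("left", "right", "feet", "tongue")[:n_classes],
        sampling_rate_hz=250.0,
    )


class TestSplit:
    def test_counts_80_20(self):
        ts = balanced_ts(n_per_class=50)
        tr, va = split_train_val(ts, 0.2, seed=0)
        assert (tr.n_trials, va.n_trials) == (80, 20)
        assert va.class_counts().tolist() == [10, 10]

    def test_deterministic_given_seed(self):
        ts = balanced_ts(n_per_class=25)
        a = split_train_val(ts, 0.2, seed=3)
        b = split_train_val(ts, 0.2, seed=3)
        assert a[0].equals(b[0]) and a[1].equals(b[1])
        c = split_train_val(ts, 0.2, seed=4)
        assert not a[1].equals(c[1])

    def test_partition_property(self):
        ts = balanced_ts(n_per_class=13)
        tr, va = split_train_val(ts, 0.25, seed=1)
        # disjoint union: every trial row of ts appears exactly once
        combined = np.concatenate([tr.trials, va.trials])
        assert combined.shape[0] == ts.n_trials
        assert sorted(map(tuple, combined.reshape(combined.shape[0], -1))) == sorted(
            map(tuple, ts.trials.reshape(ts.n_trials, -1))
        )

    def test_minimum_one_validation_trial_per_class(self):
        ts = balanced_ts(n_per_class=3)
        _, va = split_train_val(ts, 0.1, seed=0)
        assert (va.class_counts() >= 1).all()

    def test_class_with_single_trial_rejected(self):
        ts = balanced_ts(n_per_class=4)
        lone = TrialSet(
            trials=ts.trials[:5],
            labels=np.array([0, 0, 0, 0, 1]),
            class_names=ts.class_names,
            sampling_rate_hz=250.0,
        )
        with pytest.raises(ValueError, match="2"):
            split_train_val(lone, 0.2, seed=0)


class TestEarlyStopping:
    def test_stops_exactly_patience_after_last_improvement(self):
        # improvements at epochs 0 and 1; then 20 flat epochs
        trace = [1.0, 0.9] + [0.95, 0.96] + [0.95] * 18
        stopper = EarlyStopping(patience=20)
        stopped_at = None
        for epoch, loss in enumerate(trace):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 21  # 20 epochs after the best epoch (index 1)
        assert stopper.best_epoch == 1
        assert stopper.best_loss == 0.9

    def test_plateau_does_not_count_as_improvement(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(0, 1.0)
        assert not stopper.update(1, 1.0)
        assert stopper.update(2, 1.0)
        assert stopper.best_epoch == 0

    def test_late_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=3)
        losses = [1.0, 0.99, 0.995, 0.98, 0.999, 0.999, 0.999]
        stops = [stopper.update(e, l) for e, l in enumerate(losses)]
        assert stops == [False] * 6 + [True]
        assert stopper.best_epoch == 3


class TestTrainModel:
    def make(self, small_cfg_factory, seed=0, n_per_class=12):
        ts = balanced_ts(n_per_class=n_per_class, T=32, C=3, seed=seed)
        tr, va = split_train_val(ts, 0.25, seed=seed)
        cfg = small_cfg_factory("TxC", T=32, C=3)
        return build_model(cfg, seed=seed), tr, va

    def test_restored_snapshot_is_argmin_val_loss(self, small_cfg_factory):
        net, tr, va = self.make(small_cfg_factory)
        tcfg = TrainConfig(max_epochs=8, patience=3, batch_size=8, seed=0)
        net, hist = train_model(net, tr, va, "TxC", tcfg)
        recorded = [r.val_loss for r in hist.records]
        assert hist.best_epoch == int(np.argmin(recorded))
        from eegshapes.shapes import batch_to_input_shape

        x_val = batch_to_input_shape(va.trials, "TxC").astype(np.float32)
        val_loss, _ = _eval(net, x_val, va.labels, va.n_classes)
        assert val_loss == pytest.approx(min(recorded), abs=1e-6)

    def test_patience_larger_than_max_epochs_runs_all(self, small_cfg_factory):
        net, tr, va = self.make(small_cfg_factory)
        tcfg = TrainConfig(max_epochs=4, patience=50, batch_size=8, seed=0)
        _, hist = train_model(net, tr, va, "TxC", tcfg)
        assert hist.n_epochs == 4
        assert "max_epochs" in hist.stop_reason

    def test_history_invariants(self, small_cfg_factory):
        net, tr, va = self.make(small_cfg_factory)
        tcfg = TrainConfig(max_epochs=10, patience=2, batch_size=8, seed=0)
        _, hist = train_model(net, tr, va, "TxC", tcfg)
        assert hist.n_epochs <= 10
        assert hist.n_epochs >= hist.best_epoch + 1
        assert hist.best_val_loss == min(r.val_loss for r in hist.records)
        # stop epoch bounded by best + patience (unless max_epochs hit)
        if "improvement" in hist.stop_reason:
            assert hist.n_epochs - 1 <= hist.best_epoch + tcfg.patience

    def test_deterministic_given_seed(self, small_cfg_factory):
        runs = []
        for _ in range(2):
            net, tr, va = self.make(small_cfg_factory, seed=5)
            tcfg = TrainConfig(max_epochs=3, patience=5, batch_size=8, seed=5)
            _, hist = train_model(net, tr, va, "TxC", tcfg)
            runs.append([r.val_loss for r in hist.records])
        assert runs[0] == runs[1]

    def test_geometry_mismatch_rejected(self, small_cfg_factory):
        net, tr, va = self.make(small_cfg_factory)
        with pytest.raises(ValueError, match="layout"):
            train_model(net, tr, va, "CxT", TrainConfig(max_epochs=1))

    def test_empty_training_set_rejected(self, small_cfg_factory):
        net, tr, va = self.make(small_cfg_factory)
        empty = tr.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train_model(net, empty, va, "TxC", TrainConfig(max_epochs=1))


class TestSubjectExperiment:
    def pairs(self, small_cfg_factory, n_subjects=2):
        out = []
        for i in range(n_subjects):
            out.append(
                (
                    balanced_ts(n_per_class=8, T=32, C=3, seed=10 + i),
                    balanced_ts(n_per_class=4, T=32, C=3, seed=50 + i),
                )
            )
        return out

    def test_structure_and_pooling(self, small_cfg_factory):
        subjects = self.pairs(small_cfg_factory, 2)
        cfg = small_cfg_factory("TxC", T=32, C=3)
        res = run_subject_experiment(
            subjects, "TxC", cfg, TrainConfig(max_epochs=2, batch_size=8, seed=0)
        )
        assert len(res.accuracies) == 2
        assert res.pooled_counts.sum() == sum(t.n_trials for _, t in subjects)
        assert res.mean_accuracy == pytest.approx(np.mean(res.accuracies))

    def test_single_subject_mean_is_that_subject(self, small_cfg_factory):
        subjects = self.pairs(small_cfg_factory, 1)
        cfg = small_cfg_factory("TxC", T=32, C=3)
        res = run_subject_experiment(
            subjects, "TxC", cfg, TrainConfig(max_epochs=2, batch_size=8, seed=0)
        )
        assert res.mean_accuracy == res.accuracies[0]
        assert res.std_accuracy == 0.0

    def test_repeat_run_identical(self, small_cfg_factory):
        subjects = self.pairs(small_cfg_factory, 2)
        cfg = small_cfg_factory("TxC", T=32, C=3)
        tcfg = TrainConfig(max_epochs=2, batch_size=8, seed=0)
        a = run_subject_experiment(subjects, "TxC", cfg, tcfg)
        b = run_subject_experiment(subjects, "TxC", cfg, tcfg)
        assert a.accuracies == b.accuracies
        assert np.array_equal(a.pooled_counts, b.pooled_counts)


class TestEstimatorFacade:
    def test_fit_evaluate_summary(self, small_cfg_factory):
        train = balanced_ts(n_per_class=10, T=32, C=3, seed=0)
        test = balanced_ts(n_per_class=5, T=32, C=3, seed=1)
        cfg = small_cfg_factory("TxC", T=32, C=3)
        res = MotorImageryCNN(train, "TxC", cfg).fit(
            TrainConfig(max_epochs=2, batch_size=8, seed=0)
        )
        report = res.evaluate(test)
        assert 0.0 <= report.accuracy <= 1.0
        assert report.cm.total == test.n_trials
        text = res.summary()
        assert "TxC" in text and "epochs" in text
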