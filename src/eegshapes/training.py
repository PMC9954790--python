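"""Training regime: stratified 80/20 split, patience-20 early stopping,
best-snapshot restoration, and the per-subject experiment loop.

The test partition never enters this module's training path: the split
produces train/validation parts only, model selection uses validation
loss alone, and :func:`run_subject_experiment` touches each subject's
test set exactly once, after training has finished.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelConfig, build_model
from .nn import Adam, Network, softmax_cross_entropy
from .shapes import ShapeCode, batch_to_input_shape, shape_extents
from .trial_data import TrialSet

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainHistory",
    "EarlyStopping",
    "split_train_val",
    "train_model",
    "run_subject_experiment",
    "SubjectExperimentResult",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training session.

    The split fraction (0.2) and patience (20 epochs on validation loss)
    are fixed by the protocol; optimiser, learning rate, batch size and
    epoch cap are conventional defaults for this model family.
    """

    val_fraction: float = 0.2
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError(f"val_fraction must be in (0, 1); got {self.val_fraction}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1; got {self.patience}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float
    seconds: float


@dataclass
class TrainHistory:
    """Per-epoch metrics, best-epoch index and the reason training stopped."""

    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.records)

    @property
    def best_val_loss(self) -> float:
        return self.records[self.best_epoch].val_loss

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "epoch": r.epoch,
                    "train_loss": r.train_loss,
                    "train_acc": r.train_acc,
                    "val_loss": r.val_loss,
                    "val_acc": r.val_acc,
                    "seconds": r.seconds,
                }
                for r in self.records
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class EarlyStopping:
    """Stop when validation loss has not improved for ``patience`` epochs.

    "Improved" means strictly below the running minimum (any decrease
    counts; there is no minimum delta).  ``best_epoch`` is the 0-based
    index of the minimum-loss epoch.
    """

    def __init__(self, patience: int) -> None:
        if patience < 1:
            raise ValueError(f"patience must be >= 1; got {patience}")
        self.patience = int(patience)
        self.best_loss = np.inf
        self.best_epoch = -1
        self.epochs_since_improvement = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val_loss < self.best_loss:
            self.best_loss = float(val_loss)
            self.best_epoch = int(epoch)
            self.epochs_since_improvement = 0
            return False
        self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


def split_train_val(
    ts: TrialSet, val_fraction: float = 0.2, seed: int = 0
) -> tuple[TrialSet, TrialSet]:
    """Stratified train/validation split of a TrialSet.

    Per class, ``round(count * val_fraction)`` trials (at least 1) go to
    validation; the parts are disjoint, their union is the input, and the
    partition is deterministic in ``seed``.
    """
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0, 1); got {val_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5114]))
    val_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in range(ts.n_classes):
        idx = np.flatnonzero(ts.labels == cls)
        if idx.size == 0:
            continue
        if idx.size < 2:
            raise ValueError(
                f"class {ts.class_names[cls]!r} has {idx.size} trial(s); "
                "need >= 2 to split"
            )
        n_val = max(1, int(np.floor(idx.size * val_fraction + 0.5)))
        if n_val >= idx.size:
            n_val = idx.size - 1
        perm = rng.permutation(idx)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    train = np.sort(np.concatenate(train_idx))
    val = np.sort(np.concatenate(val_idx))
    return ts.subset(train), ts.subset(val)


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _eval(net: Network, x: np.ndarray, y: np.ndarray, n_classes: int) -> tuple[float, float]:
    probs = net.predict_proba(x)
    loss, _ = softmax_cross_entropy(probs, _onehot(y, n_classes))
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(
    model: Network,
    train: TrialSet,
    val: TrialSet,
    shape: ShapeCode | str,
    cfg: TrainConfig,
) -> tuple[Network, TrainHistory]:
    """Fit a built network by minibatch cross-entropy descent.

    After every epoch the validation loss/accuracy are recorded; training
    stops once the loss has not improved for ``cfg.patience`` consecutive
    epochs (or at ``cfg.max_epochs``), and the parameters from the
    best-validation-loss epoch are restored before returning.
    """
    shape = ShapeCode.parse(shape)
    if train.n_trials == 0:
        raise ValueError("training set is empty")
    expected = shape_extents(shape, train.n_timestamps, train.n_channels)
    if model.input_extents != expected:
        raise ValueError(
            f"model expects input extents {model.input_extents} but layout "
            f"{shape.value} of this data gives {expected}"
        )
    n_classes = train.n_classes
    x_train = np.ascontiguousarray(batch_to_input_shape(train.trials, shape))
    x_val = np.ascontiguousarray(batch_to_input_shape(val.trials, shape))
    y_train = train.labels
    y_val = val.labels
    onehot_train = _onehot(y_train, n_classes)

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7124]))
    model.seed_dropout(int(cfg.seed))
    opt = Adam(model.parameters(), learning_rate=cfg.learning_rate)
    stopper = EarlyStopping(cfg.patience)
    history = TrainHistory()
    best_state = model.get_weights()

    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(train.n_trials)
        losses: list[tuple[float, int]] = []
        correct = 0
        for start in range(0, train.n_trials, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            yb = onehot_train[idx]
            probs = model.forward(xb, training=True)
            loss, dprobs = softmax_cross_entropy(probs, yb)
            model.backward(dprobs)
            opt.step(model.gradients())
            losses.append((loss, len(idx)))
            correct += int((probs.argmax(axis=1) == y_train[idx]).sum())
        train_loss = sum(l * n for l, n in losses) / train.n_trials
        train_acc = correct / train.n_trials
        val_loss, val_acc = _eval(model, x_val, y_val, n_classes)
        history.records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=train_loss,
                train_acc=train_acc,
                val_loss=val_loss,
                val_acc=val_acc,
                seconds=time.perf_counter() - t0,
            )
        )
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.get_weights()
        if stop:
            history.stop_reason = (
                f"no validation-loss improvement for {cfg.patience} epochs"
            )
            break
    else:
        history.stop_reason = f"reached max_epochs={cfg.max_epochs}"

    history.best_epoch = stopper.best_epoch
    model.set_weights(best_state)
    return model, history


@dataclass
class SubjectExperimentResult:
    """Per-subject accuracies plus the pooled confusion counts."""

    shape: ShapeCode
    subject_ids: list[str]
    accuracies: list[float]
    histories: list[TrainHistory]
    pooled_counts: np.ndarray
    class_names: tuple[str, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.accuracies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subject_ids, "accuracy": self.accuracies}
        )


def run_subject_experiment(
    subjects: list[tuple[TrialSet, TrialSet]],
    shape: ShapeCode | str,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> SubjectExperimentResult:
    """Train and evaluate one model per subject for a single layout.

    ``subjects`` holds (train, test) TrialSet pairs; each subject's
    training material is split 80/20, a fresh model is fitted with early
    stopping, and accuracy is measured once on that subject's untouched
    test set.  Confusion counts are pooled across subjects.
    """
    from .evaluation import confusion_matrix  # local import; no cycle at module load

    if not subjects:
        raise ValueError("need at least one subject")
    shape = ShapeCode.parse(shape)
    train_cfg = train_cfg or TrainConfig()
    first_train = subjects[0][0]
    if model_cfg is None:
        model_cfg = ModelConfig(
            n_classes=first_train.n_classes,
            input_shape=shape,
            T=first_train.n_timestamps,
            C=first_train.n_channels,
        )
    subject_ids, accuracies, histories = [], [], []
    pooled = np.zeros((model_cfg.n_classes, model_cfg.n_classes), dtype=np.int64)
    class_names = first_train.class_names
    for i, (train_ts, test_ts) in enumerate(subjects):
        sub_seed = int(train_cfg.seed) + i
        sub_cfg = replace(train_cfg, seed=sub_seed)
        tr, va = split_train_val(train_ts, sub_cfg.val_fraction, seed=sub_seed)
        net = build_model(model_cfg, seed=sub_seed)
        net, hist = train_model(net, tr, va, shape, sub_cfg)
        x_test = batch_to_input_shape(test_ts.trials, shape)
        pred = net.predict_proba(x_test).argmax(axis=1)
        cm = confusion_matrix(test_ts.labels, pred, model_cfg.n_classes)
        pooled += cm.counts
        subject_ids.append(train_ts.subject_id)
        accuracies.append(float((pred == test_ts.labels).mean()))
        histories.append(hist)
    return SubjectExperimentResult(
        shape=shape,
        subject_ids=subject_ids,
        accuracies=accuracies,
        histories=histories,
        pooled_counts=pooled,
        class_names=class_names,
    )
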