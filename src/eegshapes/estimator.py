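"""Model/results objects tying the pipeline together.

`MotorImageryCNN` is constructed from a :class:`~eegshapes.trial_data.TrialSet`
and an input-layout code; ``fit()`` runs the full protocol (stratified
80/20 split, early stopping, best-snapshot restore) and returns a
:class:`CNNResults` carrying the trained network, the training history
and diagnostics, with ``evaluate()``/``predict()``/``summary()`` on top.

    >>> train, test = learnability_fixture("easy")
    >>> res = MotorImageryCNN(train, "TxC").fit(TrainConfig(max_epochs=50))
    >>> report = res.evaluate(test)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import (
    ConfusionMatrix,
    accuracy_from_cm,
    class_rates_from_cm,
    confusion_matrix,
    kappa_from_cm,
    macro_f1_from_cm,
)
from .model import ModelConfig, build_model, count_parameters
from .nn import Network
from .shapes import ShapeCode, batch_to_input_shape
from .training import TrainConfig, TrainHistory, split_train_val, train_model
from .trial_data import TrialSet, load_trial_archive

__all__ = ["MotorImageryCNN", "CNNResults", "ClassificationReport"]


@dataclass
class ClassificationReport:
    """Confusion matrix plus the derived statistics for one test set."""

    cm: ConfusionMatrix
    accuracy: float
    macro_f1: float
    kappa: float

    @classmethod
    def from_cm(cls, cm: ConfusionMatrix) -> "ClassificationReport":
        return cls(
            cm=cm,
            accuracy=accuracy_from_cm(cm),
            macro_f1=macro_f1_from_cm(cm),
            kappa=kappa_from_cm(cm),
        )

    def class_rates(self) -> pd.DataFrame:
        return class_rates_from_cm(self.cm)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
            "confusion_counts": self.cm.counts.tolist(),
            "class_names": list(self.cm.class_names),
        }


class MotorImageryCNN:
    """CNN classifier for one TrialSet under one input layout.

    Parameters
    ----------
    data
        Training material (the held-out test set must stay outside).
    shape
        One of the eight layout codes, e.g. ``"TxC"``.
    model_config
        Architecture overrides; geometry is inferred from ``data``.
    """

    def __init__(
        self,
        data: TrialSet,
        shape: ShapeCode | str,
        model_config: ModelConfig | None = None,
    ) -> None:
        self.data = data
        self.shape = ShapeCode.parse(shape)
        self.model_config = model_config or ModelConfig(
            n_classes=data.n_classes,
            input_shape=self.shape,
            T=data.n_timestamps,
            C=data.n_channels,
        )
        if (
            self.model_config.T != data.n_timestamps
            or self.model_config.C != data.n_channels
            or self.model_config.input_shape != self.shape
        ):
            raise ValueError("model_config geometry does not match the data/layout")

    @classmethod
    def from_archive(
        cls, path, shape: ShapeCode | str, model_config: ModelConfig | None = None
    ) -> "MotorImageryCNN":
        return cls(load_trial_archive(path), shape, model_config)

    def fit(self, train_config: TrainConfig | None = None) -> "CNNResults":
        cfg = train_config or TrainConfig()
        train, val = split_train_val(self.data, cfg.val_fraction, seed=cfg.seed)
        net = build_model(self.model_config, seed=cfg.seed)
        net, history = train_model(net, train, val, self.shape, cfg)
        return CNNResults(self, net, history, cfg, n_train=train.n_trials, n_val=val.n_trials)


class CNNResults:
    """Fitted-model results: trained network, history, diagnostics."""

    def __init__(
        self,
        model: MotorImageryCNN,
        network: Network,
        history: TrainHistory,
        train_config: TrainConfig,
        n_train: int,
        n_val: int,
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config
        self.n_train = n_train
        self.n_val = n_val

    @property
    def n_params(self) -> int:
        return count_parameters(self.network)

    def predict_proba(self, data: TrialSet | np.ndarray) -> np.ndarray:
        trials = data.trials if isinstance(data, TrialSet) else np.asarray(data)
        x = batch_to_input_shape(trials, self.model.shape)
        return self.network.predict_proba(x.astype(np.float32))

    def predict(self, data: TrialSet | np.ndarray) -> np.ndarray:
        return self.predict_proba(data).argmax(axis=1)

    def evaluate(self, test: TrialSet) -> ClassificationReport:
        """Confusion matrix and statistics on an untouched test set."""
        pred = self.predict(test)
        cm = confusion_matrix(
            test.labels, pred, test.n_classes, class_names=test.class_names
        )
        return ClassificationReport.from_cm(cm)

    def summary(self) -> str:
        h = self.history
        best = h.records[h.best_epoch]
        lines = [
            "Motor-imagery CNN fit",
            "=" * 52,
            f"input layout:        {self.model.shape.value}"
            f"  (extents {'x'.join(map(str, self.network.input_extents))})",
            f"classes:             {', '.join(self.model.data.class_names)}",
            f"trainable params:    {self.n_params:,}",
            f"train / val trials:  {self.n_train} / {self.n_val}",
            f"epochs run:          {h.n_epochs}  (stop: {h.stop_reason})",
            f"best epoch:          {h.best_epoch}  "
            f"(val loss {best.val_loss:.4f}, val acc {best.val_acc:.4f})",
            "=" * 52,
        ]
        return "\n".join(lines)
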