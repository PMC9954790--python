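"""Confusion-matrix statistics: accuracy, per-class rates, macro-F1,
Cohen's kappa, and subject-level summaries.

All statistics derive from a single :class:`ConfusionMatrix` of integer
counts indexed (true class, predicted class).  For the binary
left/right case the four cells map onto the conventional
TL (true left) = counts[left, left], FL (false left) = counts[left, right],
TR (true right) = counts[right, right], FR (false right) =
counts[right, left].
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import sklearn.metrics as skm

from .shapes import ALL_SHAPES

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "accuracy_from_cm",
    "class_rates_from_cm",
    "macro_f1_from_cm",
    "kappa_from_cm",
    "subject_summary",
    "render_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square matrix of per-class true/predicted counts."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"counts must be square; got shape {counts.shape}")
        if counts.shape[0] != len(self.class_names):
            raise ValueError("class_names length must match matrix order")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_names, name="true"),
            columns=pd.Index(self.class_names, name="predicted"),
        )


def confusion_matrix(
    y_true, y_pred, n_classes: int, class_names: tuple[str, ...] | None = None
) -> ConfusionMatrix:
    """Count matrix with entry (i, j) = items of true class i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    if y_true.size and (
        min(y_true.min(), y_pred.min()) < 0
        or max(y_true.max(), y_pred.max()) >= n_classes
    ):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    if y_true.size == 0:
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    else:
        counts = skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    names = class_names or tuple(f"class{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=names)


def accuracy_from_cm(cm: ConfusionMatrix) -> float:
    """Trace over total count."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts) / cm.total)


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def class_rates_from_cm(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class correct/incorrect counts and half-up one-decimal percentages.

    E.g. a class row with 536 of 593 correct reports 90.4%.
    """
    rows = []
    totals = cm.counts.sum(axis=1)
    if (totals == 0).any():
        bad = [cm.class_names[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"classes with no trials: {bad}")
    for i, name in enumerate(cm.class_names):
        correct = int(cm.counts[i, i])
        total = int(totals[i])
        rows.append(
            {
                "class": name,
                "correct": correct,
                "incorrect": total - correct,
                "total": total,
                "pct_correct": _round_half_up_1dp(100.0 * correct / total),
                "pct_incorrect": _round_half_up_1dp(100.0 * (total - correct) / total),
            }
        )
    return pd.DataFrame(rows)


def macro_f1_from_cm(cm: ConfusionMatrix) -> float:
    """Unweighted mean over classes of the per-class F1 score.

    Per class: precision = diagonal / column sum, recall = diagonal / row
    sum, F1 = their harmonic mean (0 where precision + recall = 0; a class
    absent from both truth and prediction also scores 0).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(np.float64)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return float(f1.mean())


def kappa_from_cm(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), 0 at full chance agreement.

    p_o is the observed accuracy and p_e = sum_k row_k * col_k / total^2
    the agreement expected from the marginals alone.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def subject_summary(accuracies, ddof: int = 0) -> tuple[float, float]:
    """Mean and standard deviation of per-subject accuracies.

    ``ddof=0`` (population, the default reported) or ``ddof=1`` (sample).
    """
    acc = np.asarray(list(accuracies), dtype=np.float64)
    if acc.size == 0:
        raise ValueError("accuracies must be non-empty")
    return float(acc.mean()), float(acc.std(ddof=ddof) if acc.size > 1 else 0.0)


def render_report(results, out_dir=None, fmt: str = "markdown") -> dict[str, pd.DataFrame]:
    """Assemble the comparison tables from per-shape experiment results.

    ``results`` maps a ShapeCode (or its string) to a
    :class:`~eegshapes.training.SubjectExperimentResult`.  Emits:

    * ``accuracy`` — subjects x shapes grid with Average and STD rows
      (subject-mean accuracy, in percent);
    * ``confusion`` — per-shape per-class pooled counts and percentages;
    * ``statistics`` — per shape: subject-mean accuracy (percent), pooled
      macro-F1, pooled Cohen's kappa, subject STD.  The subject-mean
      accuracy and the pooled-matrix accuracy are distinct quantities;
      both are reported, clearly labelled.

    Columns follow the canonical shape order.  When ``out_dir`` is given,
    each table is also written as CSV and (optionally) markdown.
    """
    results = {str(getattr(k, "value", k)): v for k, v in results.items()}
    order = [s.value for s in ALL_SHAPES if s.value in results]

    acc = pd.DataFrame(
        {
            shape: pd.Series(
                [a * 100 for a in results[shape].accuracies],
                index=results[shape].subject_ids,
            )
            for shape in order
        }
    )
    if not acc.empty:
        mean_row, std_rows = {}, {}
        for shape in order:
            m, s = subject_summary([a * 100 for a in results[shape].accuracies])
            mean_row[shape] = m
            std_rows[shape] = s
        acc.loc["Average"] = pd.Series(mean_row)
        acc.loc["STD"] = pd.Series(std_rows)

    conf_rows = []
    stat_rows = []
    for shape in order:
        r = results[shape]
        cm = ConfusionMatrix(r.pooled_counts, r.class_names)
        rates = class_rates_from_cm(cm)
        for _, row in rates.iterrows():
            conf_rows.append({"shape": shape, **row.to_dict()})
        mean_pct, std_pct = subject_summary([a * 100 for a in r.accuracies])
        stat_rows.append(
            {
                "shape": shape,
                "subject_mean_accuracy_pct": mean_pct,
                "pooled_accuracy_pct": 100 * accuracy_from_cm(cm),
                "macro_f1": macro_f1_from_cm(cm),
                "kappa": kappa_from_cm(cm),
                "subject_std_pct": std_pct,
            }
        )
    tables = {
        "accuracy": acc,
        "confusion": pd.DataFrame(conf_rows),
        "statistics": pd.DataFrame(stat_rows),
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv")
            if fmt == "markdown":
                try:
                    text = df.to_markdown()
                except ImportError:  # markdown rendering is optional
                    text = df.to_string()
                (out / f"{name}.md").write_text(text)
    return tables
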