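"""Published benchmark results for the eight input layouts.

These are the printed per-subject test accuracies (percent), pooled binary
confusion-matrix counts and summary statistics reported for the
left-vs-right task on the BCI Competition IV 2a and 2b datasets (nine
subjects each, raw unpreprocessed trials).  They serve two purposes:

* as fixed numeric inputs for re-deriving the summary statistics —
  the kappa/macro-F1/average values are recomputable from the counts and
  per-subject accuracies alone; and
* as the target context for the synthetic experiments (which layouts are
  expected to separate well and which to sit near chance).

Keys follow the canonical shape-code strings.  Confusion counts are stored
as ``[[TL, FL], [FR, TR]]`` — rows true (left, right), columns predicted
(left, right); row totals are 593/590 for 2a (left/right) and 1118/1123
for 2b.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = [
    "SUBJECT_ACCURACY",
    "CONFUSION_COUNTS",
    "SUMMARY_STATS",
    "reference_confusion_matrix",
]

# Per-subject test accuracy (percent), subjects S1..S9 in order.
SUBJECT_ACCURACY: dict[str, dict[str, list[float]]] = {
    "BCI-IV-2A": {
        "TxC": [84.40, 78.87, 96.35, 88.79, 92.59, 84.26, 92.14, 97.76, 88.46],
        "CxT": [60.28, 54.23, 54.74, 61.21, 72.59, 59.26, 72.14, 55.97, 54.62],
        "TxCx1": [54.61, 51.41, 48.18, 60.34, 68.15, 56.48, 65.00, 55.97, 53.85],
        "CxTx1": [63.12, 72.54, 71.53, 79.31, 87.41, 74.07, 91.43, 79.10, 81.54],
        "1xTxC": [68.09, 80.28, 75.18, 81.90, 94.07, 80.56, 85.71, 84.33, 82.31],
        "1xCxT": [47.52, 51.41, 51.82, 51.72, 57.04, 50.00, 56.43, 55.22, 56.15],
        "Tx1xC": [81.56, 81.69, 88.32, 84.48, 96.30, 83.33, 93.57, 94.03, 88.46],
        "Cx1xT": [60.28, 58.45, 59.12, 64.66, 74.81, 62.04, 74.29, 59.70, 60.00],
    },
    "BCI-IV-2B": {
        "TxC": [78.95, 70.20, 73.48, 96.74, 96.70, 83.67, 90.09, 91.74, 82.86],
        "CxT": [62.72, 56.73, 60.87, 57.33, 93.04, 60.96, 80.60, 64.35, 51.84],
        "TxCx1": [70.61, 63.67, 67.39, 94.14, 92.31, 76.10, 87.93, 88.26, 82.45],
        "CxTx1": [64.91, 71.43, 68.70, 64.17, 95.24, 69.32, 81.47, 81.30, 56.33],
        "1xTxC": [63.16, 64.49, 76.09, 61.56, 97.07, 68.53, 89.66, 78.26, 55.92],
        "1xCxT": [59.65, 66.53, 67.83, 58.96, 93.77, 64.14, 82.76, 62.61, 51.43],
        "Tx1xC": [78.95, 64.49, 66.96, 94.79, 98.53, 78.09, 93.10, 89.57, 79.59],
        "Cx1xT": [61.40, 61.63, 58.70, 58.31, 89.01, 61.35, 76.72, 62.17, 54.29],
    },
}

# Pooled binary confusion counts [[TL, FL], [FR, TR]] per layout.
CONFUSION_COUNTS: dict[str, dict[str, list[list[int]]]] = {
    "BCI-IV-2A": {
        "TxC": [[536, 57], [69, 521]],
        "CxT": [[384, 209], [257, 333]],
        "TxCx1": [[314, 279], [229, 361]],
        "CxTx1": [[440, 153], [110, 480]],
        "1xTxC": [[481, 112], [109, 481]],
        "1xCxT": [[329, 264], [291, 299]],
        "Tx1xC": [[514, 79], [62, 528]],
        "Cx1xT": [[378, 215], [214, 376]],
    },
    "BCI-IV-2B": {
        "TxC": [[936, 182], [144, 979]],
        "CxT": [[665, 453], [321, 802]],
        "TxCx1": [[931, 187], [241, 882]],
        "CxTx1": [[749, 369], [246, 877]],
        "1xTxC": [[805, 313], [300, 823]],
        "1xCxT": [[675, 443], [283, 840]],
        "Tx1xC": [[876, 242], [134, 989]],
        "Cx1xT": [[610, 508], [277, 846]],
    },
}

# Published summary statistics per layout:
# (subject-mean accuracy %, macro-F1, Cohen's kappa, printed STD).
SUMMARY_STATS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "BCI-IV-2A": {
        "TxC": (89.293, 0.893, 0.787, 5.471),
        "CxT": (60.561, 0.605, 0.212, 6.413),
        "TxCx1": (57.114, 0.570, 0.141, 5.704),
        "CxTx1": (77.782, 0.777, 0.555, 7.697),
        "1xTxC": (81.376, 0.813, 0.626, 6.376),
        "1xCxT": (53.033, 0.531, 0.062, 2.958),
        "Tx1xC": (87.969, 0.881, 0.762, 5.021),
        "Cx1xT": (63.713, 0.637, 0.275, 5.737),
    },
    "BCI-IV-2B": {
        "TxC": (84.943, 0.854, 0.709, 8.607),
        "CxT": (65.383, 0.653, 0.309, 11.695),
        "TxCx1": (80.318, 0.809, 0.618, 10.083),
        "CxTx1": (72.538, 0.725, 0.451, 10.436),
        "1xTxC": (72.747, 0.726, 0.453, 12.269),
        "1xCxT": (67.518, 0.674, 0.352, 11.628),
        "Tx1xC": (82.665, 0.830, 0.664, 10.846),
        "Cx1xT": (64.835, 0.646, 0.299, 9.790),
    },
}


def reference_confusion_matrix(dataset: str, shape: str) -> ConfusionMatrix:
    """The pooled binary confusion matrix for one dataset/layout pair."""
    counts = np.asarray(CONFUSION_COUNTS[dataset][str(getattr(shape, "value", shape))])
    return ConfusionMatrix(counts=counts, class_names=("left", "right"))
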