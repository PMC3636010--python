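"""Confusion matrices and per-class recognition / false-positive rates.

The per-class statistics follow the conventions of the published reference
evaluation this package reproduces:

* recognition rate of class c: 100 * counts[c][c] / rowsum(c) — the fraction
  of true c particles recognized as c;
* false-positive rate of class c: 100 * (colsum(c) - counts[c][c]) /
  counts[c][c] — particles of other classes assigned to c, relative to the
  correctly recognized c particles.  Note this differs from the usual
  FP / (FP + TN) convention.

Rates are reported rounded half-up to 2 decimals; summary averages are the
unweighted means over all classes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

#: default class order: detritus, unknown, then the ten taxa
DEFAULT_CLASS_ORDER = ("det", "ukw") + tuple(str(i) for i in range(1, 11))

#: bundled published reference evaluation counts (12-class field study)
REFERENCE_COUNTS_PATH = os.path.join(
    os.path.dirname(__file__), "data", "reference_confusion.csv")


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matching printed reference tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Class-ordered count matrix; rows = true class, columns = predicted."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.class_order = tuple(self.class_order)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {n})")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def index(self, c: str) -> int:
        try:
            return self.class_order.index(c)
        except ValueError:
            raise KeyError(f"unknown class {c!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def confusion_matrix(truth, predicted, class_order) -> ConfusionMatrix:
    """Count matrix from parallel true/predicted label lists."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    class_order = tuple(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    unknown = sorted({l for l in truth + predicted if l not in index})
    if unknown:
        raise ValueError(f"label(s) not in class_order: {unknown}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(class_order=class_order, counts=counts)


def recognition_rate(m: ConfusionMatrix, c: str) -> float:
    """Diagonal count over the true-class row total, in percent."""
    i = m.index(c)
    row = m.counts[i].sum()
    if row == 0:
        raise ValueError(f"class {c!r} has no true instances")
    return round2(100.0 * m.counts[i, i] / row)


def false_positive_rate(m: ConfusionMatrix, c: str) -> float:
    """Off-diagonal column sum over the diagonal count, in percent."""
    i = m.index(c)
    diag = m.counts[i, i]
    if diag == 0:
        raise ValueError(
            f"class {c!r} has no correctly recognized instances")
    return round2(100.0 * (m.counts[:, i].sum() - diag) / diag)


def summarize(m: ConfusionMatrix) -> dict:
    """Per-class rates plus their unweighted averages.

    Returns a dict with ``recognition`` and ``false_positive`` per-class
    maps and the ``avg_recognition`` / ``avg_false_positive`` scalars (the
    averages are taken over the exact per-class values, then rounded).
    """
    rec_exact, fp_exact = {}, {}
    for c in m.class_order:
        i = m.index(c)
        row = m.counts[i].sum()
        diag = m.counts[i, i]
        if row == 0 or diag == 0:
            raise ValueError(f"class {c!r} has undefined rates")
        rec_exact[c] = 100.0 * diag / row
        fp_exact[c] = 100.0 * (m.counts[:, i].sum() - diag) / diag
    return {
        "recognition": {c: round2(v) for c, v in rec_exact.items()},
        "false_positive": {c: round2(v) for c, v in fp_exact.items()},
        "avg_recognition": round2(np.mean(list(rec_exact.values()))),
        "avg_false_positive": round2(np.mean(list(fp_exact.values()))),
    }


def load_reference_counts(path: str | None = None) -> ConfusionMatrix:
    """The bundled reference evaluation's confusion-matrix counts."""
    df = pd.read_csv(path or REFERENCE_COUNTS_PATH, index_col=0)
    return ConfusionMatrix(class_order=tuple(df.index.astype(str)),
                           counts=df.to_numpy())


def metrics_frame(m: ConfusionMatrix) -> pd.DataFrame:
    """Tidy per-class metrics table (plus an unweighted-average row)."""
    s = summarize(m)
    rows = [{"class": c,
             "recognition_pct": s["recognition"][c],
             "false_positive_pct": s["false_positive"][c]}
            for c in m.class_order]
    rows.append({"class": "average",
                 "recognition_pct": s["avg_recognition"],
                 "false_positive_pct": s["avg_false_positive"]})
    return pd.DataFrame(rows)
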