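"""Multi-label evaluation measures.

Hamming Loss is the fraction of wrong label bits averaged over examples:
``HL = (1/N) sum_i |h(x_i) XOR y_i| / Q``.  Precision, recall and F1 are
computed per label from binary confusion counts and aggregated two ways:
macro (mean of per-label values) and micro (pooled counts first).  A
per-label precision or recall whose denominator is zero contributes 0 to
the macro mean, and a per-label F1 with P = R = 0 is defined as 0; this
matches common multi-label tooling and is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np

LABEL_AXIS_ERROR = "true and predicted label matrices must share shape (N, Q)"


def _as_bits(y) -> np.ndarray:
    arr = np.asarray(y, dtype=int)
    if arr.ndim != 2:
        raise ValueError(LABEL_AXIS_ERROR)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("label matrices must be binary (0/1)")
    return arr


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt, yp = _as_bits(y_true), _as_bits(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(LABEL_AXIS_ERROR)
    if yt.shape[0] == 0:
        raise ValueError("cannot score an empty label matrix")
    return yt, yp


def hamming_loss(y_true, y_pred) -> float:
    """Average fraction of misclassified label bits per example."""
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.mean(yt != yp))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label binary confusion counts, each a length-Q integer array."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_examples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Per-label TP/FP/FN/TN treating each label as a binary class."""
    yt, yp = _check_pair(y_true, y_pred)
    return ConfusionCounts(
        tp=((yt == 1) & (yp == 1)).sum(axis=0),
        fp=((yt == 0) & (yp == 1)).sum(axis=0),
        fn=((yt == 1) & (yp == 0)).sum(axis=0),
        tn=((yt == 0) & (yp == 0)).sum(axis=0),
    )


def _safe_div(num, denom) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    denom = np.asarray(denom, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def macro_micro(counts: ConfusionCounts) -> dict[str, float]:
    """Macro and micro averaged precision, recall and F1 from pooled counts."""
    p_j = _safe_div(counts.tp, counts.tp + counts.fp)
    r_j = _safe_div(counts.tp, counts.tp + counts.fn)
    f1_j = _safe_div(2 * p_j * r_j, p_j + r_j)
    tp, fp, fn = counts.tp.sum(), counts.fp.sum(), counts.fn.sum()
    p_micro = float(_safe_div(tp, tp + fp))
    r_micro = float(_safe_div(tp, tp + fn))
    f1_micro = float(_safe_div(2 * p_micro * r_micro, p_micro + r_micro))
    return {
        "p_macro": float(p_j.mean()), "r_macro": float(r_j.mean()),
        "f1_macro": float(f1_j.mean()),
        "p_micro": p_micro, "r_micro": r_micro, "f1_micro": f1_micro,
    }


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation: Hamming Loss plus micro/macro P, R and F1."""

    hamming_loss: float
    p_micro: float
    r_micro: float
    f1_micro: float
    p_macro: float
    r_macro: float
    f1_macro: float
    n_examples: int
    n_labels: int

    #: column order mirroring the standard report layout
    TABLE_COLUMNS = ("hamming_loss", "p_micro", "r_micro", "f1_micro",
                     "p_macro", "r_macro", "f1_macro")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self) -> list[float]:
        return [getattr(self, c) for c in self.TABLE_COLUMNS]


def evaluate(y_true, y_pred) -> MetricsReport:
    """Score a prediction: Hamming Loss plus the six averaged P/R/F1 values."""
    yt, yp = _check_pair(y_true, y_pred)
    counts = confusion(yt, yp)
    mm = macro_micro(counts)
    # internal consistency: micro F1 is the harmonic mean of micro P and R
    hm = _safe_div(2 * mm["p_micro"] * mm["r_micro"], mm["p_micro"] + mm["r_micro"])
    assert abs(float(hm) - mm["f1_micro"]) < 1e-12
    return MetricsReport(hamming_loss=hamming_loss(yt, yp), **mm,
                         n_examples=yt.shape[0], n_labels=yt.shape[1])


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Field-wise arithmetic mean of several reports."""
    if not reports:
        raise ValueError("cannot average zero reports")
    out = {}
    for f in fields(MetricsReport):
        vals = [getattr(r, f.name) for r in reports]
        out[f.name] = (float(np.mean(vals)) if f.name not in ("n_examples", "n_labels")
                       else int(round(np.mean(vals))))
    return MetricsReport(**out)
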