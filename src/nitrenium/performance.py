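"""Benchmark statistics and classification-cutoff sweep.

Seven metrics are reported per cutoff: accuracy, sensitivity, specificity,
positive and negative prediction values, Matthews correlation coefficient
and coverage.  Inconclusive and out-of-domain predictions are excluded
from the confusion matrix and reported through coverage, so a tool can
have high accuracy on the subset it covers.  A metric whose denominator
is zero is reported as absent (None), not as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

LABEL_MUT = "mutagen"
LABEL_NON = "nonmutagen"

_POSITIVE_PREDS = ("mutagenic",)
_NEGATIVE_PREDS = ("nonmutagenic",)
_EXCLUDED_PREDS = ("inconclusive", "equivocal")
_OOD_PREDS = ("out_of_domain",)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_inconclusive: int = 0
    n_out_of_domain: int = 0

    @property
    def total(self) -> int:
        return (self.tp + self.fp + self.tn + self.fn
                + self.n_inconclusive + self.n_out_of_domain)

    @property
    def covered(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsRow:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mcc: float | None
    coverage: float | None
    cutoff: float | None = None
    counts: ConfusionCounts | None = None


def confusion_counts(predictions: list[str], labels: list[str]) -> ConfusionCounts:
    """Tally a prediction/label pairing into confusion counts.

    Labels are 'mutagen'/'nonmutagen'; predictions may additionally be
    'inconclusive', 'equivocal' or 'out_of_domain', which are excluded
    from the four cells.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    c = ConfusionCounts()
    for pred, label in zip(predictions, labels):
        if label not in (LABEL_MUT, LABEL_NON):
            raise ValueError(f"unknown label '{label}'")
        if pred in _OOD_PREDS:
            c.n_out_of_domain += 1
        elif pred in _EXCLUDED_PREDS:
            c.n_inconclusive += 1
        elif pred in _POSITIVE_PREDS:
            if label == LABEL_MUT:
                c.tp += 1
            else:
                c.fp += 1
        elif pred in _NEGATIVE_PREDS:
            if label == LABEL_NON:
                c.tn += 1
            else:
                c.fn += 1
        else:
            raise ValueError(f"unknown prediction '{pred}'")
    return c


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts, cutoff: float | None = None) -> MetricsRow:
    """The seven benchmark statistics from one confusion table.

    Percentages are full precision (round only for display); MCC is
    dimensionless in [-1, 1].
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return MetricsRow(
        accuracy=_ratio(tp + tn, c.covered),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        mcc=mcc,
        coverage=_ratio(c.covered, c.total),
        cutoff=cutoff,
        counts=c,
    )


def default_grid(start: float = -10.0, stop: float = 10.0,
                 step: float = 2.5) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [start + i * step for i in range(n)]


def cutoff_sweep(dde_values: list[float | None], labels: list[str],
                 grid: list[float] | None = None
                 ) -> tuple[list[MetricsRow], MetricsRow]:
    """Metrics at every cutoff of the grid, plus the best row.

    A compound with an absent ddE counts as inconclusive at every cutoff.
    Best = maximal accuracy, ties broken by larger MCC then smaller
    absolute cutoff.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("empty cutoff grid")
    rows = []
    for cutoff in grid:
        preds = []
        for v in dde_values:
            if v is None:
                preds.append("inconclusive")
            else:
                preds.append("mutagenic" if v < cutoff else "nonmutagenic")
        rows.append(compute_metrics(confusion_counts(preds, labels), cutoff))

    def sort_key(row: MetricsRow):
        acc = -1.0 if row.accuracy is None else row.accuracy
        mcc = -2.0 if row.mcc is None else row.mcc
        return (-acc, -mcc, abs(row.cutoff))

    best = min(rows, key=sort_key)
    return rows, best


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal display rounding (0.05 -> 0.1), used for report output."""
    factor = 10 ** ndigits
    return math.floor(value * factor + 0.5) / factor


def format_row(row: MetricsRow) -> dict:
    """One-decimal display form, 'N/A' for absent metrics."""
    def fmt(v, pct=True):
        if v is None:
            return "N/A"
        return f"{round_half_up(v, 1):.1f}" + ("%" if pct else "")

    out = {
        "accuracy": fmt(row.accuracy),
        "sensitivity": fmt(row.sensitivity),
        "specificity": fmt(row.specificity),
        "ppv": fmt(row.ppv),
        "npv": fmt(row.npv),
        "mcc": fmt(row.mcc, pct=False),
        "coverage": fmt(row.coverage),
    }
    if row.cutoff is not None:
        out["cutoff"] = f"{row.cutoff:g}"
    return out
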