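"""Reference-versus-prediction evaluation statistics.

For each pathology the per-segment binary comparison is collapsed into a
confusion matrix, from which sensitivity, specificity, accuracy, PPV and
NPV are computed (in percent, rounded half-up to two decimals for display,
raw doubles kept internally).  Accuracy gets an exact Clopper-Pearson 95 %
binomial interval.  Agreement between the two readers is tested with
McNemar's test on the discordant counts; the default is the
continuity-corrected chi-square variant, an exact binomial variant is
available.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .datamodel import PATHOLOGIES, ReferenceReading, ValidationError

__all__ = [
    "ConfusionCounts",
    "PerformanceSummary",
    "confusion",
    "pooled_confusion",
    "metrics",
    "accuracy_ci",
    "mcnemar",
    "evaluate_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts for one pathology over a set of segments."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        """Reference-positive segments."""
        return self.tp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class PerformanceSummary:
    """The five reported rates (percent), the accuracy CI and McNemar p."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy_ci_95: tuple[float, float]
    mcnemar_p: float
    n: int
    prevalence_percent: float


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (display convention for percentages)."""
    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    )


def _rate(num: int, den: int) -> Optional[float]:
    """Percentage, or None (rendered "NA") on a zero denominator."""
    if den == 0:
        return None
    return _round2(100.0 * num / den)


def confusion(pred: ReferenceReading, truth: ReferenceReading, pathology: str) -> ConfusionCounts:
    """Per-segment binary comparison of one pathology for one study."""
    if pathology not in PATHOLOGIES:
        raise ValidationError(f"unknown pathology {pathology!r}")
    if set(pred.segments) != set(truth.segments):
        raise ValidationError("prediction and truth cover different segments")
    tp = tn = fp = fn = 0
    for seg in truth.segments:
        t, p = truth.get(seg, pathology), pred.get(seg, pathology)
        if t and p:
            tp += 1
        elif t and not p:
            fn += 1
        elif not t and p:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def pooled_confusion(
    pred: Mapping[str, ReferenceReading],
    truth: Mapping[str, ReferenceReading],
    pathology: str,
) -> ConfusionCounts:
    """Confusion counts pooled over all studies of a cohort."""
    if set(pred) != set(truth):
        raise ValidationError("prediction and truth cover different studies")
    total = None
    for sid in sorted(truth):
        c = confusion(pred[sid], truth[sid], pathology)
        total = c if total is None else total + c
    if total is None:
        raise ValidationError("empty cohort")
    return total


def accuracy_ci(c: ConfusionCounts, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval on the accuracy proportion."""
    low, high = proportion_confint(c.tp + c.tn, c.total, alpha=1.0 - level, method="beta")
    return float(low), float(high)


def mcnemar(c: ConfusionCounts, method: str = "cc_chi2") -> float:
    """McNemar test p-value on the discordant counts (FP vs FN).

    ``cc_chi2``: continuity-corrected chi-square on 1 df,
    ``chi2 = max(|fp - fn| - 1, 0)^2 / (fp + fn)``; zero discordant pairs
    or a zero statistic give p = 1.  ``exact``: two-sided binomial test
    of min(fp, fn) out of fp + fn at 0.5.
    """
    b, cdis = c.fp, c.fn
    n_dis = b + cdis
    if method == "cc_chi2":
        if n_dis == 0:
            return 1.0
        chi2 = max(abs(b - cdis) - 1, 0) ** 2 / n_dis
        if chi2 <= 0:
            return 1.0
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        if n_dis == 0:
            return 1.0
        return float(stats.binomtest(min(b, cdis), n_dis, 0.5).pvalue)
    raise ValueError(f"unknown McNemar method {method!r}")


def metrics(c: ConfusionCounts, mcnemar_method: str = "cc_chi2") -> PerformanceSummary:
    """The five rates, the accuracy CI and the McNemar p for one matrix."""
    return PerformanceSummary(
        counts=c,
        sensitivity=_rate(c.tp, c.tp + c.fn),
        specificity=_rate(c.tn, c.tn + c.fp),
        accuracy=_rate(c.tp + c.tn, c.total),
        ppv=_rate(c.tp, c.tp + c.fp),
        npv=_rate(c.tn, c.tn + c.fn),
        accuracy_ci_95=accuracy_ci(c),
        mcnemar_p=mcnemar(c, mcnemar_method),
        n=c.total,
        prevalence_percent=_rate(c.positives, c.total) or 0.0,
    )


def _fmt(x: Optional[float]) -> object:
    return "NA" if x is None else x


def summary_frame(
    summaries: Mapping[str, PerformanceSummary], pathologies: Sequence[str] = PATHOLOGIES
) -> pd.DataFrame:
    """One row per pathology, in the layout of a diagnostic-performance table."""
    rows = []
    for path in pathologies:
        s = summaries[path]
        c = s.counts
        rows.append(
            {
                "pathology": path,
                "n_positive": c.positives,
                "prevalence_percent": s.prevalence_percent,
                "TP": c.tp,
                "TN": c.tn,
                "FP": c.fp,
                "FN": c.fn,
                "sensitivity": _fmt(s.sensitivity),
                "specificity": _fmt(s.specificity),
                "accuracy": _fmt(s.accuracy),
                "ppv": _fmt(s.ppv),
                "npv": _fmt(s.npv),
                "accuracy_ci_low": round(s.accuracy_ci_95[0], 4),
                "accuracy_ci_high": round(s.accuracy_ci_95[1], 4),
                "mcnemar_p": s.mcnemar_p,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def evaluate_table(
    pred: Mapping[str, ReferenceReading],
    truth: Mapping[str, ReferenceReading],
    pathologies: Sequence[str] = PATHOLOGIES,
    mcnemar_method: str = "cc_chi2",
) -> pd.DataFrame:
    """Full per-pathology evaluation of a prediction set against a reference."""
    summaries = {
        path: metrics(pooled_confusion(pred, truth, path), mcnemar_method)
        for path in pathologies
    }
    return summary_frame(summaries, pathologies)
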