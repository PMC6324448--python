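"""Confusion-matrix metrics and paired classifier comparison.

Metrics follow the diagnostic-test convention with bleeding-present as the
positive class; the F score is the harmonic mean of sensitivity and positive
predictive value (i.e. F1 with PPV as precision and sensitivity as recall).
Two classifiers evaluated on the same notes are compared with a McNemar test
on the discordant correct/incorrect pairs, plus a paired Wald confidence
interval on the sensitivity difference over gold-positive notes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "PairedComparison",
    "confusion",
    "metrics",
    "mcnemar",
]

#: Discordant-pair count at or above which the chi-square approximation is
#: used instead of the exact binomial p-value.
EXACT_CUTOFF = 25


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Diagnostic metrics; ``None`` marks an undefined (0/0) quantity."""

    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    f_score: Optional[float]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "f_score": self.f_score,
            "npv": self.npv,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class PairedComparison:
    discordant_b: int  # A correct, B wrong
    discordant_c: int  # A wrong, B correct
    statistic: float
    p_value: float
    sensitivity_difference: float
    ci_low: float
    ci_high: float
    exact: bool


def _as_binary(labels: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=int)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1 labels")
    return arr


def confusion(pred: Sequence[int], gold: Sequence[int]) -> ConfusionMatrix:
    """2x2 tally of predictions against the reference standard."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gold, "gold")
    if p.shape != g.shape:
        raise ValueError(
            f"length mismatch: {p.size} predictions vs {g.size} gold labels"
        )
    return ConfusionMatrix(
        tp=int(((p == 1) & (g == 1)).sum()),
        fp=int(((p == 1) & (g == 0)).sum()),
        fn=int(((p == 0) & (g == 1)).sum()),
        tn=int(((p == 0) & (g == 0)).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV, accuracy and F score.

    Zero denominators yield ``None`` rather than a silent zero.  The F score
    is defined whenever sensitivity and PPV are both defined and not both
    zero.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    if sens is None or ppv is None or (sens + ppv) == 0:
        f = None
    else:
        f = 2 * sens * ppv / (sens + ppv)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f_score=f,
    )


def mcnemar(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    gold: Sequence[int],
    exact: Optional[bool] = None,
) -> PairedComparison:
    """McNemar comparison of two classifiers on the same notes.

    Correctness against the gold standard defines the paired outcomes:
    ``b`` counts notes A got right and B got wrong, ``c`` the reverse.  The
    p-value is the exact two-sided binomial probability when ``b + c`` is
    below :data:`EXACT_CUTOFF`, otherwise the continuity-corrected
    chi-square statistic ``(|b - c| - 1)^2 / (b + c)`` with one degree of
    freedom (the correction keeps the asymptotic p within about 0.002 of
    the exact one at moderate discordant counts); pass ``exact`` to force
    either route.  ``b + c == 0`` yields statistic 0 and p = 1 by
    convention.  Also reports the difference in sensitivity over
    gold-positive notes with a 95% paired Wald interval.
    """
    a = _as_binary(pred_a, "pred_a")
    b_arr = _as_binary(pred_b, "pred_b")
    g = _as_binary(gold, "gold")
    if not (a.shape == b_arr.shape == g.shape):
        raise ValueError("pred_a, pred_b and gold must have equal length")
    if len(np.unique(g)) < 2:
        raise ValueError("gold labels must contain both classes")

    a_ok, b_ok = a == g, b_arr == g
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    n_disc = b + c

    if exact is None:
        exact = n_disc < EXACT_CUTOFF
    statistic = 0.0 if n_disc == 0 else max(abs(b - c) - 1, 0) ** 2 / n_disc
    if n_disc == 0:
        p = 1.0
    elif exact:
        p = float(stats.binomtest(b, n_disc, 0.5).pvalue)
    else:
        p = float(stats.chi2.sf(statistic, df=1))

    # paired sensitivity difference on gold positives: Wald CI for the
    # difference of two paired proportions
    pos = g == 1
    n_pos = int(pos.sum())
    b_pos = int((a_ok & ~b_ok & pos).sum())
    c_pos = int((~a_ok & b_ok & pos).sum())
    diff = (b_pos - c_pos) / n_pos
    var = (b_pos + c_pos) / n_pos**2 - (b_pos - c_pos) ** 2 / n_pos**3
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return PairedComparison(
        discordant_b=b,
        discordant_c=c,
        statistic=statistic,
        p_value=min(p, 1.0),
        sensitivity_difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        exact=bool(exact),
    )
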