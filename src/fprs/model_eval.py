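"""Model performance metrics: AUC, Cohen's kappa, TSS and threshold maxima.

Suitability predictions are scored against presence/absence labels.  AUC
is the rank-based (Mann-Whitney) statistic — the probability that a random
presence scores above a random absence, ties counted 1/2 — so it needs no
threshold.  Kappa and the true skill statistic (TSS = sensitivity +
specificity - 1) do need one; following the reference protocol they are
evaluated on the 19-point threshold grid 0.05, 0.10, ..., 0.95 and the
grid maxima (Max kappa, Max TSS) reported.

Thresholding rule: a score exactly equal to the threshold is predicted
*present* (score >= t), the MaxEnt-community convention.  Thresholds are
generated as exact multiples k/20 to keep the 19-point grid free of float
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvalSample",
    "ConfusionCounts",
    "EvalMetrics",
    "THRESHOLD_GRID",
    "auc",
    "confusion_at_threshold",
    "kappa",
    "tss",
    "max_over_thresholds",
]

#: The 19 evaluation thresholds 0.05 .. 0.95 (exact multiples of 1/20).
THRESHOLD_GRID: tuple[float, ...] = tuple(k / 20 for k in range(1, 20))


class SingleClassError(ValueError):
    """AUC requires at least one presence and one absence."""


@dataclass
class EvalSample:
    """Parallel presence/absence labels and predicted suitabilities."""

    labels: np.ndarray  # bool, True = present
    scores: np.ndarray  # float in [0, 1]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise ValueError("labels and scores must be parallel 1-D sequences")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_present(self) -> int:
        return int(self.labels.sum())

    @property
    def n_absent(self) -> int:
        return int((~self.labels).sum())


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency table of thresholded predictions vs labels."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalMetrics:
    """AUC plus the threshold-grid maxima and the full per-threshold curve."""

    auc: float
    max_kappa: float
    max_tss: float
    threshold_curve: pd.DataFrame  # columns: threshold, kappa, tss


def auc(sample: EvalSample) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted as 1/2."""
    n1, n0 = sample.n_present, sample.n_absent
    if n1 == 0 or n0 == 0:
        raise SingleClassError("AUC needs at least one presence and one absence")
    ranks = rankdata(sample.scores)  # midranks for ties
    r1 = ranks[sample.labels].sum()
    u = r1 - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def confusion_at_threshold(sample: EvalSample, t: float) -> ConfusionCounts:
    """Count the 2x2 table with 'predicted present' defined as score >= t."""
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    pred = sample.scores >= t
    return ConfusionCounts(
        tp=int(np.sum(pred & sample.labels)),
        fp=int(np.sum(pred & ~sample.labels)),
        fn=int(np.sum(~pred & sample.labels)),
        tn=int(np.sum(~pred & ~sample.labels)),
    )


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e); 0 when p_e = 1."""
    n = c.total
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n**2
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def tss(c: ConfusionCounts) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("TSS undefined: a label class is empty")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.fp + c.tn)
    return sens + spec - 1.0


def max_over_thresholds(sample: EvalSample) -> EvalMetrics:
    """Evaluate kappa and TSS on the 19-point grid; report maxima and AUC."""
    rows = []
    for t in THRESHOLD_GRID:
        c = confusion_at_threshold(sample, t)
        rows.append((t, kappa(c), tss(c)))
    curve = pd.DataFrame(rows, columns=["threshold", "kappa", "tss"])
    return EvalMetrics(
        auc=auc(sample),
        max_kappa=float(curve["kappa"].max()),
        max_tss=float(curve["tss"].max()),
        threshold_curve=curve,
    )
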