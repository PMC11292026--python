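"""Binary classification under threshold semantics and confusion-matrix metrics.

Predictions are made by comparing a numeric score against a threshold under
the tool's direction/comparison semantics (:func:`classify`), and summarised
by the five statistics standard in predictor benchmarking: sensitivity,
specificity, accuracy, positive predictive value, and the Matthews
correlation coefficient (MCC).  MCC is the model-selection objective
throughout the package; it ranges from -1 (total anti-correlation) through 0
(random) to 1 (perfect) and is robust to the class imbalance typical of
curated disease/neutral variant sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import ASCENDING, DESCENDING, INCLUSIVE, STRICT, ToolSpec

PATHOGENIC = "pathogenic"
BENIGN = "benign"
MISSING = "missing"

DISEASE = "disease"
NEUTRAL = "neutral"
VUS = "vus"

#: categorical outputs treated as predicted pathogenic / benign
_CATEGORICAL_PATHOGENIC = frozenset(
    {"deleterious", "damaging", "probably damaging", "possibly damaging"}
)
_CATEGORICAL_BENIGN = frozenset({"tolerated", "benign"})


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with disease / predicted-pathogenic as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five performance statistics plus evaluated class sizes.

    Ratio metrics with a zero denominator are NaN; MCC with a zero
    denominator is defined as 0 (a constant classifier carries no signal).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    mcc: float
    n_pos: int
    n_neg: int

    def rounded(self) -> dict:
        """Report rendering: percentages at 0 dp, MCC at 2 dp."""
        return {
            "sensitivity_pct": round_half_away(100 * self.sensitivity)
            if not math.isnan(self.sensitivity) else float("nan"),
            "specificity_pct": round_half_away(100 * self.specificity)
            if not math.isnan(self.specificity) else float("nan"),
            "accuracy_pct": round_half_away(100 * self.accuracy)
            if not math.isnan(self.accuracy) else float("nan"),
            "ppv_pct": round_half_away(100 * self.ppv)
            if not math.isnan(self.ppv) else float("nan"),
            "mcc": round(self.mcc, 2),
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def classify(score: float, threshold: float, spec: ToolSpec) -> str:
    """Predict pathogenic/benign for one score under a tool's semantics.

    Ascending tools call high scores pathogenic, descending tools low
    scores; inclusive comparison counts the threshold value itself as
    pathogenic.  A missing (NaN/None) score yields ``"missing"``.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return MISSING
    if spec.direction == ASCENDING:
        hit = score >= threshold if spec.comparison == INCLUSIVE else score > threshold
    else:
        hit = score <= threshold if spec.comparison == INCLUSIVE else score < threshold
    return PATHOGENIC if hit else BENIGN


def classify_scores(scores, threshold: float, spec: ToolSpec) -> pd.Series:
    """Vectorised :func:`classify`; NaN scores map to ``"missing"``."""
    s = pd.Series(scores, dtype=float)
    if spec.direction == ASCENDING:
        hit = s >= threshold if spec.comparison == INCLUSIVE else s > threshold
    else:
        hit = s <= threshold if spec.comparison == INCLUSIVE else s < threshold
    out = pd.Series(np.where(hit, PATHOGENIC, BENIGN), index=s.index, dtype=object)
    out[s.isna()] = MISSING
    return out


def map_categorical(label: str) -> str:
    """Map a tool's categorical output onto pathogenic/benign."""
    norm = str(label).strip().lower()
    if norm in _CATEGORICAL_PATHOGENIC:
        return PATHOGENIC
    if norm in _CATEGORICAL_BENIGN:
        return BENIGN
    accepted = sorted(_CATEGORICAL_PATHOGENIC | _CATEGORICAL_BENIGN)
    raise MetricsError(f"unknown categorical prediction {label!r}; accepted: {accepted}")


def confusion(predictions: Sequence[str], labels: Sequence[str]) -> ConfusionMatrix:
    """Tabulate predictions against disease/neutral labels.

    Variants with a missing prediction are dropped from the counts and
    reported in ``n_missing``.  Labels must be ``disease`` or ``neutral``.
    """
    preds = np.asarray(predictions, dtype=object)
    labs = np.asarray(labels, dtype=object)
    if preds.shape != labs.shape:
        raise MetricsError("predictions and labels differ in length")
    bad = set(labs) - {DISEASE, NEUTRAL}
    if bad:
        raise MetricsError(f"labels must be disease/neutral, got {sorted(bad)}")
    keep = preds != MISSING
    n_missing = int((~keep).sum())
    preds, labs = preds[keep], labs[keep]
    if preds.size == 0:
        raise MetricsError("no evaluable variants (all predictions missing)")
    is_path = preds == PATHOGENIC
    is_dis = labs == DISEASE
    return ConfusionMatrix(
        tp=int((is_path & is_dis).sum()),
        fp=int((is_path & ~is_dis).sum()),
        tn=int((~is_path & ~is_dis).sum()),
        fn=int((~is_path & is_dis).sum()),
        n_missing=n_missing,
    )


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty.

    Products are taken in exact integer arithmetic before the single
    floating division, so the value is reproducible to machine precision.
    """
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """The five statistics of a confusion matrix (full precision)."""
    if cm.total == 0:
        raise MetricsError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    return MetricSet(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / cm.total,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        mcc=mcc_from_counts(tp, fp, tn, fn),
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
    )


def reconstruct_confusion(
    sp_pct: float, sn_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Rebuild integer counts from rounded percent sensitivity/specificity.

    Published benchmark tables typically print Sn/Sp rounded to whole
    percentages; with the class sizes known, the underlying counts are
    recovered as the nearest integers (halves away from zero).  The
    reconstruction is exact only up to that printed rounding, so derived
    quantities (PPV in particular) can disagree with a printed table by
    one count's worth.
    """
    if not (0 <= sp_pct <= 100 and 0 <= sn_pct <= 100):
        raise MetricsError("percentages must lie in [0, 100]")
    tp = round_half_away(sn_pct / 100 * n_pos)
    tn = round_half_away(sp_pct / 100 * n_neg)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
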