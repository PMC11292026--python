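"""Gene-specific threshold optimisation by exhaustive MCC sweep.

For one predictor on one labeled variant set, every classification reachable
by thresholding is realised by some candidate in the set of distinct
observed scores plus one sentinel beyond each extreme (evaluating a
threshold strictly between two consecutive observed scores produces the same
partition as the nearer observed score under the tool's native comparison
operator).  The sweep therefore evaluates exactly that candidate set, under
the tool's direction/comparison semantics, and returns the candidate with
the globally maximal MCC together with the full sweep curve.

Ties on MCC are broken deterministically in favour of the candidate with the
highest specificity (fewer false pathogenic calls), then the most stringent
threshold (largest for ascending tools, smallest for descending).

Complexity is O(n log n): one sort per class plus vectorised rank lookups;
a brute-force O(n^2) re-evaluation exists in the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import DISEASE, MetricSet, ConfusionMatrix, compute_metrics
from .registry import ASCENDING, INCLUSIVE, ToolSpec


class CalibrationError(ValueError):
    pass


@dataclass
class ThresholdSearchResult:
    """Outcome of one threshold sweep.

    ``curve`` holds one row per candidate threshold with the counts and
    the derived sensitivity/specificity/MCC, sorted by threshold.
    """

    tool: str
    best_threshold: float
    best_mcc: float
    best_metrics: MetricSet
    curve: pd.DataFrame
    n_candidates: int
    tie_count: int


def _prepare(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=object)
    if s.shape != y.shape:
        raise CalibrationError("scores and labels differ in length")
    keep = ~np.isnan(s)
    if not keep.any():
        raise CalibrationError("all scores missing")
    s, y = s[keep], y[keep]
    is_dis = y == DISEASE
    if is_dis.all() or not is_dis.any():
        raise CalibrationError(
            "threshold optimisation needs both a disease and a neutral variant "
            "with non-missing scores"
        )
    return s, is_dis


def _sweep_counts(
    s: np.ndarray, is_dis: np.ndarray, spec: ToolSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate thresholds and (tp, fp) at each, under the spec's semantics."""
    sd = np.sort(s[is_dis])
    sn = np.sort(s[~is_dis])
    candidates = np.unique(s)
    # sentinels make the all-pathogenic and all-benign partitions reachable
    candidates = np.concatenate(([candidates[0] - 1.0], candidates, [candidates[-1] + 1.0]))
    inclusive = spec.comparison == INCLUSIVE
    if spec.direction == ASCENDING:
        # pathogenic iff score > t (strict) or score >= t (inclusive)
        side = "left" if inclusive else "right"
        tp = len(sd) - np.searchsorted(sd, candidates, side=side)
        fp = len(sn) - np.searchsorted(sn, candidates, side=side)
    else:
        # pathogenic iff score < t (strict) or score <= t (inclusive)
        side = "right" if inclusive else "left"
        tp = np.searchsorted(sd, candidates, side=side)
        fp = np.searchsorted(sn, candidates, side=side)
    return candidates, tp, fp


def optimize_threshold(scores, labels, spec: ToolSpec) -> ThresholdSearchResult:
    """Find the threshold maximising MCC for one tool on labeled variants.

    ``labels`` are ``"disease"``/``"neutral"`` strings aligned with
    ``scores``; missing (NaN) scores are excluded (complete-case).
    """
    s, is_dis = _prepare(scores, labels)
    n_pos, n_neg = int(is_dis.sum()), int((~is_dis).sum())
    candidates, tp, fp = _sweep_counts(s, is_dis, spec)
    fn = n_pos - tp
    tn = n_neg - fp

    with np.errstate(invalid="ignore"):
        denom = np.sqrt(
            (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.where(denom > 0, denom, 1.0), 0.0)
        sens = np.where(n_pos > 0, tp / n_pos, np.nan)
        spec_ = np.where(n_neg > 0, tn / n_neg, np.nan)

    best_mcc = mcc.max()
    tied = np.flatnonzero(mcc == best_mcc)
    # highest specificity first, then the most stringent threshold
    tied = tied[spec_[tied] == spec_[tied].max()]
    best_idx = tied[np.argmax(candidates[tied])] if spec.direction == ASCENDING \
        else tied[np.argmin(candidates[tied])]
    tie_count = int((mcc == best_mcc).sum())

    curve = pd.DataFrame(
        {
            "threshold": candidates,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec_, "mcc": mcc,
        }
    ).sort_values("threshold", ignore_index=True)

    cm = ConfusionMatrix(
        tp=int(tp[best_idx]), fp=int(fp[best_idx]),
        tn=int(tn[best_idx]), fn=int(fn[best_idx]),
    )
    return ThresholdSearchResult(
        tool=spec.name,
        best_threshold=float(candidates[best_idx]),
        best_mcc=float(mcc[best_idx]),
        best_metrics=compute_metrics(cm),
        curve=curve,
        n_candidates=len(candidates),
        tie_count=tie_count,
    )


def roc_points(scores, labels, spec: ToolSpec) -> pd.DataFrame:
    """ROC curve from the same sweep: (fpr, tpr, threshold) per candidate.

    Points are sorted by false-positive rate (staircase: sensitivity is
    non-decreasing along the curve) and include the (0,0) and (1,1)
    endpoints via the sentinel candidates.
    """
    s, is_dis = _prepare(scores, labels)
    n_pos, n_neg = int(is_dis.sum()), int((~is_dis).sum())
    candidates, tp, fp = _sweep_counts(s, is_dis, spec)
    df = pd.DataFrame(
        {"fpr": fp / n_neg, "tpr": tp / n_pos, "threshold": candidates}
    )
    return df.sort_values(["fpr", "tpr"], ignore_index=True)


def auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under a :func:`roc_points` curve."""
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))
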