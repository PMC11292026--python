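"""Majority-rule combination of predictors and exhaustive panel evaluation.

A variant is called pathogenic by a panel when strictly more than half of
the member tools call it pathogenic ("agreement of over 50%"); an even
panel split is therefore a benign call, which makes two-tool panels
unanimity panels.  Variants missing any member's score are excluded from
that combination's evaluation (complete-case) and reported in
``n_evaluable``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import (
    BENIGN,
    MISSING,
    PATHOGENIC,
    MetricSet,
    compute_metrics,
    confusion,
    classify_scores,
)
from .registry import ToolRegistry


class EnsembleError(ValueError):
    pass


@dataclass
class CombinationResult:
    tools: tuple[str, ...]
    thresholds: dict[str, float]
    metrics: MetricSet
    n_evaluable: int


def majority_vote(predictions: Sequence[str]) -> str:
    """Combine member predictions by strict majority; ties are benign."""
    if len(predictions) == 0:
        raise EnsembleError("empty panel")
    bad = set(predictions) - {PATHOGENIC, BENIGN}
    if bad:
        raise EnsembleError(
            f"majority_vote expects pathogenic/benign member votes, got {sorted(bad)}; "
            "handle missing scores upstream"
        )
    n_path = sum(p == PATHOGENIC for p in predictions)
    return PATHOGENIC if 2 * n_path > len(predictions) else BENIGN


def panel_predictions(
    scores: pd.DataFrame,
    tools: Sequence[str],
    registry: ToolRegistry,
    thresholds: Mapping[str, float],
) -> pd.Series:
    """Per-variant majority vote for one panel; missing where incomplete."""
    votes = pd.DataFrame(
        {t: classify_scores(scores[t], thresholds[t], registry[t]) for t in tools}
    )
    complete = ~(votes == MISSING).any(axis=1)
    n_path = (votes == PATHOGENIC).sum(axis=1)
    out = pd.Series(
        np.where(2 * n_path > len(tools), PATHOGENIC, BENIGN),
        index=scores.index, dtype=object,
    )
    out[~complete] = MISSING
    return out


def evaluate_combinations(
    scores: pd.DataFrame,
    labels,
    registry: ToolRegistry,
    thresholds: Mapping[str, float],
    panel_sizes: Iterable[int] = (2, 3),
    tools: Sequence[str] | None = None,
) -> list[CombinationResult]:
    """Evaluate every tool subset at the requested panel sizes.

    ``thresholds`` maps each candidate tool to the cut-off to vote with
    (default or optimised).  Results are sorted by MCC descending, ties by
    panel name for determinism.
    """
    tools = list(tools) if tools is not None else [t for t in registry if t in scores.columns]
    absent = [t for t in tools if t not in scores.columns]
    if absent:
        raise EnsembleError(f"tool(s) absent from score matrix: {absent}")
    labels = pd.Series(np.asarray(labels, dtype=object), index=scores.index)
    results = []
    for size in sorted(set(panel_sizes)):
        for panel in itertools.combinations(tools, size):
            preds = panel_predictions(scores, panel, registry, thresholds)
            cm = confusion(preds.to_numpy(), labels.to_numpy())
            results.append(
                CombinationResult(
                    tools=panel,
                    thresholds={t: thresholds[t] for t in panel},
                    metrics=compute_metrics(cm),
                    n_evaluable=cm.total,
                )
            )
    results.sort(key=lambda r: (-r.metrics.mcc, r.tools))
    return results


def combinations_table(results: list[CombinationResult]) -> pd.DataFrame:
    """Flatten combination results into a report-ready frame."""
    rows = []
    for r in results:
        row = {"tools": "+".join(r.tools), "n_evaluable": r.n_evaluable}
        row.update(
            {
                "sensitivity": r.metrics.sensitivity,
                "specificity": r.metrics.specificity,
                "accuracy": r.metrics.accuracy,
                "ppv": r.metrics.ppv,
                "mcc": r.metrics.mcc,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
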