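"""Validation machinery: k-fold cross-validation of threshold optimisation,
threshold transfer to an independent dataset, VUS re-scoring, and the
label-contamination robustness experiment.

Cross-validation learns the MCC-optimal threshold on k-1 folds and scores
the held-out fold; the held-out variants never influence the learned
threshold (asserted by construction on disjoint id sets).  Transfer
evaluation learns thresholds on a training (primary) dataset only and
applies them unchanged to a test (secondary) dataset, alongside the default
thresholds, mirroring how a calibrated pipeline would be deployed
prospectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .calibration import CalibrationError, optimize_threshold
from .ensemble import panel_predictions
from .metrics import (
    DISEASE,
    NEUTRAL,
    PATHOGENIC,
    MetricSet,
    classify_scores,
    compute_metrics,
    confusion,
)
from .registry import ToolRegistry, ToolSpec

log = logging.getLogger(__name__)

_METRIC_FIELDS = ("sensitivity", "specificity", "accuracy", "ppv", "mcc")


class ValidationError(ValueError):
    pass


@dataclass
class FoldResult:
    fold_index: int
    threshold: float
    metrics: MetricSet


@dataclass
class CVReport:
    """Per-fold thresholds and test metrics plus their mean and sample sd."""

    tool: str
    k: int
    seed: int
    folds: list[FoldResult]
    mean: dict[str, float]
    sd: dict[str, float]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "fold": f.fold_index,
                "threshold": f.threshold,
                **{m: getattr(f.metrics, m) for m in _METRIC_FIELDS},
            }
            for f in self.folds
        ]
        return pd.DataFrame(rows)


def kfold_split(
    variant_ids: Sequence,
    k: int,
    seed: int,
    labels: Sequence[str] | None = None,
    stratified: bool = False,
    max_retries: int = 100,
) -> list[np.ndarray]:
    """Split ids into k disjoint subsets whose sizes differ by at most one.

    The shuffle is seeded, so the split is reproducible.  When ``labels``
    are supplied, any draw leaving a subset without one of the two classes
    is redrawn with an incremented seed (logged), up to ``max_retries``;
    ``stratified=True`` shuffles within each class instead, which
    guarantees class presence whenever each class has at least k members.
    """
    ids = np.asarray(variant_ids)
    if k < 2:
        raise ValidationError("k must be at least 2")
    if len(ids) < k:
        raise ValidationError(f"cannot split {len(ids)} variants into {k} folds")
    labs = None if labels is None else np.asarray(labels, dtype=object)

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        if stratified and labs is not None:
            order = []
            for cls in pd.unique(labs):
                idx = np.flatnonzero(labs == cls)
                order.append(rng.permutation(idx))
            # deal class-by-class round-robin so folds stay balanced per class
            perm = np.concatenate(order)
        else:
            perm = rng.permutation(len(ids))
        folds = [perm[i::k] for i in range(k)]
        if labs is None:
            break
        ok = all(len(set(labs[f])) == len(set(labs)) for f in folds)
        if ok:
            if attempt:
                log.info("kfold_split redrew %d time(s) for class presence", attempt)
            break
    else:
        raise ValidationError(
            f"could not draw a {k}-fold split with both classes in every fold "
            f"after {max_retries} attempts"
        )
    return [np.sort(ids[f]) for f in folds]


def cross_validate(
    scores,
    labels,
    spec: ToolSpec,
    k: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> CVReport:
    """k-fold cross-validation of threshold optimisation for one tool.

    ``scores``/``labels`` are aligned pandas Series (index = variant id)
    or arrays.  Each fold's threshold is learned on the other k-1 folds
    and all five metrics are computed on the held-out fold.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    y = pd.Series(np.asarray(labels, dtype=object))
    ids = np.arange(len(s))
    folds = kfold_split(ids, k, seed, labels=y.to_numpy(), stratified=stratified)
    results = []
    for i, test_ids in enumerate(folds, start=1):
        train_mask = ~np.isin(ids, test_ids)
        res = optimize_threshold(s[train_mask], y[train_mask], spec)
        preds = classify_scores(s[~train_mask], res.best_threshold, spec)
        cm = confusion(preds.to_numpy(), y[~train_mask].to_numpy())
        results.append(FoldResult(i, res.best_threshold, compute_metrics(cm)))
    means = {m: mean(getattr(f.metrics, m) for f in results) for m in _METRIC_FIELDS}
    sds = {m: stdev(getattr(f.metrics, m) for f in results) for m in _METRIC_FIELDS}
    return CVReport(tool=spec.name, k=k, seed=seed, folds=results, mean=means, sd=sds)


def evaluate_transfer(
    train_scores: pd.DataFrame,
    train_labels,
    test_scores: pd.DataFrame,
    test_labels,
    registry: ToolRegistry,
    tools: Sequence[str] | None = None,
    panel: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Evaluate default and train-learned thresholds on an independent test set.

    Thresholds are optimised on the training dataset only and applied
    unchanged to the test dataset.  When ``panel`` is given (or defaults
    to the top three tools by training optimised MCC) a majority-vote
    combination row at the transferred thresholds is appended.
    """
    tools = list(tools) if tools is not None else [
        t for t in registry if t in train_scores.columns and t in test_scores.columns
    ]
    if not tools:
        raise ValidationError("no tool columns shared by the two score matrices")
    train_y = np.asarray(train_labels, dtype=object)
    test_y = np.asarray(test_labels, dtype=object)
    rows = []
    learned: dict[str, float] = {}
    train_mcc: dict[str, float] = {}
    for t in tools:
        spec = registry[t]
        res = optimize_threshold(train_scores[t], train_y, spec)
        learned[t] = res.best_threshold
        train_mcc[t] = res.best_mcc
        for kind, thr in (("default", spec.default_threshold), ("optimized", res.best_threshold)):
            preds = classify_scores(test_scores[t], thr, spec)
            m = compute_metrics(confusion(preds.to_numpy(), test_y))
            rows.append(
                {"tool": t, "thresholds": kind, "threshold": thr,
                 **{f: getattr(m, f) for f in _METRIC_FIELDS}}
            )
    if panel is None:
        panel = sorted(tools, key=lambda t: -train_mcc[t])[:3]
    if len(panel) >= 2:
        preds = panel_predictions(test_scores, panel, registry, learned)
        m = compute_metrics(confusion(preds.to_numpy(), test_y))
        rows.append(
            {"tool": "+".join(panel), "thresholds": "optimized", "threshold": np.nan,
             **{f: getattr(m, f) for f in _METRIC_FIELDS}}
        )
    return pd.DataFrame(rows)


def score_vus(
    vus_scores: pd.DataFrame,
    registry: ToolRegistry,
    thresholds: Mapping[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify VUS records with every tool and summarise vote concordance.

    Returns the per-variant per-tool vote table and a summary with the
    pathogenic vote count, the number of tools with a score, and flags for
    fully concordant calls in either direction.
    """
    tools = [t for t in registry if t in vus_scores.columns and t in thresholds]
    votes = pd.DataFrame(
        {t: classify_scores(vus_scores[t], thresholds[t], registry[t]) for t in tools},
        index=vus_scores.index,
    )
    n_scored = (votes != "missing").sum(axis=1)
    n_path = (votes == PATHOGENIC).sum(axis=1)
    summary = pd.DataFrame(
        {
            "n_tools_scored": n_scored,
            "n_pathogenic_votes": n_path,
            "all_pathogenic": (n_path == n_scored) & (n_scored > 0),
            "all_benign": (n_path == 0) & (n_scored > 0),
        },
        index=vus_scores.index,
    )
    return votes, summary


def contamination_experiment(
    variants: pd.DataFrame,
    scores,
    spec: ToolSpec,
    fractions: Iterable[float] = (0.05, 0.10, 0.20),
    seeds: Iterable[int] = range(10),
    direction: str = "disease_to_neutral",
) -> pd.DataFrame:
    """Robustness of threshold optimisation to deliberate label noise.

    For each (fraction, seed) the disease/neutral labels of ``variants``
    are contaminated via :func:`genecalib.synthetic.contaminate`, the
    threshold is re-optimised on the contaminated labels, and metrics are
    recomputed against those contaminated labels.  The fraction-0 row
    reproduces the uncontaminated run, so threshold drift and MCC
    degradation can be read off directly.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    keep = variants["label"].isin([DISEASE, NEUTRAL]).to_numpy()
    base = variants.loc[keep].reset_index(drop=True)
    s = scores[keep].reset_index(drop=True)
    rows = []
    for fraction in fractions:
        for seed in seeds:
            contaminated, flipped = synthetic.contaminate(
                base, fraction, seed=seed, direction=direction
            )
            try:
                res = optimize_threshold(s, contaminated["label"], spec)
            except CalibrationError as exc:
                raise ValidationError(
                    f"contamination fraction {fraction} left a single-class dataset"
                ) from exc
            rows.append(
                {
                    "fraction": fraction,
                    "seed": seed,
                    "n_flipped": len(flipped),
                    "best_threshold": res.best_threshold,
                    **{m: getattr(res.best_metrics, m) for m in _METRIC_FIELDS},
                }
            )
    return pd.DataFrame(rows)
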