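"""End-to-end orchestration and report rendering.

``run_primary_analysis`` chains the full pipeline on a variant table and
score matrix: curation (deduplication + label assignment), per-tool
evaluation at default thresholds, gene-specific threshold optimisation,
majority-vote panel evaluation for the top tools, and cross-validation of
the best tool.  Every number rendered in a report table also appears at
full precision in a machine-readable JSON manifest; rendered percentages
are rounded to 0 decimal places and MCC to 2, and rerunning with the same
inputs and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import optimize_threshold
from .curation import annotate_domains, assign_labels, deduplicate
from .ensemble import combinations_table, evaluate_combinations
from .metrics import (
    DISEASE,
    NEUTRAL,
    classify_scores,
    compute_metrics,
    confusion,
    round_half_away,
)
from .registry import ToolRegistry, load_default_registry
from .validation import cross_validate

log = logging.getLogger(__name__)

_METRIC_FIELDS = ("sensitivity", "specificity", "accuracy", "ppv", "mcc")


@dataclass
class ReportBundle:
    """Everything one primary-analysis run produces."""

    default_metrics: pd.DataFrame
    optimized_metrics: pd.DataFrame
    combinations: pd.DataFrame
    cv_table: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def render_metrics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Report rendering: percentages at 0 dp, MCC at 2 dp."""
    out = df.copy()
    for col in ("sensitivity", "specificity", "accuracy", "ppv"):
        if col in out:
            out[col + "_pct"] = out[col].map(
                lambda v: round_half_away(100 * v) if pd.notna(v) else np.nan
            )
            del out[col]
    if "mcc" in out:
        out["mcc"] = out["mcc"].round(2)
    return out


def _tool_rows(scores, labels, registry, tools, thresholds) -> pd.DataFrame:
    rows = []
    for t in tools:
        spec = registry[t]
        preds = classify_scores(scores[t], thresholds[t], spec)
        cm = confusion(preds.to_numpy(), labels)
        m = compute_metrics(cm)
        rows.append(
            {
                "tool": t,
                "threshold": thresholds[t],
                **{f: getattr(m, f) for f in _METRIC_FIELDS},
                "n_evaluated": cm.total,
                "n_missing": cm.n_missing,
            }
        )
    return pd.DataFrame(rows)


def run_primary_analysis(
    variants: pd.DataFrame,
    scores: pd.DataFrame,
    registry: ToolRegistry | None = None,
    seed: int = 0,
    k: int = 5,
    policy: str = "exclude_conflicts",
    panel_sizes: Sequence[int] = (2, 3),
    top_n: int = 3,
    out_dir=None,
) -> ReportBundle:
    """Run curation, evaluation, optimisation, combination and CV.

    Panels are built from the ``top_n`` tools ranked by optimised MCC and
    evaluated at the optimised thresholds; cross-validation is run for the
    single best tool.  When ``out_dir`` is given, TSV reports and the JSON
    manifest are written there.
    """
    registry = registry or load_default_registry()
    variants, n_dup = deduplicate(variants)
    disease, neutral, vus, report = assign_labels(variants, policy=policy)
    labeled = pd.concat([disease, neutral], ignore_index=True)
    ids = labeled["variant_id"]
    missing_ids = [i for i in ids if i not in scores.index]
    if missing_ids:
        raise ValueError(
            f"{len(missing_ids)} curated variants have no score row "
            f"(first: {missing_ids[0]})"
        )
    sub = scores.loc[ids]
    labels = labeled["label"].to_numpy()
    tools = [t for t in registry if t in scores.columns]
    log.info(
        "primary analysis: %d disease / %d neutral / %d vus variants, %d tools",
        len(disease), len(neutral), len(vus), len(tools),
    )

    defaults = {t: registry[t].default_threshold for t in tools}
    default_df = _tool_rows(sub, labels, registry, tools, defaults)

    optimized: dict[str, float] = {}
    opt_rows = []
    for t in tools:
        res = optimize_threshold(sub[t], labels, registry[t])
        optimized[t] = res.best_threshold
        opt_rows.append(
            {
                "tool": t,
                "threshold": res.best_threshold,
                **{f: getattr(res.best_metrics, f) for f in _METRIC_FIELDS},
                "n_evaluated": res.best_metrics.n_pos + res.best_metrics.n_neg,
                "n_missing": len(sub) - (res.best_metrics.n_pos + res.best_metrics.n_neg),
            }
        )
    optimized_df = pd.DataFrame(opt_rows)

    top_tools = list(optimized_df.sort_values("mcc", ascending=False)["tool"].head(top_n))
    combos = evaluate_combinations(
        sub, labels, registry, optimized, panel_sizes=panel_sizes, tools=top_tools
    )
    combos_df = combinations_table(combos)

    best_tool = top_tools[0]
    cv = cross_validate(sub[best_tool], labels, registry[best_tool], k=k, seed=seed)
    cv_df = cv.table()

    manifest = {
        "seed": seed,
        "k": k,
        "policy": policy,
        "curation": report.to_dict(),
        "n_duplicates_removed": n_dup,
        "tools": tools,
        "default_thresholds": defaults,
        "optimized_thresholds": optimized,
        "top_tools": top_tools,
        "default_metrics": default_df.to_dict(orient="records"),
        "optimized_metrics": optimized_df.to_dict(orient="records"),
        "combinations": combos_df.to_dict(orient="records"),
        "cv": {
            "tool": cv.tool,
            "folds": cv_df.to_dict(orient="records"),
            "mean": cv.mean,
            "sd": cv.sd,
        },
    }
    bundle = ReportBundle(default_df, optimized_df, combos_df, cv_df, manifest)
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def write_report(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_metrics_table(bundle.default_metrics).to_csv(
        out / "default_metrics.tsv", sep="\t", index=False
    )
    render_metrics_table(bundle.optimized_metrics).to_csv(
        out / "optimized_metrics.tsv", sep="\t", index=False
    )
    render_metrics_table(bundle.combinations).to_csv(
        out / "combinations.tsv", sep="\t", index=False
    )
    render_metrics_table(bundle.cv_table).to_csv(
        out / "crossval.tsv", sep="\t", index=False
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def export_domain_counts(
    curated: pd.DataFrame,
    intervals: Mapping[str, tuple[int, int]],
    out_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lolliplot-style data export: per-residue and per-domain label counts.

    Returns ``(per_residue, per_domain)``; the per-residue frame has one
    row per (protein position, label) with its variant count, the data a
    lolliplot renders.  Plotting itself is out of scope.
    """
    tagged, per_domain = annotate_domains(curated, dict(intervals))
    with_pos = tagged.dropna(subset=["protein_pos"])
    per_residue = (
        with_pos.groupby(["protein_pos", "label"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    if out_path is not None:
        per_residue.to_csv(out_path, sep="\t", index=False)
    return per_residue, per_domain
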