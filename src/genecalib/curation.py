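"""Assembly of analysis-ready disease/neutral datasets from multi-source tables.

Curation mirrors the standard workflow for building a labeled benchmark of
missense variants from heterogeneous databases: records are deduplicated on
the genomic variant identifier (sources and assertions of merged duplicates
are unioned onto the survivor), then partitioned into a disease set
(pathogenic assertions or HGMD DM), a neutral set (benign assertions, or
presence only in population-scale resources such as gnomAD/BRAVO, taken as
"presumed benign" without an allele-frequency filter), and a VUS set that is
excluded from training labels but retained for downstream scoring.  A record
that is both clinically asserted pathogenic and present in a population
resource is contradictory; how it is resolved is a policy choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd

from .io import format_sources, parse_sources
from .metrics import DISEASE, NEUTRAL, VUS

log = logging.getLogger(__name__)

POPULATION_SOURCES = frozenset({"gnomad", "bravo"})
DISEASE_SOURCES = frozenset({"hgmd_dm"})

POLICIES = ("exclude_conflicts", "disease_wins", "neutral_wins")


class CurationError(ValueError):
    pass


@dataclass
class CurationReport:
    """Bookkeeping for one curation run; tallies always reconcile."""

    n_input: int = 0
    n_duplicates_removed: int = 0
    n_vus_excluded: int = 0
    n_conflicts_excluded: int = 0
    n_disease: int = 0
    n_neutral: int = 0
    per_source: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        total = (
            self.n_duplicates_removed + self.n_vus_excluded
            + self.n_conflicts_excluded + self.n_disease + self.n_neutral
        )
        if total != self.n_input:
            raise CurationError(
                f"curation tallies do not reconcile: {total} != {self.n_input}"
            )


def deduplicate(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """One record per variant_id; duplicate sources/assertions are merged.

    The first occurrence survives; the sources of later duplicates are
    unioned onto it and any distinct assertions are concatenated with
    ``"; "`` so no clinical claim is silently dropped.
    """
    if records["variant_id"].is_unique:
        return records.reset_index(drop=True), 0
    removed = 0
    rows = []
    for _, grp in records.groupby("variant_id", sort=False):
        survivor = grp.iloc[0].copy()
        if len(grp) > 1:
            removed += len(grp) - 1
            tags = frozenset().union(*(parse_sources(s) for s in grp["sources"]))
            survivor["sources"] = format_sources(tags)
            assertions = [a for a in dict.fromkeys(grp["assertion"]) if a]
            survivor["assertion"] = "; ".join(assertions)
            # any uncertain assertion, or any disease claim, dominates the label
            labels = set(grp["label"])
            if VUS in labels:
                survivor["label"] = VUS
            elif DISEASE in labels:
                survivor["label"] = DISEASE
        rows.append(survivor)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out, removed


def _resolve_label(label: str, sources: frozenset) -> str:
    """Resolve one deduplicated record to disease/neutral/vus/conflict.

    ``sources`` has already been vetted against the known-source vocabulary
    by :func:`genecalib.io.parse_sources`.
    """
    if "hgmd_dmq" in sources and label not in (DISEASE, NEUTRAL):
        return VUS
    if label == DISEASE or (not label and sources & DISEASE_SOURCES):
        if sources & POPULATION_SOURCES:
            return "conflict"
        return DISEASE
    if label == NEUTRAL:
        return NEUTRAL
    if label == VUS:
        return VUS
    # unlabeled: population-only presence is presumed benign; anything else
    # carrying a clinical source but no usable assertion stays uncertain
    if sources and sources <= POPULATION_SOURCES:
        return NEUTRAL
    return VUS


def assign_labels(
    records: pd.DataFrame, policy: str = "exclude_conflicts"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CurationReport]:
    """Partition deduplicated records into disease, neutral and VUS sets.

    Disease: asserted pathogenic (ClinVar/LOVD/PubMed/local) or HGMD DM.
    Neutral: asserted benign/likely benign, or present only in population
    resources (presumed benign).  VUS: uncertain assertions and HGMD DM?.
    Records both asserted pathogenic and present in a population resource
    are resolved per ``policy``: ``exclude_conflicts`` (default) drops and
    counts them; ``disease_wins`` / ``neutral_wins`` force a side.
    """
    if policy not in POLICIES:
        raise CurationError(f"unknown policy {policy!r}; choose from {POLICIES}")
    report = CurationReport(n_input=len(records))
    resolved = []
    for _, row in records.iterrows():
        sources = parse_sources(row["sources"])
        verdict = _resolve_label(row["label"], sources)
        if verdict == "conflict":
            if policy == "disease_wins":
                verdict = DISEASE
            elif policy == "neutral_wins":
                verdict = NEUTRAL
            else:
                log.info("excluding conflicted record %s", row["variant_id"])
        resolved.append(verdict)
        for tag in sources:
            report.per_source[tag] = report.per_source.get(tag, 0) + 1
    records = records.assign(label=resolved)
    disease = records[records["label"] == DISEASE].reset_index(drop=True)
    neutral = records[records["label"] == NEUTRAL].reset_index(drop=True)
    vus = records[records["label"] == VUS].reset_index(drop=True)
    report.n_disease = len(disease)
    report.n_neutral = len(neutral)
    report.n_vus_excluded = len(vus)
    report.n_conflicts_excluded = int((records["label"] == "conflict").sum())
    report.check()
    return disease, neutral, vus, report


def annotate_domains(
    records: pd.DataFrame,
    intervals: dict[str, tuple[int, int]] | Sequence[tuple[str, int, int]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag each record with the protein domain its residue falls in.

    ``intervals`` maps domain names to 1-based inclusive residue ranges
    (e.g. paired domain and homeodomain for a transcription factor);
    records outside every interval are tagged ``outside`` and records
    without a protein position ``unknown``.  Returns the tagged table and
    a (domain, label) count summary suitable for a lolliplot-style export.
    """
    if not isinstance(intervals, dict):
        intervals = {name: (lo, hi) for name, lo, hi in intervals}
    for name, (lo, hi) in intervals.items():
        if lo > hi or lo < 1:
            raise CurationError(f"domain {name}: bad interval ({lo}, {hi})")

    def tag(pp) -> str:
        if pd.isna(pp):
            return "unknown"
        for name, (lo, hi) in intervals.items():
            if lo <= pp <= hi:
                return name
        return "outside"

    tagged = records.assign(domain=records["protein_pos"].map(tag))
    counts = (
        tagged.groupby(["domain", "label"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return tagged, counts
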