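"""Readers and writers for variant tables and score matrices.

The native dialects are plain TSV.  A variant table has the fixed, ordered
columns ``variant_id, chrom, pos, ref, alt, protein_pos, aa_ref, aa_alt,
label, sources, assertion``; a score matrix is ``variant_id`` plus one
numeric column per tool, with missing scores encoded as an empty string or
``"."``.  External dialects are mapped onto the same in-memory model:

* ``clinvar_like`` / ``gnomad_like`` variant tables, where the clinical
  assertion text (or its absence, for population records) determines the
  label;
* ``dbnsfp_like`` score matrices, whose cells can carry semicolon-separated
  per-transcript values;
* ``alphamissense_like`` score TSVs with columns
  ``CHROM, POS, REF, ALT, protein_variant, am_pathogenicity, am_class``.

Coordinates are 1-based, VCF-style, GRCh38 only; tables on other builds
must be lifted over upstream.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

import numpy as np
import pandas as pd

from .registry import ASCENDING, ToolRegistry
from .metrics import DISEASE, NEUTRAL, VUS

log = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt",
    "protein_pos", "aa_ref", "aa_alt", "label", "sources", "assertion",
]

KNOWN_SOURCES = frozenset(
    {"gnomad", "clinvar", "lovd", "hgmd_dm", "hgmd_dmq", "pubmed", "local", "bravo"}
)

#: canonical protein length (residues) used for validation defaults
DEFAULT_PROTEIN_LENGTH = 422

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# label normalisation

_DISEASE_ASSERTIONS = ("pathogenic", "likely pathogenic", "dm")
_NEUTRAL_ASSERTIONS = ("benign", "likely benign", "presumed benign")
_VUS_ASSERTIONS = ("uncertain significance", "vus", "dm?", "uncertain")


def normalize_assertion(assertion: str) -> str | None:
    """Map free-text clinical assertions onto disease/neutral/vus.

    Returns ``None`` when the text matches no recognised vocabulary.
    ``likely pathogenic`` must be tested before ``pathogenic`` would match
    as a substring, hence exact comparison on the lowered, stripped text.
    """
    norm = str(assertion).strip().lower()
    if not norm or norm == "nan":
        return None
    if norm in _VUS_ASSERTIONS:
        return VUS
    if norm in _DISEASE_ASSERTIONS:
        return DISEASE
    if norm in _NEUTRAL_ASSERTIONS:
        return NEUTRAL
    return None


def parse_sources(cell) -> frozenset:
    """Parse a comma-separated sources cell into a tag set."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    tags = frozenset(t.strip() for t in str(cell).split(",") if t.strip())
    unknown = tags - KNOWN_SOURCES
    if unknown:
        raise FormatError(f"unknown source tag(s): {sorted(unknown)}")
    return tags


def format_sources(tags: Iterable[str]) -> str:
    return ",".join(sorted(tags))


# ---------------------------------------------------------------------------
# variant tables

def _validate_variant_rows(df: pd.DataFrame, protein_length: int) -> pd.DataFrame:
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not re.fullmatch(r"(chr)?[0-9XYM]+:\d+:[ACGT]:[ACGT]", str(row["variant_id"])):
            problems.append(f"line {line}: malformed variant_id {row['variant_id']!r}")
        if not (pd.isna(row["pos"]) or row["pos"] >= 1):
            problems.append(f"line {line}: pos must be >= 1")
        pp = row["protein_pos"]
        if not pd.isna(pp) and not (1 <= pp <= protein_length):
            problems.append(
                f"line {line}: protein_pos {int(pp)} outside [1, {protein_length}]"
            )
        if row["label"] not in (DISEASE, NEUTRAL, VUS, ""):
            problems.append(f"line {line}: unknown label {row['label']!r}")
        try:
            parse_sources(row["sources"])
        except FormatError as exc:
            problems.append(f"line {line} (column sources): {exc}")
    if problems:
        raise FormatError("variant table validation failed:\n" + "\n".join(problems))
    return df


def _finalize_variant_table(df: pd.DataFrame, protein_length: int) -> pd.DataFrame:
    df = df.copy()
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["protein_pos"] = pd.to_numeric(df["protein_pos"], errors="coerce").astype("Int64")
    for col in ("chrom", "ref", "alt", "aa_ref", "aa_alt", "label", "sources", "assertion"):
        df[col] = df[col].fillna("").astype(str).replace("nan", "")
    # DM? and uncertain assertions force the vus label even if mislabeled upstream
    asserted = df["assertion"].map(normalize_assertion)
    df.loc[asserted == VUS, "label"] = VUS
    _validate_variant_rows(df, protein_length)
    dup = df["variant_id"].duplicated()
    if dup.any():
        log.warning(
            "variant table contains %d duplicate variant_id rows; "
            "deduplicate during curation", int(dup.sum()),
        )
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def read_variant_table(
    path, dialect: str = "native", protein_length: int = DEFAULT_PROTEIN_LENGTH
) -> pd.DataFrame:
    """Read a variant table TSV into the native columns.

    ``native`` expects the exact native columns.  ``clinvar_like`` and
    ``gnomad_like`` expect ``chrom, pos, ref, alt`` plus, for
    clinvar_like, a ``clinical_significance`` column that is normalised to
    a label ("Pathogenic"/"Likely pathogenic" -> disease, "Benign"/"Likely
    benign" -> neutral, "Uncertain significance"/"DM?" -> vus); gnomad_like
    rows are unlabeled population records tagged with source ``gnomad``.
    """
    if dialect not in ("native", "clinvar_like", "gnomad_like"):
        raise FormatError(f"unknown variant-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if dialect == "native":
        missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    else:
        base = ["chrom", "pos", "ref", "alt"]
        missing = [c for c in base if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        out = pd.DataFrame()
        out["chrom"] = df["chrom"]
        out["pos"] = df["pos"]
        out["ref"] = df["ref"]
        out["alt"] = df["alt"]
        out["variant_id"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ":" + df["alt"]
        )
        for col in ("protein_pos", "aa_ref", "aa_alt"):
            out[col] = df.get(col, np.nan)
        if dialect == "clinvar_like":
            if "clinical_significance" not in df.columns:
                raise FormatError(f"{path}: clinvar_like requires clinical_significance")
            out["assertion"] = df["clinical_significance"]
            out["label"] = df["clinical_significance"].map(
                lambda a: normalize_assertion(a) or ""
            )
            out["sources"] = "clinvar"
        else:  # gnomad_like: population records, no clinical assertion
            out["assertion"] = ""
            out["label"] = ""
            out["sources"] = "gnomad"
        df = out
    return _finalize_variant_table(df, protein_length)


def write_variant_table(df: pd.DataFrame, path) -> None:
    """Write the native variant-table TSV (lossless round trip)."""
    out = df[VARIANT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# score matrices

def _reduce_multiscore(cell: str, ascending: bool, transcript_index: int | None) -> float:
    parts = [p.strip() for p in str(cell).split(";")]
    if transcript_index is not None and transcript_index < len(parts):
        parts = [parts[transcript_index]]
    vals = []
    for p in parts:
        try:
            vals.append(float(p))
        except ValueError:
            continue
    if not vals:
        return np.nan
    # maximum-pathogenicity reduction: max for ascending tools, min for descending
    return max(vals) if ascending else min(vals)


def read_score_matrix(
    path,
    registry: ToolRegistry,
    dialect: str = "native",
    transcript_index: int | None = None,
) -> pd.DataFrame:
    """Read a score matrix keyed by variant_id, one float column per tool.

    Unknown tool columns are dropped with a warning; non-numeric cells
    become missing (NaN).  For ``dbnsfp_like`` input, semicolon-separated
    multi-transcript cells reduce to the configured transcript's value
    when ``transcript_index`` is given, else to the maximum-pathogenicity
    value under the tool's direction.  ``alphamissense_like`` input is a
    single-tool extract keyed by genomic coordinates.
    """
    if dialect not in ("native", "dbnsfp_like", "alphamissense_like"):
        raise FormatError(f"unknown score-matrix dialect {dialect!r}")
    if dialect == "alphamissense_like":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = ["CHROM", "POS", "REF", "ALT", "am_pathogenicity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        idx = (
            df["CHROM"].str.removeprefix("chr") + ":" + df["POS"].astype(str)
            + ":" + df["REF"] + ":" + df["ALT"]
        )
        scores = pd.to_numeric(df["am_pathogenicity"], errors="coerce")
        return pd.DataFrame({"AlphaMissense": scores.values}, index=pd.Index(idx, name="variant_id"))

    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=["", "."]
    )
    if "variant_id" not in df.columns:
        raise FormatError(f"{path}: missing variant_id column")
    df = df.set_index("variant_id")
    known = [c for c in df.columns if c in registry]
    unknown = [c for c in df.columns if c not in registry]
    if unknown:
        log.warning("ignoring unknown score column(s): %s", unknown)
    if not known:
        raise FormatError(f"{path}: no recognized score column")
    out = pd.DataFrame(index=df.index)
    for tool in known:
        col = df[tool]
        if dialect == "dbnsfp_like":
            ascending = registry[tool].direction == ASCENDING
            out[tool] = col.map(
                lambda c: np.nan if pd.isna(c)
                else _reduce_multiscore(c, ascending, transcript_index)
            )
        else:
            out[tool] = pd.to_numeric(col, errors="coerce")
    return out.astype(float)


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    """Write the native score-matrix TSV; missing cells become '.'."""
    out = scores.copy()
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t", na_rep=".")
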