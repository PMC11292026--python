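"""Synthetic labeled variant sets with correlated per-tool scores.

The generator emulates the statistical structure of a curated missense
benchmark for a single gene: two labeled classes (defaults 167 disease / 74
neutral, the primary-analysis class sizes), optional VUS records that are
scored but never used for training, class-conditional per-tool score
distributions, inter-tool correlation, missing scores, and optional label
contamination.

Scores are drawn through a Gaussian copula: each variant carries a shared
standard-normal liability mixed with tool-specific noise
(``w = sqrt(rho) * z + sqrt(1 - rho) * e``), and the resulting uniform
quantile is pushed through the tool's class-conditional marginal (a Beta
rescaled to the tool's score range, or a Normal for unbounded scores).
Marginals are therefore exact while tools correlate at strength ``rho``.
For descending-direction tools (SIFT4G) the quantile is reflected so the
class-conditional ordering reverses: disease variants score *low*.

Everything is driven by a single seed; identical config + seed reproduces
identical tables byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import VARIANT_COLUMNS
from .metrics import DISEASE, NEUTRAL, VUS, round_half_away
from .registry import DESCENDING, ToolRegistry, load_default_registry

_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Dist:
    """A class-conditional score distribution for one tool.

    ``kind="beta"`` uses shape parameters ``a``/``b`` rescaled onto the
    tool's declared score range; ``kind="normal"`` uses ``mean``/``sd``
    (for unbounded scores such as Eigen raw).
    """

    kind: str = "beta"
    a: float = 8.0
    b: float = 2.0
    mean: float = 0.0
    sd: float = 1.0

    def validate(self, tool: str) -> None:
        if self.kind not in ("beta", "normal"):
            raise ConfigurationError(f"{tool}: unknown distribution kind {self.kind!r}")
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ConfigurationError(
                f"{tool}: Beta shape parameters must be positive, got a={self.a}, b={self.b}"
            )
        if self.kind == "normal" and self.sd <= 0:
            raise ConfigurationError(f"{tool}: Normal sd must be positive, got {self.sd}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "beta":
            return stats.beta.ppf(u, self.a, self.b)
        return stats.norm.ppf(u, loc=self.mean, scale=self.sd)

    def flipped(self) -> "Dist":
        """Mirror the distribution (used for descending-direction tools)."""
        if self.kind == "beta":
            return replace(self, a=self.b, b=self.a)
        return replace(self, mean=-self.mean)


@dataclass
class SyntheticConfig:
    """The stated world of the generator.

    Defaults reproduce the primary-analysis conditions: 167 disease and 74
    neutral variants on a 422-residue protein whose pathogenic variants
    cluster in two DNA-binding domains (paired domain 4-130, homeodomain
    210-269), scored by the ten registry tools with well-separated
    class-conditional Beta(8,2) / Beta(2,8) score distributions, moderate
    inter-tool correlation, and a low missing-score rate.
    """

    n_disease: int = 167
    n_neutral: int = 74
    n_vus: int = 0
    tools: tuple[str, ...] = ()
    disease_score_dist: Mapping[str, Dist] = field(default_factory=dict)
    neutral_score_dist: Mapping[str, Dist] = field(default_factory=dict)
    inter_tool_correlation: float = 0.5
    missing_rate: float = 0.02
    contamination_fraction: float = 0.0
    contamination_direction: str = "disease_to_neutral"
    protein_length: int = 422
    domain_intervals: tuple[tuple[int, int], ...] = ((4, 130), (210, 269))
    domain_enrichment: float = 0.9
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load a config from a JSON or YAML file.

        Per-tool distributions are given as mappings, e.g.
        ``disease_score_dist: {REVEL: {kind: beta, a: 8, b: 2}}``.
        """
        import yaml  # YAML is a JSON superset, one loader covers both

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("disease_score_dist", "neutral_score_dist"):
            if key in data:
                data[key] = {t: Dist(**d) for t, d in data[key].items()}
        if "tools" in data:
            data["tools"] = tuple(data["tools"])
        if "domain_intervals" in data:
            data["domain_intervals"] = tuple(
                (int(lo), int(hi)) for lo, hi in data["domain_intervals"]
            )
        return cls(**data)

    def resolved(self, registry: ToolRegistry) -> "SyntheticConfig":
        """Fill tool list and per-tool distributions from the registry."""
        tools = self.tools or tuple(registry.tools)
        ddist, ndist = dict(self.disease_score_dist), dict(self.neutral_score_dist)
        for t in tools:
            if t not in registry:
                raise ConfigurationError(f"tool {t!r} not in registry")
            bounded = registry[t].bounded
            ddist.setdefault(t, Dist("beta", 8, 2) if bounded else Dist("normal", mean=1.0))
            ndist.setdefault(t, Dist("beta", 2, 8) if bounded else Dist("normal", mean=-1.0))
        return replace(
            self, tools=tools, disease_score_dist=ddist, neutral_score_dist=ndist
        )

    def validate(self, registry: ToolRegistry) -> None:
        for name, p in (
            ("inter_tool_correlation", self.inter_tool_correlation),
            ("missing_rate", self.missing_rate),
            ("contamination_fraction", self.contamination_fraction),
            ("domain_enrichment", self.domain_enrichment),
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if min(self.n_disease, self.n_neutral, self.n_vus) < 0:
            raise ConfigurationError("class sizes must be non-negative")
        for lo, hi in self.domain_intervals:
            if not (1 <= lo <= hi <= self.protein_length):
                raise ConfigurationError(f"bad domain interval ({lo}, {hi})")
        for t in self.tools:
            self.disease_score_dist[t].validate(t)
            self.neutral_score_dist[t].validate(t)
            spec = registry[t]
            for d in (self.disease_score_dist[t], self.neutral_score_dist[t]):
                if d.kind == "normal" and spec.bounded:
                    raise ConfigurationError(
                        f"{t}: Normal scores on a bounded tool would leave its range"
                    )


def _draw_positions(rng, n: int, config: SyntheticConfig, enrich: bool) -> np.ndarray:
    """Protein positions; disease positions fall in a domain w.p. enrichment."""
    L = config.protein_length
    intervals = config.domain_intervals
    inside = np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in intervals]
    ) if intervals else np.arange(1, L + 1)
    outside = np.setdiff1d(np.arange(1, L + 1), inside)
    if not enrich or len(outside) == 0 or len(inside) == 0:
        return rng.integers(1, L + 1, size=n)
    in_domain = rng.random(n) < config.domain_enrichment
    pos = np.empty(n, dtype=int)
    pos[in_domain] = rng.choice(inside, size=int(in_domain.sum()))
    pos[~in_domain] = rng.choice(outside, size=int((~in_domain).sum()))
    return pos


def _variant_table(rng, config: SyntheticConfig) -> pd.DataFrame:
    n = config.n_disease + config.n_neutral + config.n_vus
    labels = np.array(
        [DISEASE] * config.n_disease + [NEUTRAL] * config.n_neutral + [VUS] * config.n_vus,
        dtype=object,
    )
    pos = 31_780_000 + rng.choice(200_000, size=n, replace=False)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref, alt = bases[ref_i], bases[alt_i]
    ppos = np.empty(n, dtype=int)
    dis = labels == DISEASE
    ppos[dis] = _draw_positions(rng, int(dis.sum()), config, enrich=True)
    ppos[~dis] = _draw_positions(rng, int((~dis).sum()), config, enrich=False)
    aa = np.array(list(_AA))
    aa_ref_i = rng.integers(0, len(aa), size=n)
    aa_alt_i = (aa_ref_i + rng.integers(1, len(aa), size=n)) % len(aa)
    source = np.where(dis, rng.choice(["clinvar", "hgmd_dm", "lovd"], size=n), "gnomad")
    source[labels == VUS] = "clinvar"
    assertion = np.select(
        [labels == DISEASE, labels == VUS], ["Pathogenic", "Uncertain significance"], ""
    )
    df = pd.DataFrame(
        {
            "variant_id": [f"11:{p}:{r}:{a}" for p, r, a in zip(pos, ref, alt)],
            "chrom": "11",
            "pos": pd.array(pos, dtype="Int64"),
            "ref": ref,
            "alt": alt,
            "protein_pos": pd.array(ppos, dtype="Int64"),
            "aa_ref": aa[aa_ref_i],
            "aa_alt": aa[aa_alt_i],
            "label": labels,
            "sources": source,
            "assertion": assertion,
        }
    )
    return df[VARIANT_COLUMNS]


def _score_matrix(
    rng, variants: pd.DataFrame, config: SyntheticConfig, registry: ToolRegistry
) -> pd.DataFrame:
    n = len(variants)
    rho = config.inter_tool_correlation
    z = rng.standard_normal(n)  # shared liability per variant
    labels = variants["label"].to_numpy()
    # VUS are scored as a coin-flip mixture of the two classes
    vus_as_disease = rng.random(n) < 0.5
    use_disease = (labels == DISEASE) | ((labels == VUS) & vus_as_disease)
    out = {}
    for tool in config.tools:
        e = rng.standard_normal(n)
        u = stats.norm.cdf(np.sqrt(rho) * z + np.sqrt(1 - rho) * e)
        x = np.empty(n)
        dd = config.disease_score_dist[tool]
        nd = config.neutral_score_dist[tool]
        x[use_disease] = dd.ppf(u[use_disease])
        x[~use_disease] = nd.ppf(u[~use_disease])
        spec = registry[tool]
        if spec.direction == DESCENDING:
            # config dists live on the "pathogenicity" scale; reflecting the
            # draw reverses the class-conditional ordering so disease scores low
            x = 1.0 - x if spec.bounded else -x
        if spec.bounded:
            x = spec.score_min + (spec.score_max - spec.score_min) * x
        if config.missing_rate > 0:
            x[rng.random(n) < config.missing_rate] = np.nan
        out[tool] = x
    return pd.DataFrame(out, index=pd.Index(variants["variant_id"], name="variant_id"))


def generate_dataset(
    config: SyntheticConfig, registry: ToolRegistry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a labeled variant table and matched score matrix.

    Returns ``(variants, scores)``: the variant table in the native
    columns and a float score matrix indexed by ``variant_id``.  When
    ``config.contamination_fraction`` is positive the returned labels are
    contaminated via :func:`contaminate` using a seed derived from the
    config seed.
    """
    registry = registry or load_default_registry()
    config = config.resolved(registry)
    config.validate(registry)
    rng = np.random.default_rng(config.seed)
    variants = _variant_table(rng, config)
    scores = _score_matrix(rng, variants, config, registry)
    if config.contamination_fraction > 0:
        variants, _ = contaminate(
            variants,
            config.contamination_fraction,
            seed=config.seed + 1,
            direction=config.contamination_direction,
        )
    return variants, scores


def contaminate(
    variants: pd.DataFrame,
    fraction: float,
    seed: int,
    direction: str = "disease_to_neutral",
) -> tuple[pd.DataFrame, list[str]]:
    """Relabel a seeded random fraction of one class, modelling label noise.

    Exactly ``round(fraction * n_source_class)`` records (halves away from
    zero) are drawn without replacement and flipped to the other label;
    every other field is untouched.  Default direction flips disease
    records into the neutral pool, modelling pathogenic variants hiding
    among presumed-benign population records.  Returns the new table and
    the flipped variant ids.
    """
    if not 0 <= fraction <= 1:
        raise ConfigurationError(f"contamination fraction must lie in [0, 1], got {fraction}")
    if direction not in ("disease_to_neutral", "neutral_to_disease"):
        raise ConfigurationError(f"unknown contamination direction {direction!r}")
    src, dst = (DISEASE, NEUTRAL) if direction == "disease_to_neutral" else (NEUTRAL, DISEASE)
    out = variants.copy()
    pool = out.index[out["label"] == src].to_numpy()
    n_flip = round_half_away(fraction * len(pool))
    rng = np.random.default_rng(seed)
    flip = rng.choice(pool, size=n_flip, replace=False) if n_flip else np.array([], dtype=int)
    out.loc[flip, "label"] = dst
    flipped_ids = out.loc[flip, "variant_id"].tolist()
    return out, flipped_ids
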