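"""Tool registry: score semantics of the missense pathogenicity predictors.

Each predictor is described by a :class:`ToolSpec` carrying its score
direction (whether high scores mean pathogenic), its comparison operator
(whether a score exactly at the threshold is called pathogenic), the
developer-recommended default threshold, and the score bounds when the
score is bounded.

The packaged default registry covers the ten tools commonly benchmarked
for Mendelian missense interpretation: AlphaMissense, BayesDel (AddAF),
CADD (phred), ClinPred, Eigen (raw, coding), MutPred2, PolyPhen-2
(HumVar), REVEL, SIFT4G and VEST4.  SIFT4G is the single
descending-direction tool: low scores are deleterious.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

ASCENDING = "ascending"
DESCENDING = "descending"
STRICT = "strict"
INCLUSIVE = "inclusive"


class RegistryError(ValueError):
    """Raised for malformed tool specifications or registries."""


@dataclass(frozen=True)
class ToolSpec:
    """Score semantics of one predictor.

    Parameters
    ----------
    name:
        Tool identifier, unique within a registry.
    direction:
        ``"ascending"`` if higher scores indicate pathogenicity,
        ``"descending"`` if lower scores do (SIFT4G).
    comparison:
        ``"inclusive"`` if a score exactly equal to the threshold is
        called pathogenic, ``"strict"`` otherwise.
    default_threshold:
        The developer-set cut-off separating predicted pathogenic from
        predicted benign.
    score_min, score_max:
        Score bounds, or ``None`` when unbounded (Eigen raw).
    """

    name: str
    direction: str
    comparison: str
    default_threshold: float
    score_min: float | None = None
    score_max: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (ASCENDING, DESCENDING):
            raise RegistryError(
                f"{self.name}: direction must be 'ascending' or 'descending', "
                f"got {self.direction!r}"
            )
        if self.comparison not in (STRICT, INCLUSIVE):
            raise RegistryError(
                f"{self.name}: comparison must be 'strict' or 'inclusive', "
                f"got {self.comparison!r}"
            )
        if self.bounded and not (self.score_min <= self.default_threshold <= self.score_max):
            raise RegistryError(
                f"{self.name}: default threshold {self.default_threshold} outside "
                f"score range [{self.score_min}, {self.score_max}]"
            )

    @property
    def bounded(self) -> bool:
        return self.score_min is not None and self.score_max is not None

    def mirrored(self) -> "ToolSpec":
        """The same classifier expressed on negated scores.

        Negating scores and threshold while flipping the direction flag
        yields a spec that classifies every variant identically; useful
        for symmetry checks.
        """
        return ToolSpec(
            name=self.name,
            direction=DESCENDING if self.direction == ASCENDING else ASCENDING,
            comparison=self.comparison,
            default_threshold=-self.default_threshold,
            score_min=None if self.score_max is None else -self.score_max,
            score_max=None if self.score_min is None else -self.score_min,
        )


class ToolRegistry(Mapping[str, ToolSpec]):
    """An ordered, name-keyed collection of :class:`ToolSpec`."""

    def __init__(self, specs: Iterable[ToolSpec]):
        self._specs: dict[str, ToolSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise RegistryError(f"duplicate registry entry for tool {spec.name!r}")
            self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> ToolSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def tools(self) -> list[str]:
        return list(self._specs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self._specs.values()], fh, indent=2)
            fh.write("\n")


# Default thresholds follow each developer's recommendation; the BayesDel
# AddAF cut-off 0.0692655 is the published AddAF convention.
_DEFAULT_SPECS = (
    ToolSpec("AlphaMissense", ASCENDING, INCLUSIVE, 0.564, 0.0, 1.0),
    ToolSpec("BayesDel", ASCENDING, STRICT, 0.0692655, -1.3, 0.76),
    ToolSpec("CADD", ASCENDING, STRICT, 20.0, 0.0, 99.0),
    ToolSpec("ClinPred", ASCENDING, STRICT, 0.5, 0.0, 1.0),
    ToolSpec("Eigen", ASCENDING, STRICT, 0.0, None, None),
    ToolSpec("MutPred2", ASCENDING, STRICT, 0.5, 0.0, 1.0),
    ToolSpec("PolyPhen2", ASCENDING, INCLUSIVE, 0.447, 0.0, 1.0),
    ToolSpec("REVEL", ASCENDING, STRICT, 0.5, 0.0, 1.0),
    ToolSpec("SIFT4G", DESCENDING, INCLUSIVE, 0.05, 0.0, 1.0),
    ToolSpec("VEST4", ASCENDING, STRICT, 0.5, 0.0, 1.0),
)


def load_default_registry() -> ToolRegistry:
    """The packaged ten-tool registry with default thresholds."""
    log.info(
        "loaded default registry (10 tools); BayesDel AddAF default threshold "
        "taken as 0.0692655 (published AddAF convention)"
    )
    return ToolRegistry(_DEFAULT_SPECS)


def load_registry(path) -> ToolRegistry:
    """Read a registry from a JSON file (list of ToolSpec objects)."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise RegistryError(f"{path}: registry JSON must be a list of tool objects")
    return ToolRegistry(ToolSpec(**entry) for entry in raw)
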