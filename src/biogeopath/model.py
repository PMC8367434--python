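"""Core domain types shared across the pipeline.

The pipeline moves through four representations: raw homology-search hits
(:class:`HmmHit`) are filtered into per-gene annotations; per-gene read counts
or coverages (:class:`CountRecord`) become length-normalized TPM values; gene
TPM aggregates into per-family profiles (:class:`AbundanceProfile`); and
pathway definitions (:class:`PathwayDefinition`) convert family profiles into
pathway relative abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ScoreType(Enum):
    """Which hmmsearch score a family's threshold applies to."""

    FULL = "full"
    DOMAIN = "domain"


@dataclass(frozen=True)
class HmmHit:
    """One row of an HMMER3 tabular search result.

    ``full_score`` is the full-sequence bit score; ``dom_score`` is the best
    single-domain bit score (tblout) or the per-domain score (domtblout).
    """

    gene_id: str
    family_id: str
    full_score: float
    dom_score: float
    evalue: float

    def __post_init__(self) -> None:
        if not self.gene_id or not self.family_id:
            raise ValueError("gene_id and family_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"E-value must be >= 0, got {self.evalue}")
        for name in ("full_score", "dom_score"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class KoThresholdEntry:
    """A KO family's adaptive bit-score cutoff, in the ko_list dialect.

    Some KO entries ship without a usable threshold (marked ``-`` upstream);
    those are retained with ``threshold=None`` and fall back to an E-value
    ceiling during annotation.
    """

    family_id: str
    threshold: Optional[float]
    score_type: Optional[ScoreType]
    definition: str = ""

    @property
    def has_threshold(self) -> bool:
        return self.threshold is not None

    def __post_init__(self) -> None:
        if self.threshold is not None and not math.isfinite(self.threshold):
            raise ValueError(f"threshold must be finite, got {self.threshold}")


@dataclass(frozen=True)
class CustomFamilyCutoff:
    """E-value ceiling for one custom (non-KO) gene family."""

    family_id: str
    max_evalue: float

    def __post_init__(self) -> None:
        if not self.max_evalue > 0:
            raise ValueError(f"max_evalue must be > 0, got {self.max_evalue}")


class CountMode(Enum):
    READS = "reads"
    COVERAGE = "coverage"


@dataclass(frozen=True)
class CountRecord:
    """Per-gene quantification input: mapped-read count or average coverage.

    Exactly one of ``count`` / ``coverage`` is populated; ``mode`` records
    which. Coverage is per-base average depth, already proportional to
    reads/length.
    """

    gene_id: str
    length: int
    count: Optional[float] = None
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene length must be > 0, got {self.length}")
        if (self.count is None) == (self.coverage is None):
            raise ValueError("exactly one of count/coverage must be set")
        v = self.count if self.count is not None else self.coverage
        if v < 0:
            raise ValueError(f"count/coverage must be >= 0, got {v}")

    @property
    def mode(self) -> CountMode:
        return CountMode.READS if self.count is not None else CountMode.COVERAGE

    @property
    def rate(self) -> float:
        """Length-normalized signal: reads/length, or coverage directly."""
        if self.count is not None:
            return self.count / self.length
        return float(self.coverage)


@dataclass(frozen=True)
class GeneTpm:
    """A gene's TPM-scale relative abundance within one sample."""

    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"tpm must be >= 0, got {self.tpm}")


@dataclass
class GeneAnnotation:
    """All accepted family labels for one gene (may be empty).

    A gene accepted against several families keeps every label; there is no
    best-hit resolution anywhere in the pipeline.
    """

    gene_id: str
    families: set[str] = field(default_factory=set)


@dataclass
class AbundanceProfile:
    """Per-sample map from family id to TPM-scale relative abundance.

    Families absent from the map are semantically zero.
    """

    sample_id: str
    abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.abundance.items() if v < 0}
        if bad:
            raise ValueError(f"negative abundances: {bad}")

    def get(self, family_id: str) -> float:
        return self.abundance.get(family_id, 0.0)


class Cycle(Enum):
    CARBON = "carbon"
    NITROGEN = "nitrogen"
    SULFUR = "sulfur"
    DMSP = "DMSP"
    OTHER = "other"


@dataclass(frozen=True)
class Component:
    """One required step of a route: a set of interchangeable families.

    Alternatives within a step (e.g. the eight DMSP lyases) pool by sum.
    """

    families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("component must list at least one family")

    @classmethod
    def of(cls, *families: str) -> "Component":
        return cls(frozenset(families))


@dataclass(frozen=True)
class Route:
    """One alternative enzyme set accomplishing a pathway.

    A route's abundance is the arithmetic mean over its components; an
    undetected component contributes 0 to the numerator while the divisor
    stays at the number of essential components.
    """

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("route must have at least one component")

    @property
    def n(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class PathwayDefinition:
    """A biogeochemical pathway as alternative routes of required components."""

    pathway_id: str
    display_name: str
    cycle: Cycle
    routes: tuple[Route, ...]

    def __post_init__(self) -> None:
        if not self.routes:
            raise ValueError(f"pathway {self.pathway_id!r} has no routes")

    def families(self) -> set[str]:
        out: set[str] = set()
        for route in self.routes:
            for comp in route.components:
                out |= comp.families
        return out
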