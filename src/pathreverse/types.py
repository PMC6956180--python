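"""Core value types shared across the pipeline.

Tabular data (differential-expression tables, signature matrices,
enrichment results) live in pandas objects; the small structured records
around them are dataclasses defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import ConfigError, EmptyInputError

UP = "UP"
DOWN = "DOWN"

#: Recognised clinical development phases, most to least advanced.
CLINICAL_PHASES = (
    "Launched",
    "Phase 3",
    "Phase 2/Phase 3",
    "Phase 2",
    "Phase 1",
    "Preclinical",
    "unknown",
)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG pathway used purely as membership)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """An ordered mapping of unique set names to :class:`GeneSet`."""

    def __init__(self, sets: Mapping[str, GeneSet] | list[GeneSet]):
        if isinstance(sets, Mapping):
            sets = list(sets.values())
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in self._sets:
                raise ConfigError(f"duplicate gene set name {gs.name!r}")
            self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs.members
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets


@dataclass
class RankedSignature:
    """An ordered gene list with per-gene statistic values.

    Genes are sorted by ``stats`` descending; positive statistics mean
    up-regulation under the condition the signature describes. ``stat_kind``
    records the provenance of the statistic: moderated t values for disease
    contrasts, z-scores for L1000-style drug signatures, amplitudes for
    CMap-style ones.
    """

    signature_id: str
    genes: list[str]
    stats: np.ndarray
    stat_kind: str = "t"

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ConfigError("genes and stats must have equal length")
        if len(self.genes) == 0:
            raise EmptyInputError("ranked signature is empty")
        if not np.all(np.isfinite(self.stats)):
            raise ConfigError("ranked statistics must be finite")
        if np.any(np.diff(self.stats) > 0):
            raise ConfigError("stats must be sorted descending")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("ranked genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def index(self) -> dict[str, int]:
        """Gene symbol -> rank position (0 = most up-regulated)."""
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class SignatureMetadata:
    """Per-signature annotation for a drug perturbation profile.

    ``quality`` is a reproducibility score in [-1, 1] (the L1000
    distil_cc_q75 statistic); ``None`` means the score is unavailable.
    """

    signature_id: str
    compound: str
    cell_line: str = ""
    dose: str = ""
    time: str = ""
    quality: float | None = None
    clinical_phase: str = "unknown"
    repurposeable: bool = False

    def __post_init__(self) -> None:
        if self.quality is not None and not -1.0 <= self.quality <= 1.0:
            raise ConfigError(
                f"quality for {self.signature_id!r} outside [-1, 1]: {self.quality}"
            )
        if self.clinical_phase not in CLINICAL_PHASES:
            raise ConfigError(
                f"unknown clinical phase {self.clinical_phase!r} "
                f"for {self.signature_id!r}"
            )


@dataclass(frozen=True)
class CellTypeMarkers:
    """A marker gene list for one cell type, from one source compilation."""

    cell_type: str
    source_label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"marker list for {self.cell_type!r} is empty")


@dataclass(frozen=True)
class ReversalQuery:
    """Pathways with desired perturbation directions.

    A compound matches the query when its direction profile calls every
    queried pathway significant in exactly the desired direction.
    """

    targets: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ConfigError("reversal query must name at least one pathway")
        bad = {d for d in self.targets.values() if d not in (UP, DOWN)}
        if bad:
            raise ConfigError(f"invalid directions in query: {sorted(bad)}")
        object.__setattr__(self, "targets", dict(self.targets))

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def aud(cls) -> "ReversalQuery":
        """The alcohol-use-disorder reversal query: oppose the pathway
        profile seen in postmortem AUD brain (four up-regulated pathways to
        push down, one down-regulated pathway to push up)."""
        return cls(
            {
                "Complement_and_coagulation_cascades": DOWN,
                "Focal_adhesion": DOWN,
                "Mapk_signaling_pathway": DOWN,
                "Systemic_lupus_erythematosus": DOWN,
                "Oxidative_phosphorylation": UP,
            }
        )


@dataclass
class DirectionProfile:
    """Significant pathway calls for one signature: pathway -> UP/DOWN."""

    signature_id: str
    calls: dict[str, str] = field(default_factory=dict)

    def matches(self, query: ReversalQuery) -> bool:
        return all(self.calls.get(p) == d for p, d in query.targets.items())
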