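"""Core data model for the site suitability model (SSM).

The SSM scores rural communities as candidate secondary palliative care
hubs.  Everything downstream operates on the types defined here: a
:class:`Dataset` bundles population centres, census-style population
blocks, a drive-time road network and health facilities, all located in
one shared planar metric coordinate system (metres).  The package never
reprojects coordinates; inputs are assumed already projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "ValidationError",
    "ReadinessFlags",
    "PopulationCentre",
    "PopulationBlock",
    "Facility",
    "PcixSubscores",
    "ComponentScores",
    "SSMResult",
    "Dataset",
]


class ValidationError(ValueError):
    """Raised when an input violates the data model's contracts."""


Coordinate = Tuple[float, float]


@dataclass(frozen=True)
class ReadinessFlags:
    """Five binary community-readiness indicators, each worth 0.2.

    ``fp_adequate`` (adequate family-physician supply) may be ``None``,
    meaning "not supplied: derive it from the physician-to-population
    ratio".  The other four flags are always concrete booleans.
    """

    aware: bool = False
    education: bool = False
    telemedicine: bool = False
    fp_adequate: Optional[bool] = None
    momentum: bool = False

    def resolved(self, fp_adequate: bool) -> "ReadinessFlags":
        """Return a copy with ``fp_adequate`` filled in if it was absent."""
        if self.fp_adequate is not None:
            return self
        return ReadinessFlags(
            aware=self.aware,
            education=self.education,
            telemedicine=self.telemedicine,
            fp_adequate=fp_adequate,
            momentum=self.momentum,
        )


@dataclass
class PopulationCentre:
    """A settlement that may become a palliative-care hub candidate."""

    community_id: str
    name: str
    location: Coordinate
    population: float
    pct_over75: float = 0.0
    pct_female: float = 0.0
    pct_alone: float = 0.0
    fp_count: int = 0
    vandix_indicators: Tuple[float, ...] = (0.0,) * 7
    readiness: ReadinessFlags = field(default_factory=ReadinessFlags)

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValidationError(
                f"centre {self.community_id!r}: population must be >= 0, "
                f"got {self.population}"
            )
        for label, p in (
            ("pct_over75", self.pct_over75),
            ("pct_female", self.pct_female),
            ("pct_alone", self.pct_alone),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"centre {self.community_id!r}: {label} must lie in "
                    f"[0, 1], got {p}"
                )
        if self.fp_count < 0:
            raise ValidationError(
                f"centre {self.community_id!r}: fp_count must be >= 0"
            )
        self.vandix_indicators = tuple(float(v) for v in self.vandix_indicators)
        if len(self.vandix_indicators) != 7:
            raise ValidationError(
                f"centre {self.community_id!r}: expected 7 deprivation "
                f"indicators, got {len(self.vandix_indicators)}"
            )


@dataclass
class PopulationBlock:
    """Smallest population unit; aggregated within drive-time catchments."""

    block_id: str
    location: Coordinate
    population: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValidationError(
                f"block {self.block_id!r}: population must be >= 0, "
                f"got {self.population}"
            )


@dataclass
class Facility:
    """A health facility: a general hospital or a dedicated hospice."""

    facility_id: str
    location: Coordinate
    kind: str
    beds: int
    name: str = ""

    KINDS = ("hospital", "hospice")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(
                f"facility {self.facility_id!r}: kind must be one of "
                f"{self.KINDS}, got {self.kind!r}"
            )
        if self.beds < 0:
            raise ValidationError(
                f"facility {self.facility_id!r}: beds must be >= 0"
            )


@dataclass(frozen=True)
class PcixSubscores:
    """The four scaled palliative care index (PCIX) variables."""

    age: float
    sex: float
    alone: float
    vandix: float

    def __post_init__(self) -> None:
        for label in ("age", "sex", "alone", "vandix"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"PCIX sub-score {label} must lie in [0, 1], got {v}"
                )


@dataclass(frozen=True)
class ComponentScores:
    """The four per-community model components, each in [0, 1]."""

    population: float
    isolation: float
    vulnerability: float
    readiness: float

    def __post_init__(self) -> None:
        for label in ("population", "isolation", "vulnerability", "readiness"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"component score {label} must lie in [0, 1], got {v}"
                )

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.population, self.isolation, self.vulnerability, self.readiness)


@dataclass
class SSMResult:
    """One community's scored, flagged and ranked model outcome."""

    community_id: str
    name: str
    components: ComponentScores
    ssm_score: float
    eligible: bool = False
    rank: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ssm_score <= 1.0:
            raise ValidationError(
                f"result {self.community_id!r}: ssm_score must lie in "
                f"[0, 1], got {self.ssm_score}"
            )


@dataclass
class Dataset:
    """Bundle of the model's four data layers.

    Invariants: identifiers unique within each layer; all coordinates in
    one shared planar metric coordinate system.
    """

    centres: list
    blocks: list
    network: "object"
    facilities: list

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for label, items, key in (
            ("centre", self.centres, "community_id"),
            ("block", self.blocks, "block_id"),
            ("facility", self.facilities, "facility_id"),
        ):
            seen = set()
            for item in items:
                ident = getattr(item, key)
                if ident in seen:
                    raise ValidationError(f"duplicate {label} identifier {ident!r}")
                seen.add(ident)


def parse_yes_no(value: object, context: str = "") -> bool:
    """Parse a yes/no style cell into a boolean.

    Accepts yes/no, y/n, true/false, 1/0 (any case) and native booleans.
    """
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("yes", "y", "true", "1"):
        return True
    if text in ("no", "n", "false", "0"):
        return False
    where = f" in {context}" if context else ""
    raise ValidationError(f"cannot interpret {value!r} as yes/no{where}")
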