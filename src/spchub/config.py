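"""Model configuration: every threshold and weight the model uses.

Defaults encode the published study conditions: a 60-minute drive-time
catchment, a 240-minute isolation cap, a 0.6 eligibility cut-point,
candidate communities above 5000 residents, palliative-care centres
defined as hospitals with more than 500 beds or hospices with more than
3 hospice beds, physician supply judged adequate at no more than 1307
persons per family physician, and equal component weights.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import yaml

from .model import ValidationError

__all__ = ["WeightVector", "ModelConfig", "read_config"]

PCIX_SCALING_MODES = ("max", "minmax", "none")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative weights for the four components; sum must be positive."""

    w_population: float = 1.0
    w_isolation: float = 1.0
    w_vulnerability: float = 1.0
    w_readiness: float = 1.0

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValidationError(f"weights must be non-negative, got {vals}")
        if sum(vals) <= 0:
            raise ValidationError(f"weights must sum to a positive value, got {vals}")

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (
            self.w_population,
            self.w_isolation,
            self.w_vulnerability,
            self.w_readiness,
        )


@dataclass(frozen=True)
class ModelConfig:
    catchment_minutes: float = 60.0
    isolation_cap_minutes: float = 240.0
    cutpoint: float = 0.6
    min_population: float = 5000.0
    hospital_min_beds: int = 500
    hospice_min_beds: int = 3
    physician_ratio_max: float = 1307.0
    weights: WeightVector = field(default_factory=WeightVector)
    pcix_scaling_mode: str = "max"
    display_decimals: int = 2

    def __post_init__(self) -> None:
        for label in (
            "catchment_minutes",
            "isolation_cap_minutes",
            "min_population",
            "hospital_min_beds",
            "hospice_min_beds",
            "physician_ratio_max",
        ):
            v = getattr(self, label)
            if v <= 0:
                raise ValidationError(f"{label} must be positive, got {v}")
        if not 0.0 <= self.cutpoint <= 1.0:
            raise ValidationError(
                f"cutpoint must lie in [0, 1], got {self.cutpoint}"
            )
        if self.pcix_scaling_mode not in PCIX_SCALING_MODES:
            raise ValidationError(
                f"pcix_scaling_mode must be one of {PCIX_SCALING_MODES}, "
                f"got {self.pcix_scaling_mode!r}"
            )
        if self.display_decimals < 0:
            raise ValidationError("display_decimals must be >= 0")

    def to_dict(self) -> dict:
        """Flat key/value form, suitable for serialization and manifests."""
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights.as_tuple())
        return d


_CONFIG_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}


def read_config(path: Union[str, Path]) -> ModelConfig:
    """Read a flat YAML/JSON configuration document.

    Unspecified keys fall back to the defaults; unknown keys are a hard
    error so that a typo cannot silently leave a threshold at its
    default.  Lists are accepted only for ``weights`` (four values,
    ordered population / isolation / vulnerability / readiness).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(
            f"config {path}: expected a key-value document, got {type(raw).__name__}"
        )
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ValidationError(f"config {path}: unknown key(s) {', '.join(unknown)}")
    kwargs = dict(raw)
    if "weights" in kwargs:
        w = kwargs["weights"]
        if not isinstance(w, (list, tuple)) or len(w) != 4:
            raise ValidationError(
                f"config {path}: weights must be a list of four values, got {w!r}"
            )
        kwargs["weights"] = WeightVector(*(float(x) for x in w))
    return ModelConfig(**kwargs)
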