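"""The four suitability components, each scored on [0, 1].

* **Population** — total population of the blocks within a 1-hour
  drive-time catchment, scaled so the largest catchment scores 1 and
  the rest proportionally.
* **Isolation** — drive minutes to the nearest palliative-care centre,
  proportional up to a cap (default 240 minutes) at which the score
  saturates at 1; unreachable communities score 1.
* **Vulnerability** — the palliative care index (PCIX): the mean of
  four scaled variables (% of population over 75, % female, % living
  alone, and a census deprivation composite), each scaled across a
  reference set of communities.
* **Community readiness** — five binary indicators (local hospice
  society, post-secondary institution within reach, telemedicine use,
  adequate family-physician supply, local hospice momentum), each
  contributing 0.2 when present.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .model import (
    PcixSubscores,
    PopulationBlock,
    PopulationCentre,
    ReadinessFlags,
    ValidationError,
)
from .network import RoadNetwork, service_area, snap_to_node

__all__ = [
    "DEFAULT_VANDIX_PROTECTIVE",
    "catchment_population",
    "population_component",
    "isolation_component",
    "scale_subscores",
    "vandix_score",
    "pcix_vulnerability",
    "physician_supply_adequate",
    "readiness_component",
]

logger = logging.getLogger(__name__)

#: For each of the seven deprivation indicators, True marks an indicator
#: where a HIGH raw value means LESS deprivation and the scaled value is
#: therefore complemented.  Default order: no-high-school %, unemployment
#: rate, lone-parent %, average income (protective), homeowner %
#: (protective), employment ratio (protective), and a seventh
#: user-defined slot (non-protective by default).
DEFAULT_VANDIX_PROTECTIVE: Tuple[bool, ...] = (
    False,
    False,
    False,
    True,
    True,
    True,
    False,
)


def catchment_population(
    network: RoadNetwork,
    centre: PopulationCentre,
    blocks: Sequence[PopulationBlock],
    limit_minutes: float,
) -> float:
    """Total block population within ``limit_minutes`` drive of a centre.

    The centre and every block attach to their nearest network node at
    zero cost; a block counts when its node lies inside the centre's
    drive-time service area.
    """
    if not blocks:
        return 0.0
    origin = snap_to_node(network, centre.location)
    area = service_area(network, origin, limit_minutes)
    return float(
        sum(b.population for b in blocks if snap_to_node(network, b.location) in area)
    )


def population_component(catchment_pops: Mapping[str, float]) -> Dict[str, float]:
    """Scale catchment populations so the largest scores exactly 1."""
    if not catchment_pops:
        raise ValidationError("population_component needs at least one centre")
    if any(v < 0 for v in catchment_pops.values()):
        raise ValidationError("catchment populations must be >= 0")
    top = max(catchment_pops.values())
    if top == 0:
        return {k: 0.0 for k in catchment_pops}
    return {k: v / top for k, v in catchment_pops.items()}


def isolation_component(minutes_to_nearest: float, cap_minutes: float) -> float:
    """Drive minutes to the nearest palliative-care centre, proportional
    to the cap; at or beyond the cap (or unreachable) the score is 1."""
    if cap_minutes <= 0:
        raise ValidationError(f"cap_minutes must be positive, got {cap_minutes}")
    if minutes_to_nearest < 0:
        raise ValidationError(
            f"minutes_to_nearest must be >= 0, got {minutes_to_nearest}"
        )
    if math.isinf(minutes_to_nearest):
        return 1.0
    return min(minutes_to_nearest / cap_minutes, 1.0)


def scale_subscores(values: Mapping[str, float], mode: str) -> Dict[str, float]:
    """Scale raw community values onto [0, 1].

    ``max``: x / max(x) — the community with the highest value scores 1
    (all-zero input scores all 0).  ``minmax``: (x - min) / (max - min)
    (degenerate spread scores all 0).  ``none``: identity, clipped to
    [0, 1].
    """
    if mode not in ("max", "minmax", "none"):
        raise ValidationError(f"unknown scaling mode {mode!r}")
    if not values:
        return {}
    vals = list(values.values())
    if any(not math.isfinite(v) for v in vals):
        raise ValidationError("scale_subscores requires finite values")
    if mode == "none":
        return {k: min(max(v, 0.0), 1.0) for k, v in values.items()}
    if mode == "max":
        if any(v < 0 for v in vals):
            raise ValidationError("mode='max' requires non-negative values")
        top = max(vals)
        if top == 0:
            return {k: 0.0 for k in values}
        return {k: v / top for k, v in values.items()}
    lo, hi = min(vals), max(vals)
    if hi == lo:
        if len(values) == 1:
            logger.warning(
                "min-max scaling over a single community is degenerate; "
                "returning 0"
            )
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def vandix_score(
    indicators: Sequence[float],
    reference: Mapping[str, Sequence[float]],
    directions: Optional[Sequence[bool]] = None,
    mode: str = "max",
) -> float:
    """Census deprivation composite for one community.

    Each of the seven indicators is scaled (per ``mode``) against the
    reference set of communities; indicators flagged in ``directions``
    are protective (high raw value = less deprivation) and are
    complemented after scaling.  The score is the unweighted mean of the
    seven adjusted values and lies in [0, 1].
    """
    if directions is None:
        directions = DEFAULT_VANDIX_PROTECTIVE
    if not reference:
        raise ValidationError("vandix_score requires a non-empty reference set")
    indicators = tuple(float(v) for v in indicators)
    if len(indicators) != 7 or len(directions) != 7:
        raise ValidationError("vandix_score expects exactly 7 indicators/directions")

    key = "__scored__"
    adjusted = []
    for j in range(7):
        col = {cid: float(vals[j]) for cid, vals in reference.items()}
        col[key] = indicators[j]
        scaled = scale_subscores(col, mode)[key]
        adjusted.append(1.0 - scaled if directions[j] else scaled)
    return sum(adjusted) / 7.0


def pcix_vulnerability(sub: PcixSubscores) -> float:
    """Palliative care index: the four variables evenly weighted —
    summed and divided by four."""
    return (sub.age + sub.sex + sub.alone + sub.vandix) / 4.0


def physician_supply_adequate(
    population: float, fp_count: int, ratio_max: float
) -> bool:
    """Whether family-physician supply meets the benchmark of at most
    ``ratio_max`` persons per physician (inclusive)."""
    if population < 0 or fp_count < 0:
        raise ValidationError("population and fp_count must be >= 0")
    if population == 0:
        return True
    if fp_count == 0:
        return False
    return population / fp_count <= ratio_max


def readiness_component(flags: ReadinessFlags) -> float:
    """0.2 for each readiness indicator present; one of
    {0, 0.2, 0.4, 0.6, 0.8, 1.0}."""
    values = (
        flags.aware,
        flags.education,
        flags.telemedicine,
        flags.fp_adequate,
        flags.momentum,
    )
    if any(v is None for v in values):
        raise ValidationError(
            "readiness_component requires fully resolved flags "
            "(fp_adequate must be decided first)"
        )
    return sum(bool(v) for v in values) / 5.0
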