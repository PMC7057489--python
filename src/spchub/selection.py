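"""Candidate selection: reduce population centres to hub candidates.

Two filters apply, in order: a community must have strictly more than
``min_population`` residents, and must lie strictly more than the
catchment drive time (default 60 minutes) from the nearest
palliative-care centre.  A palliative-care centre is a general hospital
with more than ``hospital_min_beds`` beds or a dedicated hospice with
more than ``hospice_min_beds`` hospice beds (both strict).  A community
that cannot reach any palliative-care centre at all is maximally
isolated and passes the drive-time filter.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Set

from .config import ModelConfig
from .model import Dataset, Facility, PopulationCentre
from .network import RoadNetwork, nearest_site_minutes, snap_to_node

__all__ = ["is_palliative_centre", "palliative_centre_nodes", "select_candidates"]

logger = logging.getLogger(__name__)


def is_palliative_centre(facility: Facility, config: ModelConfig) -> bool:
    """Whether a facility counts as an existing palliative-care centre."""
    if facility.kind == "hospital":
        return facility.beds > config.hospital_min_beds
    return facility.beds > config.hospice_min_beds


def palliative_centre_nodes(
    facilities: Iterable[Facility], network: RoadNetwork, config: ModelConfig
) -> Set[str]:
    """Network nodes hosting a qualifying palliative-care centre."""
    return {
        snap_to_node(network, f.location)
        for f in facilities
        if is_palliative_centre(f, config)
    }


def select_candidates(dataset: Dataset, config: ModelConfig) -> List[PopulationCentre]:
    """Apply the population and isolation filters; preserve input order."""
    sized = [c for c in dataset.centres if c.population > config.min_population]
    logger.info(
        "population filter (> %g residents): %d of %d centres retained",
        config.min_population,
        len(sized),
        len(dataset.centres),
    )
    sites = palliative_centre_nodes(dataset.facilities, dataset.network, config)
    if not sites:
        logger.warning(
            "no qualifying palliative-care centre in the dataset; all %d "
            "population-qualified centres retained",
            len(sized),
        )
        return sized
    survivors = []
    for centre in sized:
        origin = snap_to_node(dataset.network, centre.location)
        result = nearest_site_minutes(dataset.network, origin, sites)
        if result.minutes > config.catchment_minutes:
            survivors.append(centre)
    logger.info(
        "isolation filter (> %g min to nearest palliative-care centre): "
        "%d of %d centres retained",
        config.catchment_minutes,
        len(survivors),
        len(sized),
    )
    return survivors
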