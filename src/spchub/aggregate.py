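"""Final model score, eligibility flag, and ranking.

The four component scores are combined as a weighted mean (with the
default equal weights this is exactly the sum divided by four, i.e. the
0–4 raw model score rescaled to 0–1).  A community is eligible when its
final score strictly exceeds the cut-point (default 0.6).  All internal
arithmetic is kept at full precision; rounding happens only at the
display/serialization boundary, with decimal half-away-from-zero
rounding so printed tables are reproducible.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

from .config import ModelConfig, WeightVector
from .model import (
    ComponentScores,
    Dataset,
    PcixSubscores,
    PopulationCentre,
    SSMResult,
    ValidationError,
)
from .network import nearest_site_minutes, snap_to_node
from .scores import (
    catchment_population,
    isolation_component,
    pcix_vulnerability,
    physician_supply_adequate,
    population_component,
    readiness_component,
    scale_subscores,
    vandix_score,
)
from .selection import palliative_centre_nodes, select_candidates

__all__ = ["combine_components", "round_display", "rank_and_flag", "run_ssm"]

logger = logging.getLogger(__name__)


def combine_components(
    components: ComponentScores, weights: Optional[WeightVector] = None
) -> float:
    """Weighted mean of the four components: sum(w_i * s_i) / sum(w_i).

    Computed in decimal arithmetic so that table-scale inputs (scores
    quoted to two decimals) aggregate without binary-float boundary
    artifacts — e.g. components summing to 1.62 yield exactly 0.405,
    which display rounding then carries to 0.41.
    """
    if weights is None:
        weights = WeightVector()
    w = [Decimal(str(x)) for x in weights.as_tuple()]
    s = [Decimal(str(x)) for x in components.as_tuple()]
    total_w = sum(w)
    if total_w <= 0:
        raise ValidationError("weight sum must be positive")
    return float(sum(wi * si for wi, si in zip(w, s)) / total_w)


def round_display(x: float, dp: int = 2) -> str:
    """Decimal string of ``x`` at ``dp`` places, half away from zero.

    Rounding is performed on the decimal value of the shortest float
    representation, not on binary floats, so 0.325 prints as "0.33".
    """
    if dp < 0:
        raise ValidationError("dp must be >= 0")
    q = Decimal(1).scaleb(-dp)
    return str(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def rank_and_flag(results: Sequence[SSMResult], cutpoint: float) -> List[SSMResult]:
    """Order results by descending final score and assign 1-based ranks.

    Ties break by descending population component, then ascending
    community identifier (a serialization convention — the model itself
    does not distinguish tied communities).  ``eligible`` is strict:
    a score exactly at the cut-point is not eligible.
    """
    ordered = sorted(
        results,
        key=lambda r: (-r.ssm_score, -r.components.population, r.community_id),
    )
    out: List[SSMResult] = []
    for i, r in enumerate(ordered, start=1):
        out.append(
            SSMResult(
                community_id=r.community_id,
                name=r.name,
                components=r.components,
                ssm_score=r.ssm_score,
                eligible=r.ssm_score > cutpoint,
                rank=i,
            )
        )
    return out


def run_ssm(
    dataset: Dataset,
    config: Optional[ModelConfig] = None,
    pcix_reference: Optional[Sequence[PopulationCentre]] = None,
    vandix_directions: Optional[Sequence[bool]] = None,
) -> List[SSMResult]:
    """End-to-end model run: select candidates, score the four
    components, combine, flag eligibility and rank.

    ``pcix_reference`` optionally supplies the communities against which
    the vulnerability variables are scaled (e.g. a province-wide table);
    by default the candidate set itself is the reference.
    """
    if config is None:
        config = ModelConfig()
    candidates = select_candidates(dataset, config)
    if not candidates:
        logger.warning("no candidate communities survive the selection filters")
        return []

    network = dataset.network
    mode = config.pcix_scaling_mode

    # population component: catchment totals scaled to the largest
    pops = {
        c.community_id: catchment_population(
            network, c, dataset.blocks, config.catchment_minutes
        )
        for c in candidates
    }
    pop_scores = population_component(pops)

    # isolation component: minutes to the nearest palliative-care centre
    sites = palliative_centre_nodes(dataset.facilities, network, config)
    iso_scores: Dict[str, float] = {}
    for c in candidates:
        if not sites:
            iso_scores[c.community_id] = 1.0
            continue
        origin = snap_to_node(network, c.location)
        res = nearest_site_minutes(network, origin, sites)
        iso_scores[c.community_id] = isolation_component(
            res.minutes, config.isolation_cap_minutes
        )

    # vulnerability component: PCIX scaled over the reference set
    reference = list(pcix_reference) if pcix_reference else list(candidates)
    by_id = {c.community_id: c for c in reference}
    by_id.update({c.community_id: c for c in candidates})
    age = scale_subscores({i: c.pct_over75 for i, c in by_id.items()}, mode)
    sex = scale_subscores({i: c.pct_female for i, c in by_id.items()}, mode)
    alone = scale_subscores({i: c.pct_alone for i, c in by_id.items()}, mode)
    vandix_ref = {i: c.vandix_indicators for i, c in by_id.items()}
    vuln_scores = {
        c.community_id: pcix_vulnerability(
            PcixSubscores(
                age=age[c.community_id],
                sex=sex[c.community_id],
                alone=alone[c.community_id],
                vandix=vandix_score(
                    c.vandix_indicators, vandix_ref, vandix_directions, mode
                ),
            )
        )
        for c in candidates
    }

    # readiness component: resolve physician adequacy where not supplied
    ready_scores: Dict[str, float] = {}
    for c in candidates:
        flags = c.readiness.resolved(
            physician_supply_adequate(
                c.population, c.fp_count, config.physician_ratio_max
            )
        )
        ready_scores[c.community_id] = readiness_component(flags)

    results = []
    for c in candidates:
        comps = ComponentScores(
            population=pop_scores[c.community_id],
            isolation=iso_scores[c.community_id],
            vulnerability=vuln_scores[c.community_id],
            readiness=ready_scores[c.community_id],
        )
        results.append(
            SSMResult(
                community_id=c.community_id,
                name=c.name,
                components=comps,
                ssm_score=combine_components(comps, config.weights),
            )
        )
    return rank_and_flag(results, config.cutpoint)
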