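"""Seeded synthetic regions for exercising every model stage.

Real inputs to this model (census population centres and blocks,
licensed road networks, facility directories) cannot be redistributed,
so this module generates structurally equivalent stand-ins: a connected
perturbed-grid road lattice with speed-attributed edges, spatially
scattered population blocks with log-normal populations, communities
with Beta-distributed demographic proportions and binary readiness
indicators, and health facilities of both kinds with bed counts.

Two entry points:

* :func:`generate_region` — a randomized region under
  :class:`SynthParams`, byte-reproducible for a fixed seed.
* :func:`generate_line_region` — a fixed six-community line topology
  whose every intermediate quantity (selection, catchments, isolation
  minutes, all four components, final ranking) was computed by hand;
  the frozen expectations live in :data:`LINE_EXPECTATION`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import networkx as nx
import numpy as np

from .model import (
    Dataset,
    Facility,
    PopulationBlock,
    PopulationCentre,
    ReadinessFlags,
    ValidationError,
)
from .network import RoadNetwork

__all__ = ["SynthParams", "generate_region", "generate_line_region", "LINE_EXPECTATION"]

#: Grid spacing between adjacent road nodes, metres.  20 km is a
#: plausible distance between rural junctions at regional scale.
GRID_SPACING_M = 20_000.0


@dataclass(frozen=True)
class SynthParams:
    """Knobs for the randomized region generator.

    Defaults describe a sparse rural region: an 8x8 road lattice with a
    modest fraction of missing links, highway-to-backroad speeds,
    communities whose populations straddle the 5000-resident selection
    threshold, and small census-block populations.
    """

    n_grid: int = 8
    edge_keep_prob: float = 0.85
    speed_range: Tuple[float, float] = (50.0, 100.0)
    n_centres: int = 12
    n_blocks: int = 120
    n_facilities: int = 6
    #: log-normal (mu, sigma) for block populations (median ~400 persons)
    pop_lognormal_params: Tuple[float, float] = (6.0, 1.0)
    #: log-normal (mu, sigma) for centre populations (median ~6000)
    centre_pop_lognormal_params: Tuple[float, float] = (8.7, 0.5)
    #: Beta (alpha, beta) per demographic proportion
    demographic_beta_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "pct_over75": (2.0, 18.0),
            "pct_female": (80.0, 80.0),
            "pct_alone": (2.0, 18.0),
        }
    )
    readiness_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_keep_prob <= 1.0:
            raise ValidationError("edge_keep_prob must lie in [0, 1]")
        if not 0.0 <= self.readiness_prob <= 1.0:
            raise ValidationError("readiness_prob must lie in [0, 1]")
        for label in ("n_grid", "n_centres", "n_blocks", "n_facilities"):
            if getattr(self, label) < 1:
                raise ValidationError(f"{label} must be >= 1")
        lo, hi = self.speed_range
        if lo <= 0 or hi < lo:
            raise ValidationError("speed_range must be positive and ordered")
        if self.n_centres > self.n_grid ** 2:
            raise ValidationError(
                f"cannot place {self.n_centres} centres on "
                f"{self.n_grid ** 2} nodes"
            )


def generate_region(params: SynthParams) -> Dataset:
    """Generate a random region; identical params give identical output.

    One seed sequence drives four independent sub-streams (network,
    centres, blocks, facilities) so that changing one layer's count
    does not perturb the others.
    """
    streams = np.random.SeedSequence(params.seed).spawn(4)
    rng_net, rng_cen, rng_blk, rng_fac = (np.random.default_rng(s) for s in streams)

    network = _grid_network(params, rng_net)
    node_ids = sorted(network.nodes)
    node_xy = {i: network.nodes[i] for i in node_ids}

    # --- population centres, placed on distinct nodes -------------------
    mu_c, sigma_c = params.centre_pop_lognormal_params
    centre_nodes = rng_cen.choice(len(node_ids), size=params.n_centres, replace=False)
    centres = []
    for k, ni in enumerate(centre_nodes):
        pop = float(np.round(rng_cen.lognormal(mu_c, sigma_c)))
        props = {
            name: float(rng_cen.beta(a, b))
            for name, (a, b) in sorted(params.demographic_beta_params.items())
        }
        vandix = (
            float(rng_cen.beta(2, 8)),        # no high-school completion
            float(rng_cen.beta(2, 20)),       # unemployment rate
            float(rng_cen.beta(2, 10)),       # lone-parent families
            float(rng_cen.lognormal(10.9, 0.25)),  # average income (protective)
            float(rng_cen.beta(8, 4)),        # homeowners (protective)
            float(rng_cen.beta(8, 4)),        # employment ratio (protective)
            float(rng_cen.beta(2, 5)),        # seventh, user-defined slot
        )
        fp = int(rng_cen.poisson(max(pop, 1.0) / 1500.0))
        flags = ReadinessFlags(
            aware=bool(rng_cen.random() < params.readiness_prob),
            education=bool(rng_cen.random() < params.readiness_prob),
            telemedicine=bool(rng_cen.random() < params.readiness_prob),
            fp_adequate=None,
            momentum=bool(rng_cen.random() < params.readiness_prob),
        )
        centres.append(
            PopulationCentre(
                community_id=f"C{k:03d}",
                name=f"Community {k}",
                location=node_xy[node_ids[int(ni)]],
                population=pop,
                pct_over75=props["pct_over75"],
                pct_female=props["pct_female"],
                pct_alone=props["pct_alone"],
                fp_count=fp,
                vandix_indicators=vandix,
                readiness=flags,
            )
        )

    # --- population blocks, scattered near random nodes -----------------
    mu_b, sigma_b = params.pop_lognormal_params
    blocks = []
    for k in range(params.n_blocks):
        node = node_xy[node_ids[int(rng_blk.integers(len(node_ids)))]]
        dx, dy = rng_blk.uniform(-3000.0, 3000.0, size=2)
        pop = float(np.round(rng_blk.lognormal(mu_b, sigma_b))) + 1.0
        blocks.append(
            PopulationBlock(
                block_id=f"B{k:04d}",
                location=(node[0] + float(dx), node[1] + float(dy)),
                population=pop,
            )
        )

    # --- facilities: the first always qualifies as a palliative centre --
    facilities = []
    for k in range(params.n_facilities):
        node = node_xy[node_ids[int(rng_fac.integers(len(node_ids)))]]
        if k == 0:
            kind, beds = "hospital", int(rng_fac.integers(550, 1200))
        elif rng_fac.random() < 0.5:
            kind, beds = "hospital", int(rng_fac.integers(20, 450))
        else:
            kind, beds = "hospice", int(rng_fac.integers(0, 9))
        facilities.append(
            Facility(
                facility_id=f"F{k:03d}",
                name=f"Facility {k}",
                location=node,
                kind=kind,
                beds=beds,
            )
        )

    return Dataset(centres=centres, blocks=blocks, network=network,
                   facilities=facilities)


def _grid_network(params: SynthParams, rng: np.random.Generator) -> RoadNetwork:
    """Perturbed-grid road lattice; edge drops never break connectivity."""
    n = params.n_grid
    nodes = {
        f"g{i:02d}_{j:02d}": (i * GRID_SPACING_M, j * GRID_SPACING_M)
        for i in range(n)
        for j in range(n)
    }
    pairs = []
    for i in range(n):
        for j in range(n):
            if i + 1 < n:
                pairs.append((f"g{i:02d}_{j:02d}", f"g{i + 1:02d}_{j:02d}"))
            if j + 1 < n:
                pairs.append((f"g{i:02d}_{j:02d}", f"g{i:02d}_{j + 1:02d}"))

    edges = []
    for a, b in pairs:
        # road length exceeds straight-line distance by a wiggle factor
        length_km = GRID_SPACING_M / 1000.0 * float(rng.uniform(1.05, 1.35))
        speed = float(rng.uniform(*params.speed_range))
        edges.append((a, b, 60.0 * length_km / speed))

    keep_draws = rng.random(len(edges))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges, weight="minutes")
    for (a, b, _), draw in zip(list(edges), keep_draws):
        if draw >= params.edge_keep_prob:
            g.remove_edge(a, b)
            if not nx.is_connected(g):
                g.add_edge(a, b)  # restoring; weight unused below
    kept = {frozenset((a, b)) for a, b in g.edges}
    final_edges = [(a, b, m) for a, b, m in edges if frozenset((a, b)) in kept]
    return RoadNetwork(nodes=nodes, edges=final_edges)


# ---------------------------------------------------------------------------
# deterministic line fixture
#
# Six communities on a single road, travel minutes between neighbours
# 50 / 45 / 50 / 55 / 70, one 600-bed hospital at the west end (node L0)
# plus two non-qualifying hospices.  Every expectation below was traced
# by hand (exact fractions) before being frozen here.
#
#   L0 --50-- L1 --45-- L2 --50-- L3 --55-- L4 --70-- L5
#   hospital            3-bed hospice       2-bed hospice
#
# Minutes from the hospital: C0 0, C1 50, C2 95, C3 145, C4 200, C5 270.
# Selection (> 5000 residents AND > 60 min): C3, C4, C5 survive.
# 60-min catchments: C3 reaches {L2, L3, L4}; C4 reaches {L3, L4};
# C5 reaches {L5} only.

_LINE_MINUTES = (50.0, 45.0, 50.0, 55.0, 70.0)


def generate_line_region() -> Dataset:
    """The deterministic six-community line fixture."""
    xs = [0.0]
    for m in _LINE_MINUTES:
        xs.append(xs[-1] + m * 1000.0)  # 60 km/h: one minute per km
    nodes = {f"L{i}": (x, 0.0) for i, x in enumerate(xs)}
    edges = [
        (f"L{i}", f"L{i + 1}", m) for i, m in enumerate(_LINE_MINUTES)
    ]
    network = RoadNetwork(nodes=nodes, edges=edges)

    pops = [80000.0, 6000.0, 4000.0, 8000.0, 7000.0, 9000.0]
    over75 = [0.10, 0.10, 0.10, 0.10, 0.15, 0.12]
    female = [0.50, 0.50, 0.50, 0.50, 0.48, 0.52]
    alone = [0.10, 0.10, 0.10, 0.10, 0.08, 0.12]
    fp = [60, 5, 3, 7, 5, 7]
    vandix = [
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (0.2, 0.05, 0.10, 60000.0, 0.8, 0.60, 0.1),
        (0.4, 0.10, 0.20, 40000.0, 0.6, 0.50, 0.2),
        (0.3, 0.10, 0.15, 50000.0, 0.7, 0.55, 0.2),
    ]
    flags = [
        ReadinessFlags(),
        ReadinessFlags(),
        ReadinessFlags(),
        ReadinessFlags(aware=True, education=True, telemedicine=True,
                       momentum=False),
        ReadinessFlags(aware=False, education=True, telemedicine=True,
                       momentum=False),
        ReadinessFlags(aware=True, education=False, telemedicine=True,
                       momentum=True),
    ]
    centres = [
        PopulationCentre(
            community_id=f"C{i}",
            name=f"Linetown {i}",
            location=nodes[f"L{i}"],
            population=pops[i],
            pct_over75=over75[i],
            pct_female=female[i],
            pct_alone=alone[i],
            fp_count=fp[i],
            vandix_indicators=vandix[i],
            readiness=flags[i],
        )
        for i in range(6)
    ]
    blocks = [
        PopulationBlock(
            block_id=f"B{i}",
            location=(nodes[f"L{i}"][0] + 300.0, 400.0),
            population=pops[i],
        )
        for i in range(6)
    ]
    facilities = [
        Facility(facility_id="H1", name="West General Hospital",
                 location=nodes["L0"], kind="hospital", beds=600),
        Facility(facility_id="H2", name="Midway Hospice",
                 location=nodes["L2"], kind="hospice", beds=3),
        Facility(facility_id="H3", name="East Hospice",
                 location=nodes["L4"], kind="hospice", beds=2),
    ]
    return Dataset(centres=centres, blocks=blocks, network=network,
                   facilities=facilities)


#: Hand-traced expectations for :func:`generate_line_region` under the
#: default configuration (60-min catchment, 240-min cap, cut-point 0.6,
#: equal weights, max scaling, candidate-set PCIX reference).  Exact
#: fractions are written as Python ratios so the intent stays visible.
LINE_EXPECTATION = {
    "candidates": ["C3", "C4", "C5"],
    "isolation_minutes": {"C3": 145.0, "C4": 200.0, "C5": 270.0},
    "catchment_population": {"C3": 19000.0, "C4": 15000.0, "C5": 9000.0},
    "population_score": {"C3": 1.0, "C4": 15 / 19, "C5": 9 / 19},
    "isolation_score": {"C3": 145 / 240, "C4": 200 / 240, "C5": 1.0},
    # PCIX sub-scores (max scaling over the three candidates):
    #   age:   C3 2/3,  C4 1,     C5 4/5
    #   sex:   C3 25/26, C4 12/13, C5 1
    #   alone: C3 5/6,  C4 2/3,   C5 1
    #   vandix: C3 2/7, C4 19/28, C5 31/56
    "vandix_score": {"C3": 2 / 7, "C4": 19 / 28, "C5": 31 / 56},
    "vulnerability_score": {"C3": 125 / 182, "C4": 3569 / 4368, "C5": 939 / 1120},
    "readiness_score": {"C3": 0.8, "C4": 0.4, "C5": 0.8},
    "ssm_score": {
        "C3": (1.0 + 145 / 240 + 125 / 182 + 0.8) / 4,
        "C4": (15 / 19 + 200 / 240 + 3569 / 4368 + 0.4) / 4,
        "C5": (9 / 19 + 1.0 + 939 / 1120 + 0.8) / 4,
    },
    "ranking": ["C5", "C3", "C4"],
    "eligible": {"C3": True, "C4": True, "C5": True},
    "ssm_display": {"C3": "0.77", "C4": "0.71", "C5": "0.78"},
}
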