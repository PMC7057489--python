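"""Road-network travel-time engine.

Builds an undirected drive-time graph from speed-attributed line
features and answers the three queries the suitability model needs:
point-to-point travel minutes, drive-time service areas (isochrone
catchments), and nearest-facility travel time.

Travel is undirected (no one-way streets: rural road data here carries
no directionality) and off-network access is free — a community or
population block attaches to its nearest graph node at zero cost.
Unreachability is a first-class value (``UNREACHABLE``, i.e. ``inf``),
never an exception, so downstream scoring can map it to maximal
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .model import Coordinate, ValidationError

__all__ = [
    "UNREACHABLE",
    "RoadNetwork",
    "TravelQueryResult",
    "build_graph",
    "snap_to_node",
    "travel_time_minutes",
    "service_area",
    "nearest_site_minutes",
]

#: Marker for "no path exists"; compares greater than any finite time.
UNREACHABLE = math.inf

# Node-identity tolerance: endpoints within 1 mm merge into one node.
_COORD_DECIMALS = 3


class TravelQueryResult(NamedTuple):
    """Outcome of a nearest-site query: the chosen site and the minutes
    to reach it (``UNREACHABLE``/target ``None`` when no site can be
    reached)."""

    target: Optional[str]
    minutes: float

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.minutes)


@dataclass
class RoadNetwork:
    """Undirected graph with per-edge travel minutes.

    ``nodes`` maps identifiers to planar metric coordinates; ``edges``
    is a list of (node_a, node_b, minutes) with minutes > 0.
    """

    nodes: Dict[str, Coordinate]
    edges: List[Tuple[str, str, float]]
    _graph: Optional[nx.Graph] = field(default=None, repr=False, compare=False)
    _node_index: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for a, b, minutes in self.edges:
            if minutes <= 0:
                raise ValidationError(
                    f"edge ({a}, {b}): travel minutes must be positive, got {minutes}"
                )
            for n in (a, b):
                if n not in self.nodes:
                    raise ValidationError(f"edge ({a}, {b}): unknown node {n!r}")

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for a, b, minutes in self.edges:
                # parallel edges collapse to the fastest link
                if g.has_edge(a, b):
                    g[a][b]["minutes"] = min(g[a][b]["minutes"], minutes)
                else:
                    g.add_edge(a, b, minutes=minutes)
            self._graph = g
        return self._graph

    def _coords(self) -> tuple:
        if self._node_index is None:
            ids = sorted(self.nodes)
            xy = np.array([self.nodes[i] for i in ids], dtype=float)
            self._node_index = (ids, xy)
        return self._node_index


def build_graph(line_features: Iterable[dict]) -> RoadNetwork:
    """Build a drive-time graph from road line features.

    Each feature is a mapping with ``coords`` (a sequence of (x, y)
    pairs in metres; the first and last define the edge endpoints),
    ``length_km`` and ``speed_kmh``.  Edge cost is
    ``60 * length_km / speed_kmh`` minutes.  Endpoints matching within
    1 mm merge into a single node; node identifiers are assigned in
    order of first appearance and sort consistently ("n0000", ...).
    """
    nodes: Dict[str, Coordinate] = {}
    key_to_id: Dict[Tuple[float, float], str] = {}
    edges: List[Tuple[str, str, float]] = []

    def node_for(pt: Sequence[float]) -> str:
        key = (round(float(pt[0]), _COORD_DECIMALS), round(float(pt[1]), _COORD_DECIMALS))
        ident = key_to_id.get(key)
        if ident is None:
            ident = f"n{len(key_to_id):06d}"
            key_to_id[key] = ident
            nodes[ident] = key
        return ident

    for i, feat in enumerate(line_features):
        length_km = float(feat["length_km"])
        speed_kmh = float(feat["speed_kmh"])
        if length_km <= 0:
            raise ValidationError(f"road feature {i}: length_km must be > 0, got {length_km}")
        if speed_kmh <= 0:
            raise ValidationError(f"road feature {i}: speed_kmh must be > 0, got {speed_kmh}")
        coords = feat["coords"]
        if len(coords) < 2:
            raise ValidationError(f"road feature {i}: needs at least two coordinates")
        a = node_for(coords[0])
        b = node_for(coords[-1])
        if a == b:
            # degenerate loop after rounding; carries no travel information
            continue
        edges.append((a, b, 60.0 * length_km / speed_kmh))

    return RoadNetwork(nodes=nodes, edges=edges)


def snap_to_node(network: RoadNetwork, point: Coordinate) -> str:
    """Nearest graph node to a point (Euclidean); ties break toward the
    lexicographically smallest node identifier."""
    if not network.nodes:
        raise ValidationError("cannot snap to an empty network")
    ids, xy = network._coords()
    d2 = (xy[:, 0] - point[0]) ** 2 + (xy[:, 1] - point[1]) ** 2
    # ids are sorted, so the first minimum is the lexicographic tie-winner
    return ids[int(np.argmin(d2))]


def _require_node(network: RoadNetwork, node: str) -> None:
    if node not in network.nodes:
        raise ValidationError(f"unknown node {node!r}")


def travel_time_minutes(network: RoadNetwork, origin: str, dest: str) -> float:
    """Least-minutes path cost between two nodes, or ``UNREACHABLE``."""
    _require_node(network, origin)
    _require_node(network, dest)
    try:
        return nx.dijkstra_path_length(network.graph, origin, dest, weight="minutes")
    except nx.NetworkXNoPath:
        return UNREACHABLE


def service_area(network: RoadNetwork, origin: str, limit_minutes: float) -> Set[str]:
    """All nodes within ``limit_minutes`` of the origin (inclusive).

    Always contains the origin; a zero budget yields exactly the origin.
    """
    _require_node(network, origin)
    if limit_minutes < 0:
        raise ValidationError(f"limit_minutes must be >= 0, got {limit_minutes}")
    if math.isinf(limit_minutes):
        lengths = nx.single_source_dijkstra_path_length(
            network.graph, origin, weight="minutes"
        )
        return set(lengths)
    lengths = nx.single_source_dijkstra_path_length(
        network.graph, origin, cutoff=limit_minutes, weight="minutes"
    )
    return {n for n, d in lengths.items() if d <= limit_minutes}


def nearest_site_minutes(
    network: RoadNetwork, origin: str, site_nodes: Iterable[str]
) -> TravelQueryResult:
    """Travel time to the nearest of a set of site nodes.

    Ties break toward the smallest site identifier; if no site is
    reachable the result carries ``UNREACHABLE`` and no target.
    """
    sites = sorted(set(site_nodes))
    if not sites:
        raise ValidationError("site_nodes must be non-empty")
    _require_node(network, origin)
    for s in sites:
        _require_node(network, s)
    lengths = nx.single_source_dijkstra_path_length(
        network.graph, origin, weight="minutes"
    )
    best: Optional[Tuple[float, str]] = None
    for s in sites:
        if s in lengths:
            cand = (lengths[s], s)
            if best is None or cand < best:
                best = cand
    if best is None:
        return TravelQueryResult(target=None, minutes=UNREACHABLE)
    return TravelQueryResult(target=best[1], minutes=best[0])
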