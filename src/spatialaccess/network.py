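"""Multimodal travel-time computation on abstract networks.

Car and walk modes are plain weighted graphs traversed with Dijkstra shortest
paths.  Transit is a stop/line model: a trip walks to a boarding stop, waits
an expected half headway, rides in-vehicle along one line (single boarding,
no transfers), and walks from the alighting stop to the destination; the pure
walk alternative is always compared and the smaller taken, so transit time
never exceeds walk time.  Departure-time effects are out of scope — the
half-headway expected wait stands in for schedules.

Origins and destinations are coordinates snapped to the nearest network node
within a snap radius; points outside the radius are unreachable (``+inf``,
with a logged warning), never an exception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .types import AreaUnit, ProviderSite, TravelTimeMatrix

__all__ = ["ModeNetwork", "TransitLine", "TransitNetwork", "shortest_time", "transit_time", "build_matrix"]

logger = logging.getLogger(__name__)

#: Default nearest-node snap radius, in the planar distance units of the
#: network coordinates (1 km equivalent at toy scale).
DEFAULT_SNAP_RADIUS = 1.0


class ModeNetwork:
    """A single-mode (car or walk) network: nodes with coordinates, edges in minutes."""

    def __init__(
        self,
        mode: str,
        nodes: Sequence[tuple[str, float, float]],
        edges: Sequence[tuple[str, str, float]],
        directed: bool = False,
        snap_radius: float = DEFAULT_SNAP_RADIUS,
    ) -> None:
        if mode not in ("car", "walk"):
            raise ConfigurationError(f"mode must be 'car' or 'walk', got {mode!r}")
        ids = [str(n) for n, _, _ in nodes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("node IDs must be unique")
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for nid, x, y in nodes:
            g.add_node(str(nid), x=float(x), y=float(y))
        for u, v, minutes in edges:
            if minutes < 0:
                raise ConfigurationError(f"negative edge weight on ({u}, {v})")
            if str(u) not in g or str(v) not in g:
                raise ConfigurationError(f"edge ({u}, {v}) references unknown node")
            g.add_edge(str(u), str(v), minutes=float(minutes))
        self.mode = mode
        self.graph = g
        self.directed = directed
        self.snap_radius = float(snap_radius)
        self._coords = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in g.nodes], dtype=float)
        self._node_ids = list(g.nodes)

    def snap(self, point: tuple[float, float]) -> str | None:
        """Nearest node within the snap radius, else ``None`` (logged)."""
        if not self._node_ids:
            return None
        d = np.hypot(self._coords[:, 0] - point[0], self._coords[:, 1] - point[1])
        i = int(np.argmin(d))
        if d[i] > self.snap_radius:
            logger.warning("point %s is %.2f units from the nearest %s node (radius %.2f); unreachable",
                           point, d[i], self.mode, self.snap_radius)
            return None
        return self._node_ids[i]

    def node_point(self, node_id: str) -> tuple[float, float]:
        data = self.graph.nodes[node_id]
        return (data["x"], data["y"])

    def times_from(self, source: str) -> dict[str, float]:
        """Dijkstra travel times from a node to every reachable node."""
        return nx.single_source_dijkstra_path_length(self.graph, source, weight="minutes")


@dataclass(frozen=True)
class TransitLine:
    """An ordered stop sequence with per-segment in-vehicle minutes and a headway."""

    line_id: str
    stops: tuple[str, ...]
    segment_minutes: tuple[float, ...]
    headway: float
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if len(self.stops) < 2 or len(self.segment_minutes) != len(self.stops) - 1:
            raise ConfigurationError(f"line {self.line_id!r}: need n stops and n-1 segment times")
        if not self.headway > 0:
            raise ConfigurationError(f"line {self.line_id!r}: headway must be > 0")
        if any(m < 0 for m in self.segment_minutes):
            raise ConfigurationError(f"line {self.line_id!r}: segment minutes must be >= 0")


@dataclass
class TransitNetwork:
    """Transit stops and lines layered over a walk network for access/egress.

    ``max_access_walk_min`` caps the walking leg to the boarding stop and from
    the alighting stop; ``walk_cap_min`` caps the pure-walk fallback (default
    unlimited, so walking is always available as an alternative).
    """

    stops: dict[str, tuple[float, float]]
    lines: list[TransitLine]
    walk: ModeNetwork
    max_access_walk_min: float = 15.0
    walk_cap_min: float = math.inf
    _stop_walk_cache: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for line in self.lines:
            unknown = [s for s in line.stops if s not in self.stops]
            if unknown:
                raise ConfigurationError(f"line {line.line_id!r} references unknown stops {unknown}")

    def walk_minutes_from_stop(self, stop_id: str) -> dict[str, float]:
        """Walk times from a stop to every walk-network node (cached)."""
        if stop_id not in self._stop_walk_cache:
            node = self.walk.snap(self.stops[stop_id])
            self._stop_walk_cache[stop_id] = {} if node is None else self.walk.times_from(node)
        return self._stop_walk_cache[stop_id]


def shortest_time(
    network: ModeNetwork,
    origin: tuple[float, float] | str,
    destination: tuple[float, float] | str,
) -> float:
    """Minimal path time in minutes between two points (or node IDs).

    Points snap to the nearest node within the snap radius; an unsnappable
    point or a disconnected pair yields ``+inf``.
    """
    o = origin if isinstance(origin, str) else network.snap(origin)
    d = destination if isinstance(destination, str) else network.snap(destination)
    if o is None or d is None:
        return math.inf
    try:
        return float(nx.dijkstra_path_length(network.graph, o, d, weight="minutes"))
    except nx.NetworkXNoPath:
        return math.inf


def _line_leg_minutes(line: TransitLine, i: int, j: int) -> float:
    """In-vehicle minutes from stop index i to j along the line, or inf."""
    if i < j:
        return float(sum(line.segment_minutes[i:j]))
    if i > j and line.bidirectional:
        return float(sum(line.segment_minutes[j:i]))
    return math.inf


def transit_time(
    network: TransitNetwork,
    origin: tuple[float, float],
    destination: tuple[float, float],
) -> float:
    """Door-to-door transit time with walk access/egress and expected wait.

    Minimises walk(origin, board) + headway/2 + in-vehicle(board, alight) +
    walk(alight, destination) over all single-line stop pairs whose walking
    legs stay within ``max_access_walk_min``, then takes the smaller of that
    and the pure walk time (subject to ``walk_cap_min``).
    """
    walk_net = network.walk
    pure_walk = shortest_time(walk_net, origin, destination)
    best = pure_walk if pure_walk <= network.walk_cap_min else math.inf

    o_node = walk_net.snap(origin)
    d_node = walk_net.snap(destination)
    if o_node is None or d_node is None:
        return best
    from_origin = walk_net.times_from(o_node)

    for line in network.lines:
        # walk legs per stop of this line
        access = []
        egress = []
        for s in line.stops:
            stop_node = walk_net.snap(network.stops[s])
            access.append(math.inf if stop_node is None else from_origin.get(stop_node, math.inf))
            egress.append(network.walk_minutes_from_stop(s).get(d_node, math.inf))
        for i in range(len(line.stops)):
            if access[i] > network.max_access_walk_min:
                continue
            for j in range(len(line.stops)):
                if i == j or egress[j] > network.max_access_walk_min:
                    continue
                ride = _line_leg_minutes(line, i, j)
                if not math.isfinite(ride):
                    continue
                cand = access[i] + line.headway / 2.0 + ride + egress[j]
                if cand < best:
                    best = cand
    return best


def build_matrix(
    network: ModeNetwork | TransitNetwork,
    origins: Sequence[AreaUnit],
    destinations: Sequence[ProviderSite],
) -> TravelTimeMatrix:
    """Origin-destination matrix of shortest/transit times in list order.

    An empty destination list yields a valid zero-column matrix; an empty
    origin list is an error.
    """
    if not origins:
        raise ConfigurationError("origin list must be nonempty")
    origin_ids = [a.area_id for a in origins]
    dest_ids = [s.site_id for s in destinations]
    minutes = np.full((len(origins), len(destinations)), math.inf)

    if isinstance(network, TransitNetwork):
        for i, a in enumerate(origins):
            for j, s in enumerate(destinations):
                minutes[i, j] = transit_time(network, (a.x, a.y), (s.x, s.y))
        return TravelTimeMatrix("transit", origin_ids, dest_ids, minutes)

    # single-mode: one Dijkstra sweep per distinct snapped origin node
    dest_nodes = [network.snap((s.x, s.y)) for s in destinations]
    sweep_cache: dict[str, dict[str, float]] = {}
    for i, a in enumerate(origins):
        o_node = network.snap((a.x, a.y))
        if o_node is None:
            continue
        if o_node not in sweep_cache:
            sweep_cache[o_node] = network.times_from(o_node)
        times = sweep_cache[o_node]
        for j, d_node in enumerate(dest_nodes):
            if d_node is not None:
                minutes[i, j] = times.get(d_node, math.inf)
    return TravelTimeMatrix(network.mode, origin_ids, dest_ids, minutes)
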