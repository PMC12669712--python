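"""Signed-PPI route enumeration and ranked-list alignment scoring.

Parses a SIGNOR-dialect signed interaction table into a directed graph,
enumerates simple directed routes from a source protein (e.g. KSR1) to a
target (e.g. YAP1), and scores each route against a ranked protein list
with three disjoint criteria:

* c1 — route nodes that appear in the ranked list;
* c2 — ranked proteins not on the route but adjacent (one edge, either
  direction) to at least one route node;
* c3 — ranked proteins not already counted that are reachable from a route
  node through exactly one mediator node (two edges, either direction).

Each ranked protein is counted once, in the lowest-numbered applicable
criterion; the total is the unweighted sum c1 + c2 + c3.  Edge signs are
parsed and retained but do not enter the score; an activation-only edge
filter is available for sign-restricted route enumeration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNKNOWN = "unknown"

REQUIRED_COLUMNS = ("entity_a", "entity_b", "effect")


@dataclass(frozen=True)
class RouteScore:
    """Three-criterion alignment of a route with a ranked protein list."""

    c1: int
    c2: int
    c3: int

    @property
    def total(self) -> int:
        return self.c1 + self.c2 + self.c3


def _parse_effect(effect: str) -> str:
    e = str(effect).lower()
    if "up-regulates" in e or "activat" in e:
        return ACTIVATION
    if "down-regulates" in e or "inhib" in e:
        return INHIBITION
    return UNKNOWN


def read_signor(edge_file) -> nx.DiGraph:
    """Read a SIGNOR-dialect TSV (entity_a, entity_b, effect) into a digraph.

    Gene symbols are upper-cased; duplicate rows are deduplicated; parallel
    edges with different effects collapse to one edge whose ``signs``
    attribute is the frozenset of observed signs; self-loops are dropped
    (count logged).  Extra columns are ignored.
    """
    frame = pd.read_csv(edge_file, sep="\t", dtype=str)
    if frame.empty and frame.columns.size == 0:
        raise ValueError(f"empty interaction file: {edge_file}")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"interaction file missing mandatory column(s): {missing}"
        )
    if frame.empty:
        raise ValueError(f"interaction file has no data rows: {edge_file}")
    g = nx.DiGraph()
    dropped = 0
    for a, b, eff in frame[list(REQUIRED_COLUMNS)].itertuples(index=False):
        u, v = str(a).strip().upper(), str(b).strip().upper()
        if u == v:
            dropped += 1
            continue
        sign = _parse_effect(eff)
        if g.has_edge(u, v):
            g[u][v]["signs"] = g[u][v]["signs"] | {sign}
        else:
            g.add_edge(u, v, signs=frozenset({sign}))
    if dropped:
        logger.info("dropped %d self-loop row(s)", dropped)
    return g


def enumerate_routes(
    graph: nx.DiGraph,
    source: str,
    target: str,
    max_len: int = 4,
    max_routes: int = 100_000,
    require_signs: frozenset[str] | None = None,
) -> tuple[list[list[str]], bool]:
    """All simple directed paths source->target with at most ``max_len`` edges.

    Routes are returned in deterministic order (length, then lexicographic
    node sequence).  The enumeration stops after ``max_routes`` paths and
    reports truncation via the second return value.  ``require_signs``
    restricts route edges to those carrying at least one of the given signs
    (e.g. ``{"activation"}``).
    """
    source, target = source.upper(), target.upper()
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in graph:
            raise ValueError(f"node {node!r} not in graph")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if require_signs is not None:
        keep = [
            (u, v) for u, v, d in graph.edges(data=True)
            if d.get("signs", frozenset()) & require_signs
        ]
        graph = graph.edge_subgraph(keep).copy()
        if source not in graph or target not in graph:
            return [], False
    routes = []
    truncated = False
    for path in nx.all_simple_paths(graph, source, target, cutoff=max_len):
        routes.append(list(path))
        if len(routes) > max_routes:
            truncated = True
            routes = routes[:max_routes]
            break
    routes.sort(key=lambda p: (len(p), p))
    return routes, truncated


def score_route(
    route: list[str], graph: nx.DiGraph, ranked: list[str]
) -> RouteScore:
    """Score one route against a ranked protein list (c1, c2, c3).

    Adjacency for c2 and c3 ignores edge direction.  The criteria are
    disjoint: a ranked protein on the route is only c1, a ranked neighbour
    only c2, and c3 collects remaining ranked proteins at undirected
    distance two from a route node.
    """
    route_set = {n.upper() for n in route}
    for u, v in zip(route, route[1:]):
        if not graph.has_edge(u.upper(), v.upper()):
            raise ValueError(f"route edge {u}->{v} not in graph")
    ranked_set = {p.upper() for p in ranked}
    und = graph.to_undirected(as_view=True)

    dist1: set[str] = set()
    for n in route_set:
        if n in und:
            dist1.update(und.neighbors(n))
    dist1 -= route_set
    dist2: set[str] = set()
    for m in dist1 | route_set:
        if m in und:
            dist2.update(und.neighbors(m))
    dist2 -= route_set | dist1

    c1 = len(ranked_set & route_set)
    c2 = len(ranked_set & dist1)
    c3 = len(ranked_set & dist2)
    return RouteScore(c1=c1, c2=c2, c3=c3)


def rank_routes_identify_hub(
    routes: list[list[str]],
    scores: list[RouteScore],
    top_k: int = 20,
) -> tuple[list[tuple[list[str], RouteScore]], set[str]]:
    """Order routes by (total desc, length asc, lexicographic) and find hubs.

    The hub set holds the interior (non-terminal) node(s) occurring most
    often among the top ``top_k`` routes; ties are reported together.  An
    empty route list is an error.
    """
    if not routes:
        raise ValueError("no routes to rank")
    if len(routes) != len(scores):
        raise ValueError("routes and scores must align")
    order = sorted(
        zip(routes, scores),
        key=lambda rs: (-rs[1].total, len(rs[0]), rs[0]),
    )
    top = order[:top_k]
    counts: dict[str, int] = {}
    for route, _ in top:
        for node in route[1:-1]:
            counts[node] = counts.get(node, 0) + 1
    if not counts:
        return order, set()
    best = max(counts.values())
    hubs = {n for n, c in counts.items() if c == best}
    return order, hubs


def routes_to_frame(
    ranked_routes: list[tuple[list[str], RouteScore]]
) -> pd.DataFrame:
    """Tabulate ranked routes: comma-joined node path plus c1/c2/c3/total."""
    rows = [
        (",".join(route), len(route) - 1, s.c1, s.c2, s.c3, s.total)
        for route, s in ranked_routes
    ]
    return pd.DataFrame(
        rows, columns=["route", "length", "c1", "c2", "c3", "total"]
    )


def brute_force_routes(
    graph: nx.DiGraph, source: str, target: str, max_len: int
) -> list[list[str]]:
    """Exhaustive simple-path enumeration by permutation of interior nodes.

    Independent oracle for :func:`enumerate_routes`: tries every ordered
    subset of candidate interior nodes (feasible only for small graphs).
    """
    others = [n for n in graph.nodes if n not in (source, target)]
    found = []
    for k in range(0, max_len):
        for interior in itertools.permutations(others, k):
            path = [source, *interior, target]
            if all(graph.has_edge(u, v) for u, v in zip(path, path[1:])):
                found.append(path)
    found.sort(key=lambda p: (len(p), p))
    return found
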