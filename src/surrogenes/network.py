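"""Scored interaction graphs, shortest paths, and bridge-gene subnetworks.

The background network follows the STRING flat-file convention: an
undirected edge list ``protein1 protein2 combined_score`` with integer
confidence scores in [0, 1000].  Shortest paths between every pair of
seed (selected surrogate) genes are computed with Dijkstra's algorithm;
the union of those paths forms the reported sub-network, and its
non-seed nodes are the bridging genes — interaction partners that lie
between the surrogates and are candidates for co-acting factors.

Two edge-weight modes are supported: ``hop`` (every edge weighs 1, so a
shortest path minimizes the intermediate count) and ``score`` (weight =
1 - combined_score/1000, so high-confidence edges are cheap).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("hop", "score")
DEFAULT_SCORE_THRESHOLD = 400  # STRING "medium confidence"

#: Tolerance for comparing accumulated float path weights in score mode.
_W_TOL = 1e-9


class EdgeFileParseError(ValueError):
    """Raised on a malformed edge-list line (carries the line number)."""


class MissingNodeError(KeyError):
    """Raised when a path endpoint is absent from the graph."""


class InsufficientSeedsError(ValueError):
    """Raised when fewer than two seed genes can be resolved in the graph."""


@dataclasses.dataclass
class InteractionGraph:
    """Undirected scored interaction network.

    Scores live on edges as the integer attribute ``score``; at most one
    edge per node pair (duplicates collapse to the maximum score), no
    self-loops.
    """

    graph: nx.Graph
    weight_mode: str = "hop"

    def __post_init__(self) -> None:
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"unknown weight_mode: {self.weight_mode!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: str, v: str) -> float:
        if self.weight_mode == "hop":
            return 1.0
        return 1.0 - self.graph[u][v]["score"] / 1000.0

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"protein1": min(u, v), "protein2": max(u, v), "combined_score": d["score"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        frame = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
        return frame.sort_values(["protein1", "protein2"]).reset_index(drop=True)


@dataclasses.dataclass
class SubnetworkResult:
    """Union of seed-pair shortest paths and the resulting bridge genes."""

    seed_genes: list[str]
    paths: pd.DataFrame  # columns: source, target, length, path ("a|b|c")
    nodes: set[str]
    edges: list[tuple[str, str, int]]
    bridge_genes: set[str]
    unresolved_pairs: list[tuple[str, str, str]]  # (source, target, reason)


def build_graph(
    edges: Sequence[tuple[str, str, int]],
    weight_mode: str = "hop",
) -> InteractionGraph:
    """Assemble an :class:`InteractionGraph` from (u, v, score) triples.

    Self-loops are dropped; duplicate pairs keep the maximum score;
    scores outside [0, 1000] are rejected.
    """
    g = nx.Graph()
    for u, v, score in edges:
        u, v, score = str(u), str(v), int(score)
        if not 0 <= score <= 1000:
            raise ValueError(f"combined_score {score} outside [0, 1000]")
        if u == v:
            logger.debug("dropping self-loop on %s", u)
            continue
        if g.has_edge(u, v):
            g[u][v]["score"] = max(g[u][v]["score"], score)
        else:
            g.add_edge(u, v, score=score)
    return InteractionGraph(graph=g, weight_mode=weight_mode)


def load_interactions(
    edge_file,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
    weight_mode: str = "hop",
) -> InteractionGraph:
    """Read a STRING-convention edge list, dropping low-confidence edges.

    Lines are whitespace-separated ``protein1 protein2 combined_score``
    records; a leading header line (third field not an integer, as in
    STRING ``protein.links`` files) is skipped.  Edges with score below
    ``score_threshold`` are discarded; the node set is the endpoints of
    the retained edges.
    """
    if score_threshold < 0:
        raise ValueError("score_threshold must be nonnegative")
    path = Path(edge_file)
    triples: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise EdgeFileParseError(
                    f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            u, v, score_s = parts
            try:
                score = int(score_s)
            except ValueError:
                if lineno == 1:  # STRING files carry a header row
                    continue
                raise EdgeFileParseError(
                    f"{path}:{lineno}: non-integer score {score_s!r}") from None
            if not 0 <= score <= 1000:
                raise EdgeFileParseError(
                    f"{path}:{lineno}: score {score} outside [0, 1000]")
            if score >= score_threshold:
                triples.append((u, v, score))
    g = build_graph(triples, weight_mode=weight_mode)
    logger.info("loaded %d edges on %d nodes from %s (threshold %d)",
                g.n_edges, g.n_nodes, path, score_threshold)
    return g


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def _weight_fn(igraph: InteractionGraph):
    if igraph.weight_mode == "hop":
        return lambda u, v, d: 1.0
    return lambda u, v, d: 1.0 - d["score"] / 1000.0


def shortest_path(
    igraph: InteractionGraph,
    source: str,
    target: str,
) -> tuple[list[str] | None, float]:
    """Dijkstra shortest path; deterministic among equal-weight paths.

    Returns ``(node_sequence, length)``; among all minimum-weight paths
    the lexicographically smallest node sequence is returned.  A
    disconnected pair yields ``(None, inf)`` rather than an error, so
    callers can record it and continue.
    """
    g = igraph.graph
    for node in (source, target):
        if node not in g:
            raise MissingNodeError(f"node {node!r} not in graph")
    if source == target:
        return [source], 0.0
    weight = _weight_fn(igraph)
    dist = nx.single_source_dijkstra_path_length(g, target, weight=weight)
    if source not in dist:
        return None, math.inf
    # Greedy reconstruction: at each step take the lexicographically
    # smallest neighbor that stays on some shortest path to the target.
    path = [source]
    current = source
    visited = {source}
    while current != target:
        feasible = [
            v for v in g.neighbors(current)
            if v in dist and v not in visited
            and abs(weight(current, v, g[current][v]) + dist[v] - dist[current])
            <= _W_TOL * (1 + abs(dist[current]))
        ]
        if not feasible:  # zero-weight plateau dead end; fall back
            rest = nx.dijkstra_path(g, current, target, weight=weight)
            path.extend(rest[1:])
            break
        nxt = min(feasible)
        path.append(nxt)
        visited.add(nxt)
        current = nxt
    length = dist[source]
    if igraph.weight_mode == "hop":
        length = int(round(length))
    return path, float(length)


def build_subnetwork(
    igraph: InteractionGraph,
    seed_genes: Sequence[str],
    all_shortest: bool = False,
) -> SubnetworkResult:
    """Union of shortest paths over every unordered pair of seed genes.

    Seeds absent from the graph and disconnected pairs are recorded in
    ``unresolved_pairs`` with a logged warning; at least two seeds must
    resolve.  ``bridge_genes`` is the union node set minus the seeds.
    With ``all_shortest=True`` every minimum-weight path per pair is
    unioned into the sub-network (the reported per-pair path stays the
    deterministic lexicographic representative).
    """
    seeds: list[str] = []
    for s in seed_genes:
        s = str(s)
        if s not in seeds:
            seeds.append(s)
    if len(seeds) < 2:
        raise InsufficientSeedsError("need at least 2 distinct seed genes")

    g = igraph.graph
    present = [s for s in seeds if s in g]
    for s in seeds:
        if s not in g:
            logger.warning("seed gene %r not present in graph", s)
    if len(present) < 2:
        raise InsufficientSeedsError(
            f"only {len(present)} of {len(seeds)} seed genes found in graph")

    weight = _weight_fn(igraph)
    nodes: set[str] = set()
    edge_set: set[tuple[str, str]] = set()
    path_rows = []
    unresolved: list[tuple[str, str, str]] = []

    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            a, b = seeds[i], seeds[j]
            if a not in g or b not in g:
                unresolved.append((a, b, "missing endpoint"))
                continue
            path, length = shortest_path(igraph, a, b)
            if path is None:
                logger.warning("no path between seeds %r and %r", a, b)
                unresolved.append((a, b, "disconnected"))
                continue
            reps = [path]
            if all_shortest:
                reps = [list(p) for p in
                        nx.all_shortest_paths(g, a, b, weight=weight)]
            for p in reps:
                nodes.update(p)
                for u, v in zip(p, p[1:]):
                    edge_set.add((min(u, v), max(u, v)))
            path_rows.append({
                "source": a, "target": b,
                "length": length, "path": "|".join(path),
            })

    if not path_rows:
        raise InsufficientSeedsError("no seed pair could be connected")
    edges = sorted(
        (u, v, int(g[u][v]["score"])) for u, v in edge_set
    )
    paths = pd.DataFrame(path_rows,
                         columns=["source", "target", "length", "path"])
    return SubnetworkResult(
        seed_genes=seeds,
        paths=paths,
        nodes=nodes,
        edges=edges,
        bridge_genes=nodes - set(seeds),
        unresolved_pairs=unresolved,
    )
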