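"""Weighted node metrics of a daily OD network.

Three per-area metrics summarise each day's mobility network:

* **strength** ``s_i = sum_j A_ij w_ij`` — the weighted degree, i.e. the
  number of trips starting or ending in area *i* (self trips excluded);

* **weighted betweenness** ``BC_i = sum_{q != k != i} sigma_qk(i) / sigma_qk``
  over ordered pairs, where ``sigma_qk`` counts minimum-cost paths between
  *q* and *k* and ``sigma_qk(i)`` those with *i* strictly interior.  Edge
  weights are trip counts — similarities — so the default cost of traversing
  an edge is ``1/w_ij``: heavily used connections are "short".  The raw sum
  is divided by ``(N-1)(N-2)`` which bounds the result in [0, 1];

* **weighted clustering** in the Barrat form
  ``C_i = 1/(s_i (k_i - 1)) * sum_{(j,h)} (w_ij + w_ih)/2`` over ordered
  neighbour pairs (j, h) of *i* that close a triangle.  It lies in [0, 1],
  equals 1 on any complete graph, and reduces to the ordinary local
  clustering coefficient when all weights are equal.

Brute-force reference implementations (:func:`naive_betweenness` by
exhaustive simple-path enumeration, :func:`naive_clustering` by triangle
enumeration) are provided for testing; they share no code with the fast
paths.
"""

from __future__ import annotations

import datetime as dt
import itertools
from heapq import heappush, heappop
from typing import Callable, Literal, Mapping

import networkx as nx
import pandas as pd

from .network_builder import DailyNetwork

CostTransform = Literal["inverse-weight", "unit"]
ClusteringVariant = Literal["barrat", "printed"]

#: Path costs closer than this are treated as ties (all tied minimum-cost
#: paths count toward sigma); absorbs floating-point accumulation error.
COST_TOL = 1e-12


def _cost_fn(cost: CostTransform) -> Callable[[float], float]:
    if cost == "inverse-weight":
        return lambda w: 1.0 / w
    if cost == "unit":
        return lambda w: 1.0
    raise ValueError(f"unknown cost transform: {cost!r}")


def strength(net: DailyNetwork) -> dict[int, float]:
    """Weighted degree per node; isolated nodes map to 0."""
    s = dict.fromkeys(net.graph.nodes, 0.0)
    for u, v, w in net.graph.edges(data="weight"):
        s[u] += w
        s[v] += w
    return {int(k): float(v) for k, v in s.items()}


def degree(net: DailyNetwork) -> dict[int, int]:
    return {int(n): int(d) for n, d in net.graph.degree()}


def weighted_betweenness(
    net: DailyNetwork, cost: CostTransform = "inverse-weight"
) -> dict[int, float]:
    """Normalized weighted betweenness centrality per node.

    Brandes' accumulation over Dijkstra shortest-path DAGs, with minimum-cost
    ties counted within :data:`COST_TOL`.  Pairs in different components
    contribute nothing; the normalizer stays ``(N-1)(N-2)`` with *N* the whole
    network's node count.  Raises on non-positive edge weights.
    """
    g = net.graph
    for u, v, w in g.edges(data="weight"):
        if w <= 0:
            raise ValueError(f"non-positive weight {w} on edge ({u}, {v})")
    cf = _cost_fn(cost)
    bc = dict.fromkeys(g.nodes, 0.0)
    for s in g.nodes:
        order, preds, sigma = _dijkstra_census(g, s, cf)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    n = net.N
    if n < 3:
        return {int(v): 0.0 for v in bc}
    norm = (n - 1) * (n - 2)
    return {int(v): float(b) / norm for v, b in bc.items()}


def _dijkstra_census(
    g: nx.Graph, source, cf: Callable[[float], float]
) -> tuple[list, dict, dict]:
    """Single-source Dijkstra with shortest-path counting.

    Returns nodes in nondecreasing final-distance order, predecessor lists on
    the shortest-path DAG, and path counts sigma.
    """
    dist: dict = {}
    seen = {source: 0.0}
    sigma = {source: 1.0}
    preds: dict = {source: []}
    counter = itertools.count()
    heap: list = [(0.0, next(counter), source)]
    order: list = []
    while heap:
        d, _, v = heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        order.append(v)
        for w, attrs in g[v].items():
            vw = d + cf(attrs["weight"])
            if w in dist:
                continue
            if w not in seen or vw < seen[w] - COST_TOL:
                seen[w] = vw
                sigma[w] = sigma[v]
                preds[w] = [v]
                heappush(heap, (vw, next(counter), w))
            elif abs(vw - seen[w]) <= COST_TOL:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, preds, sigma


def weighted_clustering(
    net: DailyNetwork, variant: ClusteringVariant = "barrat"
) -> dict[int, float]:
    """Weighted local clustering coefficient per node.

    ``barrat`` (default) credits each triangle at *i* with the mean weight of
    the two edges *incident to i*; ``printed`` uses the mean of the *i–j* and
    *j–h* edges instead — an alternative reading that is not bounded by 1 and
    is kept only for comparison.  Nodes with degree <= 1 map to 0.
    """
    if variant not in ("barrat", "printed"):
        raise ValueError(f"unknown clustering variant: {variant!r}")
    g = net.graph
    out: dict[int, float] = {}
    for i in g.nodes:
        nbrs = list(g[i])
        k = len(nbrs)
        if k <= 1:
            out[int(i)] = 0.0
            continue
        s_i = sum(g[i][j]["weight"] for j in nbrs)
        acc = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if not g.has_edge(j, h):
                continue
            if variant == "barrat":
                # ordered pairs (j,h) and (h,j) each contribute (w_ij+w_ih)/2
                acc += g[i][j]["weight"] + g[i][h]["weight"]
            else:
                w_jh = g[j][h]["weight"]
                acc += (g[i][j]["weight"] + w_jh) / 2.0 + (g[i][h]["weight"] + w_jh) / 2.0
        out[int(i)] = acc / (s_i * (k - 1))
    return out


def compute_all(
    net: DailyNetwork,
    cost: CostTransform = "inverse-weight",
    variant: ClusteringVariant = "barrat",
) -> pd.DataFrame:
    """Per-node metric table for one day: date, area, s, k, BC, C.

    Rows are ordered by area code; an empty network yields an empty frame.
    """
    s = strength(net)
    k = degree(net)
    bc = weighted_betweenness(net, cost=cost)
    c = weighted_clustering(net, variant=variant)
    areas = sorted(net.graph.nodes)
    return pd.DataFrame(
        {
            "date": [net.date] * len(areas),
            "area": [int(a) for a in areas],
            "s": [s[a] for a in areas],
            "k": [k[a] for a in areas],
            "BC": [bc[a] for a in areas],
            "C": [c[a] for a in areas],
        }
    )


def metrics_table(
    nets: Mapping[dt.date, DailyNetwork],
    cost: CostTransform = "inverse-weight",
    variant: ClusteringVariant = "barrat",
) -> pd.DataFrame:
    """Concatenated :func:`compute_all` over days, sorted by (date, area)."""
    frames = [compute_all(nets[d], cost=cost, variant=variant) for d in sorted(nets)]
    if not frames:
        return pd.DataFrame(columns=["date", "area", "s", "k", "BC", "C"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# brute-force reference implementations (for tests; exponential time)

def naive_betweenness(
    net: DailyNetwork, cost: CostTransform = "inverse-weight"
) -> dict[int, float]:
    """Betweenness by exhaustive enumeration of all simple paths.

    For every ordered pair (q, k) all simple paths are enumerated, the
    minimum-cost set is identified (ties within 1e-9), and each strictly
    interior node is credited.  Only feasible on very small graphs.
    """
    g = net.graph
    cf = _cost_fn(cost)
    raw = dict.fromkeys(g.nodes, 0.0)
    for q, k in itertools.permutations(g.nodes, 2):
        paths = list(nx.all_simple_paths(g, q, k))
        if not paths:
            continue
        costs = [sum(cf(g[a][b]["weight"]) for a, b in zip(p, p[1:])) for p in paths]
        best = min(costs)
        minimal = [p for p, c in zip(paths, costs) if c <= best + 1e-9]
        for p in minimal:
            for node in p[1:-1]:
                raw[node] += 1.0 / len(minimal)
    n = net.N
    if n < 3:
        return {int(v): 0.0 for v in raw}
    return {int(v): b / ((n - 1) * (n - 2)) for v, b in raw.items()}


def naive_clustering(net: DailyNetwork) -> dict[int, float]:
    """Barrat clustering by direct triangle enumeration."""
    g = net.graph
    out: dict[int, float] = {}
    for i in g.nodes:
        nbrs = list(g[i])
        if len(nbrs) <= 1:
            out[int(i)] = 0.0
            continue
        s_i = sum(g[i][j]["weight"] for j in nbrs)
        total = 0.0
        for j, h in itertools.permutations(nbrs, 2):  # ordered pairs
            if g.has_edge(j, h):
                total += (g[i][j]["weight"] + g[i][h]["weight"]) / 2.0
        out[int(i)] = total / (s_i * (len(nbrs) - 1))
    return out
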