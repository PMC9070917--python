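"""Aggregation of trip records into daily weighted undirected OD networks.

Two community areas are connected on a given day if at least one taxi trip
ran between them that day, in either direction; the edge weight is the total
number of such trips.  Same-area (self) trips never form edges — shortest
paths and triangles are undefined for self-loops — but are retained in a
separate per-node count so that daily trip totals are conserved.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import networkx as nx
import pandas as pd

NodePolicy = Literal["active-only", "all-areas"]

ALL_AREAS = range(1, 78)


@dataclass
class DailyNetwork:
    """Weighted undirected network of community areas for one calendar day."""

    date: dt.date
    graph: nx.Graph
    self_trips: dict[int, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Network size: number of nodes (depends on the node policy used)."""
        return self.graph.number_of_nodes()

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    def weight(self, i: int, j: int) -> int:
        """Trip count on edge {i, j}; 0 if absent. Symmetric by construction."""
        data = self.graph.get_edge_data(i, j)
        return 0 if data is None else int(data["weight"])

    def edges(self) -> Iterator[tuple[int, int, int]]:
        """Yield (i, j, weight) with i < j."""
        for u, v, w in self.graph.edges(data="weight"):
            i, j = (u, v) if u < v else (v, u)
            yield i, j, int(w)

    def total_trips(self) -> int:
        """Edge weights plus self trips: the day's trip count."""
        return sum(w for *_, w in self.edges()) + sum(self.self_trips.values())


def build_daily_networks(
    trips: pd.DataFrame, node_policy: NodePolicy = "active-only"
) -> dict[dt.date, DailyNetwork]:
    """Aggregate a trip table into one :class:`DailyNetwork` per pickup date.

    Every trip must carry both area codes; a missing code here is a contract
    violation (filter upstream) and raises :class:`ValueError`.  Under
    ``active-only`` the nodes of a day are the areas appearing in at least
    one trip that day (including self trips); under ``all-areas`` every code
    1..77 is a node every day, isolated or not.
    """
    if node_policy not in ("active-only", "all-areas"):
        raise ValueError(f"unknown node policy: {node_policy!r}")
    if trips["pickup_area"].isna().any() or trips["dropoff_area"].isna().any():
        n_bad = int(
            (trips["pickup_area"].isna() | trips["dropoff_area"].isna()).sum()
        )
        raise ValueError(
            f"{n_bad} trips with missing community-area codes reached the "
            "network builder; filter them out first"
        )

    df = pd.DataFrame(
        {
            "date": trips["pickup_time"].dt.date,
            "a": trips["pickup_area"].astype(int),
            "b": trips["dropoff_area"].astype(int),
        }
    )
    lo = df[["a", "b"]].min(axis=1)
    hi = df[["a", "b"]].max(axis=1)
    df["i"], df["j"] = lo, hi

    networks: dict[dt.date, DailyNetwork] = {}
    for day, group in df.groupby("date", sort=True):
        pair_counts = group.groupby(["i", "j"]).size()
        g = nx.Graph()
        self_trips: dict[int, int] = {}
        for (i, j), w in pair_counts.items():
            if i == j:
                self_trips[int(i)] = int(w)
            else:
                g.add_edge(int(i), int(j), weight=int(w))
        g.add_nodes_from(int(z) for z in self_trips)
        if node_policy == "all-areas":
            g.add_nodes_from(ALL_AREAS)
        networks[day] = DailyNetwork(date=day, graph=g, self_trips=self_trips)
    return networks


# ---------------------------------------------------------------------------
# persistence

def write_graphml(net: DailyNetwork, path: str | Path) -> None:
    """Write one daily network as GraphML (node attr ``area`` and
    ``self_trips``, edge attr ``weight``, graph attr ``date``)."""
    g = nx.Graph()
    g.graph["date"] = net.date.isoformat()
    for node in sorted(net.graph.nodes):
        g.add_node(node, area=int(node), self_trips=int(net.self_trips.get(node, 0)))
    for i, j, w in sorted(net.edges()):
        g.add_edge(i, j, weight=w)
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> DailyNetwork:
    raw = nx.read_graphml(path)
    g = nx.Graph()
    self_trips: dict[int, int] = {}
    for _, attrs in raw.nodes(data=True):
        code = int(attrs["area"])
        g.add_node(code)
        st = int(attrs.get("self_trips", 0))
        if st:
            self_trips[code] = st
    for u, v, attrs in raw.edges(data=True):
        g.add_edge(int(raw.nodes[u]["area"]), int(raw.nodes[v]["area"]),
                   weight=int(attrs["weight"]))
    return DailyNetwork(
        date=dt.date.fromisoformat(raw.graph["date"]), graph=g, self_trips=self_trips
    )


def networks_to_frame(nets: Mapping[dt.date, DailyNetwork]) -> pd.DataFrame:
    """Long-format edge list over days: columns date, i, j, weight.

    Self-trip counts appear as rows with ``i == j`` so the frame conserves
    trip totals; isolated nodes are recorded with ``j = -1, weight = 0``.
    """
    rows: list[tuple[dt.date, int, int, int]] = []
    for day in sorted(nets):
        net = nets[day]
        linked: set[int] = set()
        for i, j, w in sorted(net.edges()):
            rows.append((day, i, j, w))
            linked.update((i, j))
        for i, c in sorted(net.self_trips.items()):
            rows.append((day, i, i, c))
            linked.add(i)
        for i in sorted(net.nodes - linked):
            rows.append((day, i, -1, 0))
    return pd.DataFrame(rows, columns=["date", "i", "j", "weight"])


def frame_to_networks(frame: pd.DataFrame) -> dict[dt.date, DailyNetwork]:
    """Inverse of :func:`networks_to_frame`."""
    out: dict[dt.date, DailyNetwork] = {}
    for day, group in frame.groupby("date", sort=True):
        if isinstance(day, str):
            day = dt.date.fromisoformat(day)
        elif isinstance(day, pd.Timestamp):
            day = day.date()
        g = nx.Graph()
        self_trips: dict[int, int] = {}
        for _, r in group.iterrows():
            i, j, w = int(r["i"]), int(r["j"]), int(r["weight"])
            if j == -1:
                g.add_node(i)
            elif i == j:
                self_trips[i] = w
                g.add_node(i)
            else:
                g.add_edge(i, j, weight=w)
        out[day] = DailyNetwork(date=day, graph=g, self_trips=self_trips)
    return out
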