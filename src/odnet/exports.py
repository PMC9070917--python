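"""Export products: annotated GraphML snapshots, choropleth-ready GeoJSON,
and the end-to-end pipeline runner.

Only the data products are contract-bound; styling (colors, layouts) is the
consumer's business.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from shapely.geometry import mapping

from . import metrics as metrics_mod
from . import synthetic_data, timeseries, trip_io
from .network_builder import (
    DailyNetwork,
    build_daily_networks,
    networks_to_frame,
)
from .trip_io import CommunityArea

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def export_snapshot(net: DailyNetwork, metrics: pd.DataFrame, path: str | Path) -> None:
    """Write a daily network as GraphML with per-node metric attributes.

    Node attributes: area, s, k, BC, C, self_trips; edge attribute: weight.
    The metric table must be for the network's date.
    """
    if not metrics.empty:
        meta_dates = {pd.Timestamp(d).date() for d in metrics["date"]}
        if meta_dates != {net.date}:
            raise ValueError(
                f"metrics dated {sorted(meta_dates)} do not match network date {net.date}"
            )
    by_area = metrics.set_index("area") if not metrics.empty else pd.DataFrame()
    g = nx.Graph()
    g.graph["date"] = net.date.isoformat()
    for node in sorted(net.graph.nodes):
        row = by_area.loc[node] if node in getattr(by_area, "index", []) else None
        g.add_node(
            node,
            area=int(node),
            s=float(row["s"]) if row is not None else 0.0,
            k=int(row["k"]) if row is not None else 0,
            BC=float(row["BC"]) if row is not None else 0.0,
            C=float(row["C"]) if row is not None else 0.0,
            self_trips=int(net.self_trips.get(node, 0)),
        )
    for i, j, w in sorted(net.edges()):
        g.add_edge(i, j, weight=int(w))
    nx.write_graphml(g, path)


def read_snapshot(path: str | Path) -> tuple[DailyNetwork, pd.DataFrame]:
    """Inverse of :func:`export_snapshot`."""
    raw = nx.read_graphml(path)
    date = dt.date.fromisoformat(raw.graph["date"])
    g = nx.Graph()
    self_trips: dict[int, int] = {}
    rows = []
    for _, attrs in sorted(raw.nodes(data=True), key=lambda t: int(t[1]["area"])):
        code = int(attrs["area"])
        g.add_node(code)
        if int(attrs.get("self_trips", 0)):
            self_trips[code] = int(attrs["self_trips"])
        rows.append(
            {
                "date": date,
                "area": code,
                "s": float(attrs.get("s", 0.0)),
                "k": int(attrs.get("k", 0)),
                "BC": float(attrs.get("BC", 0.0)),
                "C": float(attrs.get("C", 0.0)),
            }
        )
    for u, v, attrs in raw.edges(data=True):
        g.add_edge(int(raw.nodes[u]["area"]), int(raw.nodes[v]["area"]),
                   weight=int(attrs["weight"]))
    net = DailyNetwork(date=date, graph=g, self_trips=self_trips)
    cols = ["date", "area", "s", "k", "BC", "C"]
    return net, pd.DataFrame(rows, columns=cols)


def export_choropleth(
    areas: list[CommunityArea],
    metrics: pd.DataFrame,
    field_name: str,
    path: str | Path,
) -> None:
    """Write a GeoJSON FeatureCollection carrying one metric per area.

    Each feature's properties hold code, name and the metric value; for
    strength a log10 companion property is included.  Areas absent from the
    metric table get a null value; a metric row whose area has no geometry is
    an error naming the area.
    """
    aliases = {"s": "s", "strength": "s", "BC": "BC", "betweenness": "BC",
               "C": "C", "clustering": "C", "k": "k"}
    if field_name not in aliases:
        raise ValueError(f"unknown metric field: {field_name!r}")
    col = aliases[field_name]
    have_geo = {a.code for a in areas}
    if not metrics.empty:
        missing = sorted(set(metrics["area"].astype(int)) - have_geo)
        if missing:
            raise ValueError(f"no geometry for metric areas: {missing}")
        values = dict(zip(metrics["area"].astype(int), metrics[col].astype(float)))
    else:
        values = {}
    features = []
    for area in sorted(areas, key=lambda a: a.code):
        v = values.get(area.code)
        props = {"code": area.code, "name": area.name, col: v}
        if col == "s":
            props["s_log10"] = (
                math.log10(v) if v is not None and v > 0 else None
            )
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(area.geometry),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """End-to-end run configuration.

    Exactly one of ``trips_path`` (CSV in the configured dialect) or
    ``simulate`` (a :class:`~odnet.synthetic_data.SimConfig`) supplies the
    trips.  ``snapshot_dates`` selects days for annotated GraphML exports and
    choropleths (the latter need ``boundaries_path`` or synthetic
    boundaries).
    """

    out_dir: Path
    trips_path: Path | None = None
    dialect: trip_io.TripDialect = trip_io.CHICAGO_PORTAL
    simulate: synthetic_data.SimConfig | None = None
    boundaries_path: Path | None = None
    synthetic_boundaries: bool = False
    start: dt.date | None = None
    end: dt.date | None = None
    node_policy: str = "active-only"
    cost: str = "inverse-weight"
    clustering_variant: str = "barrat"
    n_breaks: int = 2
    min_segment: int = 7
    snapshot_dates: list[dt.date] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if (self.trips_path is None) == (self.simulate is None):
            raise ValueError("exactly one of trips_path or simulate must be set")
        if self.trips_path is not None and not Path(self.trips_path).exists():
            raise FileNotFoundError(f"trips file not found: {self.trips_path}")
        if self.boundaries_path is not None and not Path(self.boundaries_path).exists():
            raise FileNotFoundError(f"boundary file not found: {self.boundaries_path}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute ingest → build → metrics → series → segment → export.

    Writes all products under ``config.out_dir`` and returns the manifest
    (also written as ``manifest.json``).  Deterministic for fixed inputs,
    configuration and seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "node_policy": config.node_policy,
            "cost": config.cost,
            "clustering_variant": config.clustering_variant,
            "n_breaks": config.n_breaks,
            "min_segment": config.min_segment,
            "seed": config.seed,
            "sd_convention": "sample (n-1)",
        },
        "conventions": {
            "network": "undirected; edge weight = daily trip count between the "
                       "two areas in either direction; self trips kept separately",
            "betweenness": "minimum-cost paths with edge cost 1/weight unless "
                           "cost=unit; ordered-pair sum / ((N-1)(N-2))",
            "clustering": "Barrat weighted local clustering unless configured "
                          "to the alternative variant",
        },
        "inputs": {},
        "outputs": {},
    }

    @_stage("ingest")
    def ingest():
        if config.simulate is not None:
            cfg = dataclasses.replace(config.simulate, seed=config.seed)
            trips, truth = synthetic_data.generate_trips(cfg)
            truth.to_json(out / "ground_truth.json")
            manifest["inputs"]["simulate"] = {
                "n_zones": cfg.n_zones,
                "baseline_daily_trips": cfg.baseline_daily_trips,
                "shock_start": cfg.shock_start.isoformat(),
                "decline_days": cfg.decline_days,
                "residual_ratio": cfg.residual_ratio,
                "hub_extra_decline": cfg.hub_extra_decline,
                "seed": cfg.seed,
            }
            report = None
        else:
            trips, report = trip_io.read_trips(config.trips_path, config.dialect)
            manifest["inputs"]["trips_path"] = str(config.trips_path)
            manifest["inputs"]["ingest_report"] = report.as_dict()
        if config.start is not None and config.end is not None:
            trips = trip_io.filter_window(trips, config.start, config.end)
        complete = trips.dropna(subset=["pickup_area", "dropoff_area"])
        manifest["inputs"]["trips_used"] = int(len(complete))
        manifest["inputs"]["trips_missing_area"] = int(len(trips) - len(complete))
        return complete

    @_stage("build")
    def build(trips):
        return build_daily_networks(trips, node_policy=config.node_policy)

    @_stage("metrics")
    def compute(nets):
        return metrics_mod.metrics_table(
            nets, cost=config.cost, variant=config.clustering_variant
        )

    @_stage("series")
    def series(nets, table):
        out_series = {
            "volume": timeseries.trip_volume_series(nets),
            "volume_total": timeseries.trip_volume_series(
                nets, mode="log10-total-trips"
            ),
        }
        for fld in ("s", "BC", "C"):
            for agg in ("mean", "sd"):
                out_series[f"{fld}_{agg}"] = timeseries.metric_series(table, fld, agg)
        return out_series

    @_stage("segment")
    def segment(all_series):
        segs = {}
        for key in ("volume_total", "s_mean", "BC_mean", "C_mean"):
            ser = all_series[key]
            try:
                segs[key] = timeseries.segment_regimes(
                    ser, n_breaks=config.n_breaks, min_segment=config.min_segment
                )
            except ValueError as exc:
                logger.warning("segmentation skipped for %s: %s", key, exc)
        return segs

    @_stage("export")
    def export(nets, table, all_series, segs):
        f = out / "networks.csv"
        networks_to_frame(nets).to_csv(f, index=False)
        f = out / "metrics.csv"
        table.to_csv(f, index=False, float_format="%.10g")
        frames = [s.to_frame().set_index("date") for s in all_series.values()]
        pd.concat(frames, axis=1).to_csv(out / "series.csv", float_format="%.10g")
        seg_doc = {
            key: {
                "changepoints": [d.isoformat() for d in seg.changepoints],
                "segment_means": seg.segment_means,
                "segment_sds": seg.segment_sds,
                "cost": seg.cost,
            }
            for key, seg in segs.items()
        }
        (out / "segmentation.json").write_text(json.dumps(seg_doc, indent=1))

        areas = None
        if config.boundaries_path is not None:
            areas = trip_io.read_boundaries(config.boundaries_path)
        elif config.synthetic_boundaries:
            n = config.simulate.n_zones if config.simulate else 77
            areas = synthetic_data.synthetic_boundaries(n)
        for day in config.snapshot_dates:
            if day not in nets:
                raise PipelineError(f"stage 'export' failed: no network for {day}")
            day_metrics = table[table["date"] == day]
            export_snapshot(nets[day], day_metrics, out / f"snapshot_{day}.graphml")
            if areas is not None:
                for fld in ("s", "BC", "C"):
                    export_choropleth(
                        areas, day_metrics, fld, out / f"choropleth_{fld}_{day}.geojson"
                    )

    trips = ingest()
    nets = build(trips)
    table = compute(nets)
    all_series = series(nets, table)
    segs = segment(all_series)
    export(nets, table, all_series, segs)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
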