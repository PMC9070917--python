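#!/usr/bin/env python
"""Export annotated network snapshots and choropleth-ready GeoJSON.

One GraphML snapshot per chosen date (node attributes: strength,
betweenness, clustering, self trips; edge attribute: weight) plus, for each
date, per-metric GeoJSON choropleths over the synthetic zone grid — the data
side of the map figures, with styling left to the consumer.
"""

import datetime as dt
from pathlib import Path

import pandas as pd

from odnet.exports import export_choropleth, export_snapshot
from odnet.network_builder import frame_to_networks
from odnet.trip_io import read_boundaries

RESULTS = Path(__file__).resolve().parents[1] / "results"

# baseline, mid-decline, plateau
SNAPSHOT_DATES = [dt.date(2020, 3, 4), dt.date(2020, 3, 18), dt.date(2020, 4, 1)]


def main() -> None:
    out = RESULTS / "exports"
    out.mkdir(parents=True, exist_ok=True)
    nets = frame_to_networks(pd.read_csv(RESULTS / "networks.csv"))
    table = pd.read_csv(RESULTS / "metrics.csv", parse_dates=["date"])
    table["date"] = table["date"].dt.date
    areas = read_boundaries(RESULTS / "boundaries.geojson")

    for day in SNAPSHOT_DATES:
        day_metrics = table[table["date"] == day]
        export_snapshot(nets[day], day_metrics, out / f"snapshot_{day}.graphml")
        for fld in ("s", "BC", "C"):
            export_choropleth(areas, day_metrics, fld,
                              out / f"choropleth_{fld}_{day}.geojson")
        print(f"{day}: {nets[day].N} areas, {nets[day].graph.number_of_edges()} "
              f"edges, total strength {day_metrics['s'].sum():.0f}")
    print(f"wrote snapshots and choropleths to {out}")


if __name__ == "__main__":
    main()
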