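# odnet — pandemic regime shifts in urban origin–destination mobility networks

`odnet` analyzes how an epidemic shock restructures a city's taxi mobility.
It is built around the Chicago setting — 77 community areas, trip records in
the Chicago Data Portal "Taxi Trips" CSV dialect — but every step is generic:
trip records in, one weighted undirected origin–destination (OD) network per
calendar day out, three per-area network metrics, city-level time series,
and change-point segmentation of the series into mobility regimes
(pre-pandemic baseline, decline, stabilized plateau).  It is aimed at
researchers in urban mobility and epidemiological modelling who want the
full pipeline — including a synthetic trip generator with known ground
truth — as tested, importable code rather than a one-off notebook.

## The model

For each day, community areas *i*, *j* are joined by an edge when at least
one trip ran between them that day, in either direction, with weight
*w<sub>ij</sub>* = the number of such trips.  Same-area trips never form
edges (paths and triangles are undefined on self-loops) but are retained so
daily totals are conserved.  On each daily network three node metrics are
computed:

- **Strength** — the weighted degree,
  *s<sub>i</sub>* = Σ<sub>j</sub> *A<sub>ij</sub> w<sub>ij</sub>*:
  the number of trips starting or ending in area *i*.
- **Weighted betweenness centrality** —
  *BC<sub>i</sub>* = Σ<sub>q≠k≠i</sub> σ<sub>qk</sub>(i)/σ<sub>qk</sub>,
  where σ counts minimum-cost paths with edge cost 1/*w<sub>ij</sub>*
  (trip counts are similarities: heavily used connections are "short").
  The ordered-pair sum is normalized by (N−1)(N−2), bounding it in [0, 1].
  Computed by Brandes' algorithm over Dijkstra shortest-path DAGs, with
  minimum-cost ties counted to a 1e−12 tolerance.
- **Weighted local clustering** (Barrat) —
  *C<sub>i</sub>* = 1/(*s<sub>i</sub>*(*k<sub>i</sub>*−1)) ·
  Σ<sub>(j,h)</sub> (*w<sub>ij</sub>* + *w<sub>ih</sub>*)/2 over ordered
  neighbour pairs closing a triangle at *i* — in [0, 1], reducing to the
  ordinary local clustering coefficient when weights are equal.

City-level series (means and sample standard deviations over areas, and
trip-volume summaries) are segmented by exact dynamic programming: the
placement of breakpoints that minimizes the within-segment sum of squared
deviations from segment means, ties broken toward the earliest breaks.

The synthetic generator draws independent Poisson counts per day and ordered
zone pair under a gravity kernel λ<sub>od</sub>(t) ∝ T(t) · u<sub>o</sub>(t)
u<sub>d</sub>(t), with heavy-tailed zone attractiveness, a three-regime
volume profile T(t) (baseline T₀; log-linear decline to r·T₀ over D days
from the shock date; plateau), an extra suppression of top-decile "hub"
zones from the shock date on, and optional distance decay on zone-centroid
distance.  Expected totals are renormalized to T(t) exactly, and every run
carries its ground truth for recovery tests.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py        # 77 zones, 3000 trips/day baseline
python analysis/02_build_networks.py
python analysis/03_compute_metrics.py
python analysis/04_segment_regimes.py
python analysis/05_export_products.py
python analysis/06_recovery_study.py  # 20-seed study at full scale (~2 min)
```

A run at the default seed prints, among other lines:

```
s_mean: regime means 74.17 -> 29.36 -> 5.213
BC_mean: regime means 0.01838 -> 0.02284 -> 0.03309
C_mean: regime means 0.7703 -> 0.5172 -> 0.1449
detected shock 2020-03-11 .. 2020-03-24 (truth 2020-03-11 .. 2020-03-25)
...
  median |breakpoint error| 0.0 days
  median volume-ratio estimate 0.0499 (truth 0.05)
  hub decline > non-hub decline in 100% of seeds
```

Reading: mean area strength collapses across the three regimes (74 → 29 →
5, tracking the configured 20-fold volume drop), while mean weighted
betweenness *rises* (0.018 → 0.033) — as the network thins, surviving areas
sit on a larger share of the remaining shortest paths.  The shock window
detected from the data alone misses the configured boundaries by at most
one day, the estimated residual volume ratio (0.0499) recovers the
configured r = 0.05, and hub zones decline more than non-hub zones in every
replicate.  `06_recovery_study.py` also runs the trip-localization scenario
(distance-decayed kernel, downtown/airport hubs suppressed 95%, volume
halved), where mean clustering rises ~+39% during the decline while mean
strength falls and stabilizes.

The same steps are scriptable from the shell via the `odnet` CLI
(`odnet simulate | ingest | build | metrics | series | segment | export |
run`); `odnet run --config run.yaml` executes the pipeline end to end and
writes a manifest with checksums.

## Layout

- `src/odnet/` — the library: `trip_io`, `network_builder`, `metrics`,
  `timeseries`, `synthetic_data`, `studies`, `exports`, `cli`.
- `analysis/` — the numbered narrative drivers above.
- `tests/` — pytest suite, including brute-force oracles for betweenness
  (exhaustive path enumeration) and clustering (triangle enumeration) and
  cross-checks against networkx and igraph.
- `docs/methods.md` — modelling assumptions, conventions, and limitations.

Notes: boundary files are read from GeoJSON (convert shapefiles first);
COVID case ingestion is supported, but joining zip-code cases to community
areas is an extension point, not implemented.
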