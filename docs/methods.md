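# Methods

## Daily OD networks

Trips are assigned to calendar days by their pickup timestamp (pickup
defines the timing of demand at the origin; no timezone arithmetic is done
because only local calendar dates matter).  Each day's network is undirected:
the weight of {i, j} pools trips in both directions.  Records missing either
community-area code are kept at ingest — the ingest report counts them — and
must be filtered before network construction; a missing code reaching the
builder is treated as a caller bug, not data.

Self-trips (pickup area = dropoff area) are excluded from edges and from all
metric computations, because adjacency, shortest paths and triangles are
undefined for self-loops, but they are retained in per-node counts so that
edge weights plus self-trips reproduce the day's trip total exactly.  This
conservation identity is asserted in the tests for every generated dataset.

Two node policies exist and both are exported where relevant.  The default,
`active-only`, takes a day's nodes to be the areas appearing in at least one
trip that day; per-day network size N then enters the betweenness
normalization.  The alternative `all-areas` keeps all 77 codes every day.
The choice matters for per-day *means* over areas: under `active-only` the
mean conditions on which areas happened to be active (a selection effect in
sparse regimes), while under `all-areas` mean strength is proportional to
total edge volume.  Regime-shape checks on strength therefore use
`all-areas`; everything else defaults to `active-only`.

## Metrics

**Strength** is the weighted degree; isolated nodes have strength 0.

**Weighted betweenness.** Edge weights are trip counts — similarities — so
shortest paths are computed under the cost transform c = 1/w (a `unit` cost
option is retained for sensitivity).  Path counting follows Brandes'
algorithm on the Dijkstra shortest-path DAG; accumulated path costs within
1e−12 of each other are treated as ties and all tied minimum-cost paths
count toward σ.  The raw ordered-pair sum is divided by (N−1)(N−2) with N
the whole network's node count, which bounds the metric in [0, 1]; pairs in
different components contribute nothing and the normalizer is not reduced.
Networks with N < 3 score 0 everywhere.  The implementation is checked
against exhaustive enumeration of all simple paths on 500 random small
graphs (≤ 7 nodes) and against networkx's weighted betweenness on larger
random graphs.

**Weighted clustering** uses the Barrat form: each triangle at node *i*
contributes the mean weight of the two edges *incident to i*, normalized by
s_i(k_i − 1); nodes with degree ≤ 1 score 0.  The form is bounded by 1,
equals 1 on complete graphs regardless of weights, and reduces to the
unweighted local clustering coefficient under equal weights.  An alternative
variant crediting (w_ij + w_jh)/2 — the i–j edge averaged with the *opposite*
edge of the triangle — is available behind a flag for comparison; it is not
bounded by 1 (a heavy opposite edge can push it far above 1, which is
incompatible with interpreting the metric on a [0, 1] scale), so Barrat is
the default.  The implementation is checked against direct triangle
enumeration and against igraph's Barrat local transitivity.

Both weighted metrics are invariant under rescaling all weights by a
positive constant; this and the [0, 1] bounds are property-tested.

## City-level series and regime segmentation

Series aggregate per-day metric tables over the areas present that day;
standard deviations are *sample* (n − 1) throughout.  Trip-volume series
come in two modes, reflecting an ambiguity in how a daily-volume summary on
a log scale can be defined: the default is the mean over edges of
log10(w_ij); the alternative is log10 of the day's total trips (self-trips
included).  Days with no edges (or no trips) contribute 0 with a logged
warning rather than −∞.

`segment_regimes` is an exact least-squares change-point solver: dynamic
programming over all placements of k breakpoints with a minimum segment
length (default two breaks — three regimes — and 7-day segments, roughly the
scale of the observed pre-pandemic / decline / plateau structure).  The
within-segment cost uses prefix sums; ties are broken toward the earliest
breakpoints by scanning candidate splits in ascending order with strict
improvement, making the output deterministic even for constant series.
Optimality is spot-checked against 1000 random valid break placements.

A practical caveat established numerically: on a *level* series whose middle
regime is a steady ramp (the shock's log-linear decline), the optimal
piecewise-constant fit absorbs the ramp's ends into the neighbouring
segments, biasing detected breaks 2–6 days inward.  Shock-boundary
*detection* therefore segments the day-over-day change of log10 total
trips: under the generator's shock that differenced series is genuinely
piecewise constant (≈ 0, then −log10(1/r)/D, then 0), its mean shifts fall
exactly at the regime boundaries, and recovery at the study conditions is
exact.  Level-series segmentations are still computed and exported for the
regime means and dispersions they provide.

## Synthetic trip generator

The generator emulates the statistical structure the analysis assumes: 77
zones, heterogeneous attractiveness with dominant hubs, independent Poisson
daily counts per ordered zone pair, and a three-regime shock.  Per day t and
ordered pair (o, d), counts are Poisson with

    lambda_od(t) = T(t) * K_od(t) / sum(K(t)),
    K_od(t) = u_o(t) u_d(t) * d_od^-gamma * (self-pair damping on o = d),
    u_z(t) = M_z(t) p_z,

where p_z are normalized attractiveness shares (default: lognormal with
sigma = 1.6, chosen so the cross-area spread of strengths is hub-dominated,
with a coefficient of variation in the observed range), M_z applies the
extra hub decline (1 − h for top-decile zones from the shock date on), and
the denominator renormalizes so the expected daily total is T(t) exactly —
an identity asserted analytically in the tests.  T(t) is constant at T₀
before the shock date, declines log-linearly to r·T₀ over D days (matching
the steady log-scale decline of the observed series), and stays at r·T₀
after.  Defaults mirror the observed study conditions: T₀ = 30,000 trips/day
(the pre-pandemic daily volume, ~33k/day, rounded to the study scale),
shock on 2020-03-11, D = 14 days, r = 0.05 (the observed collapse to ~1.5k
trips/day), h = 0.5.  Trips are expanded to records with uniform times
within the day and filler miles/durations that downstream analysis never
reads.  Everything is reproducible from one integer seed.

Two optional kernel fields extend the basic product form.  `distance_decay`
(gamma above, default 0 = off) damps pairs by centroid distance on the
synthetic zone grid, giving trips spatial locality; the observed analysis
never uses inter-zone distance, so the default stays off.  `self_trip_weight`
(default 1) multiplies the kernel diagonal; it exists because under a pure
product kernel with heavy-tailed shares, same-zone pairs of hub zones absorb
a large share of total volume (u_z² is largest exactly where u_z is), which
is unrealistic for taxis and distorts edge-volume accounting in shock
scenarios.  The default preserves the pure product-kernel expectations
(e.g. two equal zones at T₀ = 100 give 25 expected trips per ordered pair,
self pairs included).

What the generator does *not* emulate: weekly seasonality (the observed
weekend effect), the partial recovery between plateau and late-2020 levels,
spatially correlated Poisson noise, and real Chicago geography (zones are a
synthetic grid).  Passing recovery tests therefore demonstrates that the
pipeline recovers the imposed regime structure from realistic counting
noise — not that real data are this clean.

## Recovery and shape studies

`recovery_study` replicates the shock scenario over 20 seeds at the default
study conditions on a January–April window (121 days: 70 baseline, 14
decline, 36 plateau — enough observations per regime while keeping a
replicate around 2.3M trips) and reports: signed breakpoint errors against
the configured shock start/end; the post/pre mean daily-trip ratio as the
estimate of r; and relative strength declines (1 − post/pre mean strength)
for hub vs non-hub zones.  At these conditions the median absolute
breakpoint error is 0 days, the ratio estimate is within a percent of r,
and hub zones decline strictly more than non-hub zones in every seed.

`shape_study` asks a qualitative question: can the generator reproduce the
observed regime *dynamics* — mean strength falling then stabilizing while
mean weighted clustering rises during the decline?  A mechanism result,
established by scanning the shock configurations: under a distance-free
gravity kernel the answer is no.  Hubs are the triangle-closers — a
low-attractiveness node's clustering mass runs through its hub neighbours —
so any shock that suppresses hub trips (however the remaining volume is
distributed) *lowers* mean clustering.  A clustering rise requires spatial
locality: with a distance-decayed kernel, a node's neighbours are its
spatial neighbours, which are also each other's neighbours, so redistributing
volume toward short-range pairs densifies triangles.  The packaged
`localized_shock_config` realizes this: city-like attractiveness (a
Gaussian downtown core plus an airport corner, deterministic so the layout
does not vary across seeds), gamma = 4, volume halved (r = 0.5), hubs
suppressed 95%, self-pairs damped to 0.1.  Under it, mean strength
(all-areas policy) falls monotonically across regimes and stabilizes, and
mean clustering rises ~+30–40% during the decline window — robust across
seeds.  The interpretation carries over to the real setting: the observed
clustering rise is evidence of trip localization, not an automatic
consequence of falling volume.

## I/O and export conventions

Trip CSVs are read through a column-mapping dialect whose default matches
the Chicago Data Portal "Taxi Trips" headers and timestamp format; rows with
unparseable timestamps are dropped and counted (kept + dropped = total is
asserted), missing or out-of-range area codes are retained as missing.
Boundaries are read from GeoJSON only (no shapefile driver is bundled;
convert first), with the area-code property auto-detected among the city
portal's key spellings.  Weekly COVID case/death counts can be ingested and
validated; joining zip-code cases to community areas requires a crosswalk
the data does not provide and is left as a documented extension point.

Per-day networks round-trip through GraphML (node attribute `area`, edge
attribute `weight`, self-trip counts as node attributes) and a long-format
CSV (`date, i, j, weight`; `i = j` rows carry self-trips, `j = −1` marks
isolated nodes).  Snapshots add the per-node metrics as GraphML attributes;
choropleth exports are GeoJSON FeatureCollections carrying code, name and
the chosen metric per area (log10 companion for strength), with null values
for areas absent from the metric table.  The pipeline runner writes a
manifest with parameters, convention notes and SHA-256 checksums of every
product; reruns with the same inputs and seed are byte-identical.

## Known limitations

- Betweenness is exact Brandes in pure Python: fine at 77 nodes × hundreds
  of days, not sized for thousands of nodes.
- Breakpoint detection assumes the decline is roughly log-linear (so the
  differenced log-volume series is near piecewise-constant); gradual or
  multi-wave shocks would need more breaks or a piecewise-linear cost.
- The betweenness normalization keeps the full-network N for disconnected
  networks, so values on badly fragmented days are conservative
  (upper-bounded by the connected case).
- The segmentation reports no uncertainty on breakpoints; the recovery study
  quantifies error empirically instead.
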