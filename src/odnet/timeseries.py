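"""City-level metric time series and change-point regime segmentation.

Per-day networks and metric tables are reduced to dated series (mean or
sample standard deviation over community areas, or trip-volume summaries),
and a series is split into mobility regimes — pre-pandemic, decline,
stabilized — by exact least-squares change-point detection: dynamic
programming over all placements of the breakpoints, minimizing the
within-segment sum of squared deviations from segment means.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .network_builder import DailyNetwork

logger = logging.getLogger(__name__)

VolumeMode = Literal["log10-mean-edge-weight", "log10-total-trips"]
Aggregator = Literal["mean", "sd", "sum"]

#: Column aliases accepted by :func:`metric_series`.
_FIELD_ALIASES = {
    "s": "s", "strength": "s",
    "BC": "BC", "betweenness": "BC",
    "C": "C", "clustering": "C",
    "k": "k", "degree": "k",
}


@dataclass
class MetricSeries:
    """A dated city-level series of one metric (sample-sd convention)."""

    name: str
    dates: list[dt.date]
    values: np.ndarray
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values differ in length")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, self.name: self.values})

    def diff(self) -> "MetricSeries":
        """Day-over-day first difference (length n-1, dated by the later day)."""
        return MetricSeries(
            name=f"d_{self.name}",
            dates=self.dates[1:],
            values=np.diff(self.values),
            aggregator=self.aggregator,
        )


@dataclass
class RegimeSegmentation:
    """Optimal piecewise-constant split of a series into regimes.

    ``changepoints`` holds the first date of each regime after the first;
    per-regime means and sample standard deviations follow in order.
    """

    changepoints: list[dt.date]
    segment_means: list[float]
    segment_sds: list[float]
    cost: float
    segment_spans: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    @property
    def n_regimes(self) -> int:
        return len(self.segment_means)


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def trip_volume_series(
    nets: Mapping[dt.date, DailyNetwork],
    mode: VolumeMode = "log10-mean-edge-weight",
) -> MetricSeries:
    """Daily trip-volume summary across the networks.

    Default: the mean over that day's edges of log10(edge weight).  The
    alternative ``log10-total-trips`` takes log10 of the day's total trips
    (edge weights plus self trips).  A day with no edges (or no trips)
    contributes 0 with a warning.
    """
    if mode not in ("log10-mean-edge-weight", "log10-total-trips"):
        raise ValueError(f"unknown volume mode: {mode!r}")
    dates, values = [], []
    for day in sorted(nets):
        net = nets[day]
        if mode == "log10-mean-edge-weight":
            weights = [w for *_, w in net.edges()]
            if not weights:
                logger.warning("day %s has no edges; volume set to 0", day)
                v = 0.0
            else:
                v = float(np.mean(np.log10(weights)))
        else:
            total = net.total_trips()
            if total == 0:
                logger.warning("day %s has no trips; volume set to 0", day)
                v = 0.0
            else:
                v = math.log10(total)
        dates.append(day)
        values.append(v)
    return MetricSeries(name=f"volume[{mode}]", dates=dates, values=np.array(values),
                        aggregator="sum" if mode == "log10-total-trips" else "mean")


def metric_series(
    metrics: pd.DataFrame, field_name: str, aggregator: Aggregator = "mean"
) -> MetricSeries:
    """Aggregate a long metric table (date, area, s, k, BC, C) per day.

    The aggregate runs over the areas present that day; ``sd`` is the sample
    standard deviation (n-1 denominator), 0 for single-area days.
    """
    if field_name not in _FIELD_ALIASES:
        raise ValueError(f"unknown metric field: {field_name!r}")
    col = _FIELD_ALIASES[field_name]
    if aggregator not in ("mean", "sd"):
        raise ValueError(f"unknown aggregator: {aggregator!r}")
    if metrics.empty:
        raise ValueError("empty metric table")
    dates, values = [], []
    for day, group in metrics.groupby("date", sort=True):
        x = group[col].to_numpy(dtype=float)
        dates.append(day if isinstance(day, dt.date) else pd.Timestamp(day).date())
        values.append(float(np.mean(x)) if aggregator == "mean" else _sample_sd(x))
    return MetricSeries(
        name=f"{col}_{aggregator}", dates=dates, values=np.array(values),
        aggregator=aggregator,
    )


def segment_regimes(
    series: MetricSeries, n_breaks: int = 2, min_segment: int = 7
) -> RegimeSegmentation:
    """Exact least-squares change-point segmentation.

    Minimizes the within-segment sum of squared deviations from segment means
    over all placements of ``n_breaks`` breakpoints with every segment at
    least ``min_segment`` observations long.  Deterministic: ties are broken
    toward the earliest breakpoints.  Raises if the series is shorter than
    ``(n_breaks + 1) * min_segment``.
    """
    x = np.asarray(series.values, dtype=float)
    n = len(x)
    if n_breaks < 0 or min_segment < 1:
        raise ValueError("n_breaks must be >= 0 and min_segment >= 1")
    if n < (n_breaks + 1) * min_segment:
        raise ValueError(
            f"series of length {n} too short for {n_breaks} breaks with "
            f"min_segment={min_segment}"
        )

    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # half-open [i, j)
        s, s2, m = ps[j] - ps[i], ps2[j] - ps2[i], j - i
        return max(s2 - s * s / m, 0.0)

    K = n_breaks + 1
    INF = float("inf")
    dp = np.full((K + 1, n + 1), INF)
    argmin = np.full((K + 1, n + 1), -1, dtype=int)
    for j in range(min_segment, n + 1):
        dp[1, j] = seg_cost(0, j)
    for k in range(2, K + 1):
        for j in range(k * min_segment, n + 1):
            best, bi = INF, -1
            # ascending scan + strict improvement => earliest optimal break
            for i in range((k - 1) * min_segment, j - min_segment + 1):
                c = dp[k - 1, i] + seg_cost(i, j)
                if c < best:
                    best, bi = c, i
            dp[k, j] = best
            argmin[k, j] = bi

    bounds = [n]
    j = n
    for k in range(K, 1, -1):
        j = int(argmin[k, j])
        bounds.append(j)
    bounds.append(0)
    bounds.reverse()  # 0 = b0 < b1 < ... < bK = n

    means, sds, spans = [], [], []
    for a, b in zip(bounds, bounds[1:]):
        seg = x[a:b]
        means.append(float(np.mean(seg)))
        sds.append(_sample_sd(seg))
        spans.append((series.dates[a], series.dates[b - 1]))
    return RegimeSegmentation(
        changepoints=[series.dates[b] for b in bounds[1:-1]],
        segment_means=means,
        segment_sds=sds,
        cost=float(dp[K, n]),
        segment_spans=spans,
    )
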