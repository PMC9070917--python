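"""Canned simulation studies over the synthetic generator.

Two studies summarise how well the pipeline recovers known structure:

* :func:`recovery_study` — replicate the shock scenario over many seeds and
  collect breakpoint errors, the post/pre volume-ratio estimate, and the hub
  vs non-hub relative strength declines.

* :func:`shape_study` — run the trip-localization scenario
  (:func:`~odnet.synthetic_data.localized_shock_config`) and report the
  regime means of city-level strength and weighted clustering, to check the
  qualitative regime dynamics (strength falls then stabilizes; clustering
  rises during the decline).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping

import numpy as np
import pandas as pd

from .metrics import strength, weighted_clustering
from .network_builder import build_daily_networks
from .synthetic_data import (
    SimConfig,
    generate_trips,
    localized_shock_config,
    recovery_report,
)

#: Study conditions for parameter recovery: a scaled analogue of the observed
#: early-2020 decline (baseline 30k trips/day, shock on day 71 = March 11,
#: two-week decline to a 5% residual, hubs suppressed twice as hard).
RECOVERY_CONFIG = SimConfig(
    n_zones=77,
    baseline_daily_trips=30_000.0,
    start=dt.date(2020, 1, 1),
    end=dt.date(2020, 4, 30),
    shock_start=dt.date(2020, 3, 11),
    decline_days=14,
    residual_ratio=0.05,
    hub_extra_decline=0.5,
)


def recovery_study(
    n_seeds: int = 20, base_seed: int = 0, config: SimConfig = RECOVERY_CONFIG
) -> pd.DataFrame:
    """One row per seed: breakpoint errors, ratio estimate, hub declines."""
    rows = []
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=(base_seed + k) % 2**31)
        trips, truth = generate_trips(cfg)
        rep = recovery_report(trips, truth)
        row = rep.as_dict()
        row["seed"] = cfg.seed
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(study: pd.DataFrame) -> dict[str, float]:
    errors = np.abs(
        np.concatenate([study["breakpoint_error_start"], study["breakpoint_error_end"]])
    )
    return {
        "median_abs_breakpoint_error_days": float(np.median(errors)),
        "median_ratio_estimate": float(study["ratio_estimate"].median()),
        "ratio_true": float(study["ratio_true"].iloc[0]),
        "hub_decline_exceeds_nonhub_fraction": float(
            (study["hub_relative_decline"] > study["nonhub_relative_decline"]).mean()
        ),
        "n_seeds": int(len(study)),
    }


def shape_study(seed: int = 0) -> dict[str, float]:
    """Regime means of mean strength and mean clustering in the
    trip-localization scenario, under the all-areas node policy (so the
    strength mean tracks total edge volume rather than the active-area set).
    """
    cfg = localized_shock_config(seed=seed)
    trips, truth = generate_trips(cfg)
    nets = build_daily_networks(trips, node_policy="all-areas")
    dates = np.array(sorted(nets))
    s_mean = np.array([np.mean(list(strength(nets[d]).values())) for d in dates])
    c_mean = np.array(
        [np.mean(list(weighted_clustering(nets[d]).values())) for d in dates]
    )
    pre = dates < truth.shock_start
    dec = (dates >= truth.shock_start) & (dates <= truth.shock_end)
    post = dates > truth.shock_end
    return {
        "strength_pre": float(s_mean[pre].mean()),
        "strength_decline": float(s_mean[dec].mean()),
        "strength_post": float(s_mean[post].mean()),
        "strength_post_sd": float(np.std(s_mean[post], ddof=1)),
        "clustering_pre": float(c_mean[pre].mean()),
        "clustering_decline": float(c_mean[dec].mean()),
        "clustering_post": float(c_mean[post].mean()),
    }
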