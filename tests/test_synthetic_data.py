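import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest

from odnet.network_builder import build_daily_networks
from odnet.synthetic_data import (
    SimConfig,
    city_like_attractiveness,
    generate_trips,
    localized_shock_config,
    recovery_report,
    synthetic_boundaries,
)
from odnet import metrics


def window(days):
    start = dt.date(2020, 1, 1)
    return dict(start=start, end=start + dt.timedelta(days=days - 1))


class TestConfigValidation:
    def test_invalid_config_lists_every_violation(self):
        cfg = SimConfig(
            n_zones=1, baseline_daily_trips=-5, residual_ratio=2.0,
            decline_days=0, hub_extra_decline=3.0,
        )
        with pytest.raises(ValueError) as err:
            cfg.validate()
        msg = str(err.value)
        for frag in ("n_zones", "baseline_daily_trips", "residual_ratio",
                     "decline_days", "hub_extra_decline"):
            assert frag in msg

    def test_attractiveness_must_be_positive_and_sized(self):
        cfg = SimConfig(n_zones=3, attractiveness=np.array([1.0, -1.0, 2.0]))
        with pytest.raises(ValueError, match="strictly positive"):
            cfg.validate()


class TestExpectedRates:
    def test_rates_sum_to_daily_total_under_any_shock(self):
        cfg = SimConfig(
            n_zones=10, baseline_daily_trips=500.0,
            shock_start=dt.date(2020, 1, 10), decline_days=5,
            residual_ratio=0.2, hub_extra_decline=0.7,
            distance_decay=2.5, self_trip_weight=0.3,
            seed=5, **window(25),
        )
        _, truth = generate_trips(cfg)
        for day in cfg.dates():
            assert truth.rates_on(day).sum() == pytest.approx(truth.total_on(day))

    def test_shock_profile_is_log_linear(self):
        cfg = SimConfig(
            shock_start=dt.date(2020, 1, 10), decline_days=10,
            residual_ratio=0.04, baseline_daily_trips=1000.0, **window(31),
        )
        cfg.validate()
        _, truth = generate_trips(
            SimConfig(n_zones=5, baseline_daily_trips=1000.0,
                      shock_start=dt.date(2020, 1, 10), decline_days=10,
                      residual_ratio=0.04, seed=0, **window(31))
        )
        assert truth.total_on(dt.date(2020, 1, 9)) == 1000.0
        assert truth.total_on(dt.date(2020, 1, 15)) == pytest.approx(1000.0 * 0.04**0.5)
        assert truth.total_on(dt.date(2020, 1, 25)) == pytest.approx(40.0)

    def test_two_equal_zones_expect_25_trips_per_ordered_pair(self):
        cfg = SimConfig(
            n_zones=2, attractiveness=np.array([1.0, 1.0]),
            baseline_daily_trips=100.0, residual_ratio=1.0,
            hub_extra_decline=0.0, seed=42, **window(100),
        )
        trips, truth = generate_trips(cfg)
        assert np.allclose(truth.rates_on(dt.date(2020, 1, 2)), 25.0)
        counts = (
            trips.groupby([trips["pickup_area"], trips["dropoff_area"]])
            .size()
            .unstack()
            .to_numpy()
            / 100.0
        )
        # 100 days of Poisson(25): SE = 0.5 per ordered pair
        assert np.all(np.abs(counts - 25.0) < 3 * 0.5)


class TestGeneratedTrips:
    def test_stationary_process_matches_baseline_rate(self):
        cfg = SimConfig(
            n_zones=10, baseline_daily_trips=400.0, residual_ratio=1.0,
            hub_extra_decline=0.0, seed=8, **window(100),
        )
        trips, _ = generate_trips(cfg)
        daily = trips.groupby(trips["pickup_time"].dt.date).size()
        se = np.sqrt(400.0 / 100)
        assert abs(daily.mean() - 400.0) < 3 * se

    def test_same_seed_reproduces_identically(self):
        cfg = SimConfig(n_zones=8, baseline_daily_trips=200.0, seed=3, **window(10))
        a, _ = generate_trips(cfg)
        b, _ = generate_trips(cfg)
        pd.testing.assert_frame_equal(a, b)
        c, _ = generate_trips(
            SimConfig(n_zones=8, baseline_daily_trips=200.0, seed=4, **window(10))
        )
        assert not a.equals(c)

    def test_self_trips_are_generated(self):
        cfg = SimConfig(n_zones=5, baseline_daily_trips=500.0, seed=1, **window(10))
        trips, _ = generate_trips(cfg)
        assert (trips["pickup_area"] == trips["dropoff_area"]).any()

    def test_trip_table_is_schema_complete(self):
        cfg = SimConfig(n_zones=5, baseline_daily_trips=100.0, seed=2, **window(5))
        trips, _ = generate_trips(cfg)
        assert (trips["dropoff_time"] >= trips["pickup_time"]).all()
        assert trips["pickup_area"].between(1, 5).all()
        assert (trips["trip_miles"] >= 0).all()
        assert trips["trip_id"].is_unique


class TestRecovery:
    def test_hub_zones_decline_more_in_relative_strength(self):
        for seed in range(3):
            cfg = SimConfig(
                n_zones=20, baseline_daily_trips=2000.0,
                start=dt.date(2020, 1, 1), end=dt.date(2020, 3, 10),
                shock_start=dt.date(2020, 1, 31), decline_days=10,
                residual_ratio=0.1, hub_extra_decline=0.5, seed=seed,
            )
            trips, truth = generate_trips(cfg)
            rep = recovery_report(trips, truth)
            assert rep.hub_relative_decline > rep.nonhub_relative_decline

    def test_low_noise_limit_recovers_breaks_within_one_day(self):
        cfg = SimConfig(
            n_zones=30, baseline_daily_trips=10_000.0,
            start=dt.date(2020, 1, 1), end=dt.date(2020, 2, 29),
            shock_start=dt.date(2020, 1, 26), decline_days=10,
            residual_ratio=0.05, hub_extra_decline=0.5, seed=19,
        )
        trips, truth = generate_trips(cfg)
        rep = recovery_report(trips, truth)
        assert abs(rep.breakpoint_error_start) <= 1
        assert abs(rep.breakpoint_error_end) <= 1
        assert rep.ratio_estimate == pytest.approx(0.05, rel=0.1)

    def test_ground_truth_json_round_trips(self, tmp_path):
        cfg = SimConfig(n_zones=5, baseline_daily_trips=50.0, seed=1, **window(5))
        _, truth = generate_trips(cfg)
        f = tmp_path / "truth.json"
        truth.to_json(f)
        doc = json.loads(f.read_text())
        assert doc["n_zones"] == 5
        assert len(doc["daily_totals"]) == 5
        assert doc["shares"] == pytest.approx(list(truth.shares))


class TestScenarioHelpers:
    def test_city_like_profile_peaks_downtown_and_airport(self):
        a = city_like_attractiveness(77)
        assert len(a) == 77 and np.all(a > 0)
        assert a[76] > np.median(a)  # airport corner is a hub
        cfg = localized_shock_config(seed=1)
        cfg.validate()
        assert cfg.distance_decay > 0

    def test_synthetic_boundaries_tile_the_grid(self):
        areas = synthetic_boundaries(77)
        assert [a.code for a in areas] == list(range(1, 78))
        assert all(a.geometry.area == pytest.approx(1.0) for a in areas)
        # no overlaps between neighbouring squares
        assert areas[0].geometry.intersection(areas[1].geometry).area == 0.0
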