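"""Two-step engine: hand-checked examples, oracle equivalence, invariants."""

import math

import numpy as np
import pytest

from ems2sfca import (
    ChoiceSpec,
    DemandPoint,
    GeoPoint,
    StationSite,
    ThresholdPolicy,
    accessibility,
    catchment_threshold,
    distance_matrix,
    lambda_sweep,
    predicted_station_demand,
    supply_demand_ratio,
)
from ems2sfca.decay_models import gaussian_weight

from conftest import make_instance, naive_accessibility

MODELS = ("cumr", "kd", "gauss", "gp")


def planar(i, x, y):
    return GeoPoint(id=i, x=x, y=y, crs_mode="planar")


def build(station_xy, demand_xy, demands, supplies=None, zone="main_urban"):
    supplies = supplies or [1.0] * len(station_xy)
    stations = [
        StationSite(planar(f"s{j}", *xy), supply=supplies[j], zone=zone)
        for j, xy in enumerate(station_xy)
    ]
    demand = [
        DemandPoint(planar(f"d{i}", *xy), demand=demands[i], zone=zone)
        for i, xy in enumerate(demand_xy)
    ]
    dm = distance_matrix([p.point for p in demand], [s.point for s in stations])
    return stations, demand, dm


class TestThresholdPolicy:
    def test_default_thresholds(self, default_policy):
        assert catchment_threshold("main_urban", default_policy) == 5.0
        assert catchment_threshold("non_main_urban", default_policy) == 15.0

    def test_custom_passthrough(self):
        pol = ThresholdPolicy(d0_main=2.0, d0_nonmain=4.0)
        assert catchment_threshold("main_urban", pol) == 2.0
        assert catchment_threshold("non_main_urban", pol) == 4.0

    def test_unknown_zone_rejected(self, default_policy):
        with pytest.raises(ValueError):
            catchment_threshold("suburban", default_policy)


class TestPredictedDemand:
    def test_cumr_unweighted_sum(self):
        stations, demand, dm = build(
            [(0, 0)], [(1, 0), (0, 2), (3, 0)], [1000.0, 1000.0, 1000.0]
        )
        pred = predicted_station_demand(stations, demand, dm, "cumr")
        assert pred["s0"] == pytest.approx(3000.0)

    def test_gp_equals_gauss_with_single_station(self):
        stations, demand, dm = build([(0, 0)], [(1, 0), (0, 2)], [700.0, 300.0])
        gp = predicted_station_demand(stations, demand, dm, "gp")
        ga = predicted_station_demand(stations, demand, dm, "gauss")
        assert gp["s0"] == pytest.approx(ga["s0"], rel=1e-15)

    def test_gp_symmetric_split(self):
        # one demand point equidistant from two stations: each gets 500*G(d,d0)
        d = 2.0
        stations, demand, dm = build([(-d, 0), (d, 0)], [(0, 0)], [1000.0])
        pred = predicted_station_demand(
            stations, demand, dm, "gp", ChoiceSpec(lam=2.0)
        )
        expected = 500.0 * gaussian_weight(d, 5.0)
        assert pred["s0"] == pytest.approx(expected, rel=1e-12)
        assert pred["s1"] == pytest.approx(expected, rel=1e-12)


class TestSupplyDemandRatio:
    def test_coincident_demand(self):
        stations, demand, dm = build([(0, 0)], [(0, 0)], [1000.0])
        for model in ("cumr", "gauss", "gp"):
            R = supply_demand_ratio(stations, demand, dm, model)
            assert R["s0"] == pytest.approx(0.001, rel=1e-9)
        # the kernel apex is 3/4, so KD's ratio is 1/750
        assert supply_demand_ratio(stations, demand, dm, "kd")["s0"] == pytest.approx(
            1 / 750.0, rel=1e-12
        )

    def test_idle_station_flagged(self):
        stations, demand, dm = build([(0, 0), (50, 50)], [(0, 0)], [100.0])
        res = accessibility(stations, demand, dm, "gauss")
        assert res.R["s1"] == 0.0
        assert res.idle_station_ids == ["s1"]

    def test_two_symmetric_demand_points_gauss(self):
        # choose d so that G(d, 5) = 0.5 exactly
        target = 0.5 * (1 + math.exp(-0.5))
        d = 5.0 * math.sqrt(-2.0 * math.log(target))
        assert gaussian_weight(d, 5.0) == pytest.approx(0.5, abs=1e-12)
        stations, demand, dm = build([(0, 0)], [(d, 0), (-d, 0)], [500.0, 500.0])
        R = supply_demand_ratio(stations, demand, dm, "gauss")
        assert R["s0"] == pytest.approx(1.0 / (0.5 * 500 * 2), rel=1e-9)

    def test_negative_supply_rejected(self):
        with pytest.raises(ValueError, match="supply"):
            StationSite(planar("s", 0, 0), supply=-1.0)


class TestAccessibility:
    def test_chain_of_steps(self):
        stations, demand, dm = build([(0, 0)], [(0, 0)], [1000.0])
        res = accessibility(stations, demand, dm, "gp")
        assert res.A["d0"] == pytest.approx(0.001, rel=1e-9)

    def test_unreachable_demand_zero(self):
        stations, demand, dm = build([(0, 0)], [(0, 0), (40, 40)], [100.0, 100.0])
        res = accessibility(stations, demand, dm, "gauss")
        assert res.A["d1"] == 0.0
        assert res.unreachable_demand_ids == ["d1"]

    def test_id_mismatch_rejected(self, rng):
        stations, demand, dm = make_instance(rng, 5, 3)
        with pytest.raises(ValueError, match="ids"):
            accessibility(stations[:2], demand, dm, "gauss")

    @pytest.mark.parametrize("model", MODELS)
    def test_conservation_fully_connected(self, model, rng, default_choice):
        for _ in range(20):
            stations, demand, dm = make_instance(rng, 15, 8, fully_connected=True)
            res = accessibility(stations, demand, dm, model, default_choice)
            lhs = sum(p.demand * res.A[p.id] for p in demand)
            rhs = sum(s.supply for s in stations)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    @pytest.mark.parametrize("model", MODELS)
    @pytest.mark.parametrize("scope", ["within_threshold", "all_stations"])
    def test_matches_naive_oracle(self, model, scope, rng):
        choice = ChoiceSpec(lam=2.4, normalization_scope=scope)
        policy = ThresholdPolicy()
        for _ in range(5):
            stations, demand, dm = make_instance(rng, 20, 10)
            res = accessibility(stations, demand, dm, model, choice, policy)
            A, R, pred = naive_accessibility(stations, demand, dm, model, choice, policy)
            for key, val in A.items():
                assert res.A[key] == pytest.approx(val, rel=1e-12, abs=1e-15)
            for key, val in R.items():
                assert res.R[key] == pytest.approx(val, rel=1e-12, abs=1e-15)
            for key, val in pred.items():
                assert res.predicted_demand[key] == pytest.approx(val, rel=1e-12, abs=1e-15)

    def test_demand_homogeneity(self, rng, default_choice):
        stations, demand, dm = make_instance(rng, 12, 6, fully_connected=True)
        res1 = accessibility(stations, demand, dm, "gp", default_choice)
        scaled = [
            DemandPoint(p.point, demand=p.demand * 3.0, zone=p.zone) for p in demand
        ]
        res3 = accessibility(stations, scaled, dm, "gp", default_choice)
        for key in res1.A:
            assert res3.A[key] == pytest.approx(res1.A[key] / 3.0, rel=1e-12)
        for key in res1.R:
            assert res3.R[key] == pytest.approx(res1.R[key] / 3.0, rel=1e-12)

    def test_supply_homogeneity(self, rng, default_choice):
        stations, demand, dm = make_instance(rng, 12, 6, fully_connected=True)
        res1 = accessibility(stations, demand, dm, "gp", default_choice)
        scaled = [
            StationSite(s.point, supply=s.supply * 2.0, zone=s.zone) for s in stations
        ]
        res2 = accessibility(scaled, demand, dm, "gp", default_choice)
        for key in res1.A:
            assert res2.A[key] == pytest.approx(res1.A[key] * 2.0, rel=1e-12)

    def test_cumr_equal_for_same_station_set(self):
        # three demand points, all within threshold of both stations
        stations, demand, dm = build(
            [(0, 0), (3, 0)], [(0, 1), (1.5, -1), (3, 1)], [10.0, 2000.0, 55.0]
        )
        res = accessibility(stations, demand, dm, "cumr")
        vals = list(res.A.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)


class TestLambdaSweep:
    def test_single_lambda_consistency(self, rng):
        stations, demand, dm = make_instance(rng, 10, 5)
        sweep = lambda_sweep(stations, demand, dm, [2.4])
        single = accessibility(stations, demand, dm, "gp", ChoiceSpec(lam=2.4))
        assert sweep[2.4].A == single.A

    def test_default_grid(self, rng):
        stations, demand, dm = make_instance(rng, 8, 4)
        sweep = lambda_sweep(stations, demand, dm)
        assert list(sweep) == [2.0, 2.2, 2.4, 2.6, 2.8, 3.0]

    def test_lambda_inert_with_one_station_per_catchment(self):
        # stations 100 km apart; each demand point reaches exactly one
        stations, demand, dm = build(
            [(0, 0), (100, 0)], [(1, 0), (99, 1)], [500.0, 800.0]
        )
        sweep = lambda_sweep(stations, demand, dm)
        base = sweep[2.0].A
        for lam, res in sweep.items():
            assert res.A == base  # exact equality: P is identically 1

    def test_invalid_lambda_rejected(self, rng):
        stations, demand, dm = make_instance(rng, 4, 2)
        with pytest.raises(ValueError):
            lambda_sweep(stations, demand, dm, [2.0, -1.0])
        with pytest.raises(ValueError):
            lambda_sweep(stations, demand, dm, [])
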