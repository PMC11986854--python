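"""Shared fixtures: random planar instances and a naive reference engine.

The naive engine re-implements the two-step computation scalar-by-scalar
with explicit loops and serves as the independent oracle for the vectorized
catchment module; it must stay loop-based and simple.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ems2sfca import (
    ChoiceSpec,
    DemandPoint,
    GeoPoint,
    StationSite,
    ThresholdPolicy,
    distance_matrix,
)


def make_instance(
    rng: np.random.Generator,
    n_demand: int = 20,
    n_stations: int = 10,
    side: float = 30.0,
    fully_connected: bool = False,
):
    """Random planar instance; fully_connected shrinks it so every pair is
    within every threshold (no unreachable points or idle stations)."""
    if fully_connected:
        side = 3.0  # diameter < min(d0) = 5 km
    sxy = rng.uniform(0, side, (n_stations, 2))
    dxy = rng.uniform(0, side, (n_demand, 2))
    zones = ("main_urban", "non_main_urban")
    stations = [
        StationSite(
            GeoPoint(f"s{j}", float(x), float(y), crs_mode="planar"),
            supply=float(rng.uniform(0.5, 2.0)),
            zone=zones[int(rng.integers(2))],
        )
        for j, (x, y) in enumerate(sxy)
    ]
    demand = [
        DemandPoint(
            GeoPoint(f"d{i}", float(x), float(y), crs_mode="planar"),
            demand=float(rng.integers(1, 2000)),
            zone=zones[int(rng.integers(2))],
        )
        for i, (x, y) in enumerate(dxy)
    ]
    dm = distance_matrix([p.point for p in demand], [s.point for s in stations])
    return stations, demand, dm


def naive_accessibility(stations, demand_points, dm, model, choice, policy):
    """Loop-based reference implementation of both steps."""
    n_i, n_j = len(demand_points), len(stations)

    def d0_for(i, j):
        if policy.attribution == "demand_zone":
            return policy.threshold(demand_points[i].zone)
        return policy.threshold(stations[j].zone)

    def gauss(d, d0):
        return (math.exp(-0.5 * (d / d0) ** 2) - math.exp(-0.5)) / (1 - math.exp(-0.5))

    def weight(i, j):
        d = dm.values[i, j]
        d0 = d0_for(i, j)
        if d > d0:
            return 0.0
        if model == "cumr":
            return 1.0
        if model == "kd":
            return 0.75 * (1.0 - (d / d0) ** 2)
        g = gauss(d, d0)
        if model == "gauss":
            return g
        dc = max(d, choice.epsilon_km)
        if choice.normalization_scope == "within_threshold":
            denom = sum(
                max(dm.values[i, jj], choice.epsilon_km) ** (-choice.lam)
                for jj in range(n_j)
                if dm.values[i, jj] <= d0_for(i, jj)
            )
        else:
            denom = sum(
                max(dm.values[i, jj], choice.epsilon_km) ** (-choice.lam)
                for jj in range(n_j)
            )
        return (dc ** (-choice.lam) / denom) * g

    R = {}
    pred = {}
    for j, s in enumerate(stations):
        total = sum(weight(i, j) * demand_points[i].demand for i in range(n_i))
        pred[s.id] = total
        R[s.id] = s.supply / total if total > 0 else 0.0
    A = {}
    for i, p in enumerate(demand_points):
        A[p.id] = sum(weight(i, j) * R[stations[j].id] for j in range(n_j))
        if all(dm.values[i, j] > d0_for(i, j) for j in range(n_j)):
            A[p.id] = 0.0
    return A, R, pred


@pytest.fixture(scope="session")
def default_policy():
    return ThresholdPolicy()


@pytest.fixture(scope="session")
def default_choice():
    return ChoiceSpec(lam=2.4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
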