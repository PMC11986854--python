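"""Two-step floating-catchment accessibility engine.

Step 1 computes each station's supply–demand ratio ``R_j``: its capacity
``S_j`` divided by the decay-weighted (and, for the GP variant,
choice-probability-weighted) demand inside its catchment.  Step 2 sums the
reachable stations' ratios, with the same weights, at each demand point to
give the accessibility score ``A_i``.

Variants:

* ``cumr``  — binary weight (classic 2SFCA / cumulative-opportunity rectangular)
* ``kd``    — Epanechnikov kernel decay
* ``gauss`` — truncated Gaussian decay
* ``gp``    — Gaussian decay × inverse-power selection probability (GP2SFCA)

Because both steps use the same weight matrix, total supply is conserved:
``Σ_i D_i·A_i = Σ_j S_j`` whenever no station is idle and no demand point is
unreachable.  Stations with zero weighted demand get ``R_j = 0`` and are
flagged idle; demand points with no in-threshold station get ``A_i = 0`` and
are flagged unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .decay_models import ChoiceSpec, Variant, decay_weight
from .geometry import DistanceMatrix, GeoPoint

Zone = Literal["main_urban", "non_main_urban"]
ZONES = ("main_urban", "non_main_urban")

#: λ grid used for the GP2SFCA sweep.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (2.0, 2.2, 2.4, 2.6, 2.8, 3.0)


@dataclass(frozen=True)
class StationSite:
    """A supply point: location, capacity (uniform 1 by default) and zone."""

    point: GeoPoint
    supply: float = 1.0
    zone: Zone = "non_main_urban"

    def __post_init__(self) -> None:
        if self.supply < 0:
            raise ValueError(f"station {self.point.id!r}: negative supply")
        if self.zone not in ZONES:
            raise ValueError(f"station {self.point.id!r}: unknown zone {self.zone!r}")

    @property
    def id(self) -> str:
        return self.point.id


@dataclass(frozen=True)
class DemandPoint:
    """A demand centroid: location, case count needing urgent care, and zone."""

    point: GeoPoint
    demand: float = 0.0
    zone: Zone = "non_main_urban"

    def __post_init__(self) -> None:
        if self.demand < 0:
            raise ValueError(f"demand point {self.point.id!r}: negative demand")
        if self.zone not in ZONES:
            raise ValueError(
                f"demand point {self.point.id!r}: unknown zone {self.zone!r}"
            )

    @property
    def id(self) -> str:
        return self.point.id


@dataclass(frozen=True)
class ThresholdPolicy:
    """Zone-dependent catchment radii (km).

    Defaults follow the 5 km (main urban) / 15 km (non-main urban) maximum
    acceptable distances used for prehospital EMS planning.  ``attribution``
    decides whose zone governs a demand–station pair: the demand point's
    (default — the patient's area sets the acceptable distance) or the
    station's.  The same attribution applies in both steps so catchments are
    symmetric and supply conservation holds.
    """

    d0_main: float = 5.0
    d0_nonmain: float = 15.0
    attribution: Literal["demand_zone", "station_zone"] = "demand_zone"

    def __post_init__(self) -> None:
        if self.d0_main <= 0 or self.d0_nonmain <= 0:
            raise ValueError("thresholds must be positive")
        if self.attribution not in ("demand_zone", "station_zone"):
            raise ValueError(f"unknown attribution {self.attribution!r}")

    def threshold(self, zone: Zone) -> float:
        """Catchment radius (km) for an entity in ``zone``."""
        if zone == "main_urban":
            return self.d0_main
        if zone == "non_main_urban":
            return self.d0_nonmain
        raise ValueError(f"unknown zone {zone!r}")


def catchment_threshold(entity_zone: Zone, policy: ThresholdPolicy) -> float:
    """Threshold (km) governing an entity in ``entity_zone`` under ``policy``."""
    return policy.threshold(entity_zone)


@dataclass
class AccessibilityResult:
    """Per-demand-point accessibility plus per-station diagnostics."""

    model: Variant
    lam: float | None
    A: dict[str, float]
    R: dict[str, float]
    predicted_demand: dict[str, float]
    unreachable_demand_ids: list[str] = field(default_factory=list)
    idle_station_ids: list[str] = field(default_factory=list)

    def a_vector(self, demand_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(demand_ids) if demand_ids is not None else list(self.A)
        return np.array([self.A[i] for i in ids], dtype=float)


def _check_alignment(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
) -> None:
    if [p.id for p in demand_points] != dm.demand_ids:
        raise ValueError("demand ids do not match the distance matrix rows")
    if [s.id for s in stations] != dm.station_ids:
        raise ValueError("station ids do not match the distance matrix columns")


def _threshold_matrix(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    policy: ThresholdPolicy,
) -> np.ndarray:
    if policy.attribution == "demand_zone":
        d0 = np.array([policy.threshold(p.zone) for p in demand_points])
        return np.broadcast_to(d0[:, None], (len(demand_points), len(stations)))
    d0 = np.array([policy.threshold(s.zone) for s in stations])
    return np.broadcast_to(d0[None, :], (len(demand_points), len(stations)))


def _weight_matrix(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
    model: Variant,
    choice: ChoiceSpec,
    policy: ThresholdPolicy,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined step weight w_ij and the in-catchment mask."""
    D = dm.values
    d0 = _threshold_matrix(stations, demand_points, policy)
    mask = D <= d0

    if model == "cumr":
        w = mask.astype(float)
    elif model in ("kd", "gauss", "gp"):
        # decay_weight is evaluated per pair with its pair's threshold; the
        # closed forms are elementwise so the matrix call is exact.
        base = model if model != "gp" else "gauss"
        ratio = np.where(d0 > 0, D / d0, np.inf)
        w = decay_weight(ratio, 1.0, base) * mask
        if model == "gp":
            w = w * _selection_matrix(D, mask, choice)
    else:
        raise ValueError(f"unknown model variant {model!r}")
    return w, mask


def _selection_matrix(D: np.ndarray, mask: np.ndarray, choice: ChoiceSpec) -> np.ndarray:
    """Row-wise Huff probabilities P_ij; rows with empty catchments are 0."""
    dc = np.maximum(D, choice.epsilon_km)
    logw = -choice.lam * np.log(dc)
    if choice.normalization_scope == "within_threshold":
        denom_mask = mask
    else:
        denom_mask = np.ones_like(mask, dtype=bool)
    masked = np.where(denom_mask, logw, -np.inf)
    rowmax = masked.max(axis=1, keepdims=True)
    rowmax = np.where(np.isfinite(rowmax), rowmax, 0.0)
    w = np.where(denom_mask, np.exp(logw - rowmax), 0.0)
    denom = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), 0.0)
    return P


def predicted_station_demand(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
    model: Variant = "gp",
    choice: ChoiceSpec | None = None,
    policy: ThresholdPolicy | None = None,
) -> dict[str, float]:
    """Expected case load per station under the model's weighting.

    CUMR sums the raw demand inside the catchment; KD/GAUSS decay-weight it;
    GP additionally multiplies by the probability that each demand point
    chooses the station.
    """
    choice = choice or ChoiceSpec()
    policy = policy or ThresholdPolicy()
    _check_alignment(stations, demand_points, dm)
    w, _ = _weight_matrix(stations, demand_points, dm, model, choice, policy)
    demand = np.array([p.demand for p in demand_points], dtype=float)
    pred = w.T @ demand
    return dict(zip(dm.station_ids, pred.tolist()))


def supply_demand_ratio(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
    model: Variant = "gp",
    choice: ChoiceSpec | None = None,
    policy: ThresholdPolicy | None = None,
) -> dict[str, float]:
    """Step 1: R_j = S_j / weighted in-catchment demand (0 if idle)."""
    result = accessibility(stations, demand_points, dm, model, choice, policy)
    return result.R


def accessibility(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
    model: Variant = "gp",
    choice: ChoiceSpec | None = None,
    policy: ThresholdPolicy | None = None,
) -> AccessibilityResult:
    """Run both steps and return the full accessibility result."""
    choice = choice or ChoiceSpec()
    policy = policy or ThresholdPolicy()
    _check_alignment(stations, demand_points, dm)

    w, mask = _weight_matrix(stations, demand_points, dm, model, choice, policy)
    demand = np.array([p.demand for p in demand_points], dtype=float)
    supply = np.array([s.supply for s in stations], dtype=float)

    pred = w.T @ demand
    idle = pred <= 0
    R = np.where(idle, 0.0, supply / np.where(idle, 1.0, pred))
    A = w @ R

    unreachable = ~mask.any(axis=1)
    A = np.where(unreachable, 0.0, A)

    return AccessibilityResult(
        model=model,
        lam=choice.lam if model == "gp" else None,
        A=dict(zip(dm.demand_ids, A.tolist())),
        R=dict(zip(dm.station_ids, R.tolist())),
        predicted_demand=dict(zip(dm.station_ids, pred.tolist())),
        unreachable_demand_ids=[i for i, u in zip(dm.demand_ids, unreachable) if u],
        idle_station_ids=[j for j, z in zip(dm.station_ids, idle) if z],
    )


def lambda_sweep(
    stations: Sequence[StationSite],
    demand_points: Sequence[DemandPoint],
    dm: DistanceMatrix,
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
    policy: ThresholdPolicy | None = None,
    choice: ChoiceSpec | None = None,
) -> dict[float, AccessibilityResult]:
    """GP2SFCA accessibility for each λ on a shared distance matrix.

    ``choice`` supplies the scope/epsilon settings; its λ is overridden by
    each grid value.
    """
    if len(lambdas) == 0:
        raise ValueError("lambda grid is empty")
    if any(lam <= 0 for lam in lambdas):
        raise ValueError("all lambda values must be positive")
    base = choice or ChoiceSpec()
    out: dict[float, AccessibilityResult] = {}
    for lam in lambdas:
        spec = ChoiceSpec(
            lam=lam,
            normalization_scope=base.normalization_scope,
            epsilon_km=base.epsilon_km,
        )
        out[lam] = accessibility(stations, demand_points, dm, "gp", spec, policy)
    return out
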