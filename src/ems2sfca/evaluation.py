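"""Model-vs-observation scoring and cross-parameter accessibility comparison.

``fit_metrics`` scores a model's predicted per-station case load against the
observed dispatch counts (Pearson r with two-sided p, MSE, RMSE, MAE, MAPE).
``mmad`` is the min-max normalized accessibility difference: each
accessibility vector is min-max normalized to [0, 1] and differenced
elementwise, so values lie in [-1, 1] and negative values mean the first
model understates accessibility relative to the reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catchment import (
    DEFAULT_LAMBDA_GRID,
    ThresholdPolicy,
    accessibility,
)
from .decay_models import ChoiceSpec, Variant


@dataclass
class FitMetrics:
    """Agreement between observed and predicted per-station case counts.

    ``pearson_r``/``p_value`` are NaN when either vector is constant.  MAPE
    is in percent and averages only stations with a positive observed count;
    ``mape_n_excluded`` records how many were left out.
    """

    pearson_r: float
    p_value: float
    mse: float
    rmse: float
    mae: float
    mape: float
    n: int
    mape_n_excluded: int = 0


def fit_metrics(observed, predicted) -> FitMetrics:
    """Score predicted station demand against observed counts."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if o.size < 3:
        raise ValueError("need at least 3 paired stations")

    err = o - p
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(err)))

    pos = o > 0
    if pos.any():
        mape = float(np.mean(np.abs(err[pos]) / o[pos]) * 100.0)
    else:
        mape = math.nan

    if np.ptp(o) == 0 or np.ptp(p) == 0:
        r, pv = math.nan, math.nan
    else:
        r, pv = stats.pearsonr(o, p)

    return FitMetrics(
        pearson_r=float(r),
        p_value=float(pv),
        mse=mse,
        rmse=rmse,
        mae=mae,
        mape=mape,
        n=int(o.size),
        mape_n_excluded=int((~pos).sum()),
    )


def minmax_normalize(values) -> np.ndarray:
    """Rescale a vector to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    span = v.max() - v.min()
    if span == 0:
        warnings.warn("constant vector: min-max normalization returns zeros")
        return np.zeros_like(v)
    return (v - v.min()) / span


def mmad(model1_A, model2_A, ids: Sequence[str] | None = None) -> np.ndarray:
    """Min-max normalized accessibility difference, elementwise in [-1, 1].

    Inputs may be mappings keyed by demand id (aligned by key) or plain
    aligned vectors.  ``model2_A`` is the reference (e.g. the λ = 2.4
    configuration); negative output means model 1 understates accessibility
    relative to it.
    """
    if isinstance(model1_A, Mapping) or isinstance(model2_A, Mapping):
        if not (isinstance(model1_A, Mapping) and isinstance(model2_A, Mapping)):
            raise ValueError("both inputs must be mappings when either is")
        if set(model1_A) != set(model2_A):
            raise ValueError("demand-id sets differ between the two models")
        keys = list(ids) if ids is not None else sorted(model1_A)
        v1 = np.array([model1_A[k] for k in keys], dtype=float)
        v2 = np.array([model2_A[k] for k in keys], dtype=float)
    else:
        v1 = np.asarray(model1_A, dtype=float)
        v2 = np.asarray(model2_A, dtype=float)
        if v1.shape != v2.shape:
            raise ValueError("accessibility vectors have different shapes")
    return minmax_normalize(v1) - minmax_normalize(v2)


def compare_models(
    scenario,
    models: Sequence[Variant] = ("cumr", "kd", "gauss", "gp"),
    lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
    policy: ThresholdPolicy | None = None,
    choice: ChoiceSpec | None = None,
) -> pd.DataFrame:
    """Fit-metric table for each model (one row per λ for GP, plus average).

    ``scenario`` must carry stations, demand points and observed per-station
    case counts.  Baselines get a single row each; the GP variant gets one
    row per λ in ``lambdas`` and an ``Average`` row with the arithmetic mean
    of its per-λ metrics.
    """
    policy = policy or ThresholdPolicy()
    base_choice = choice or ChoiceSpec()
    dm = scenario.distance_matrix()
    observed = np.array(
        [scenario.observed_cases.get(s.id, 0) for s in scenario.stations], dtype=float
    )

    rows = []

    def _row(label: str, model: Variant, lam: float | None) -> None:
        spec = (
            ChoiceSpec(
                lam=lam,
                normalization_scope=base_choice.normalization_scope,
                epsilon_km=base_choice.epsilon_km,
            )
            if lam is not None
            else base_choice
        )
        res = accessibility(scenario.stations, scenario.demand_points, dm, model, spec, policy)
        pred = np.array([res.predicted_demand[s.id] for s in scenario.stations])
        m = fit_metrics(observed, pred)
        rows.append(
            {
                "model": label,
                "lambda": lam,
                "pearson_r": m.pearson_r,
                "p_value": m.p_value,
                "mse": m.mse,
                "rmse": m.rmse,
                "mae": m.mae,
                "mape": m.mape,
            }
        )

    for model in models:
        if model == "gp":
            for lam in lambdas:
                _row(f"gp{lam:.1f}", "gp", lam)
        else:
            _row(model, model, None)

    df = pd.DataFrame(rows)
    gp_rows = df[df["model"].str.startswith("gp")]
    if len(gp_rows) > 0:
        avg = gp_rows[["pearson_r", "p_value", "mse", "rmse", "mae", "mape"]].mean()
        avg_row = {"model": "gp_average", "lambda": np.nan, **avg.to_dict()}
        df.loc[len(df)] = avg_row
    return df
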