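"""Distance-impedance schemes for floating-catchment accessibility.

Three catchment decay weights — rectangular (the classic binary 2SFCA
weight, here the CUMR variant), an Epanechnikov-type kernel-density weight,
and a truncated, renormalized Gaussian — plus the Huff-type inverse-power
selection probability that, multiplied with the Gaussian weight, defines the
GP2SFCA model.

All weight functions accept scalars or arrays and treat the catchment
boundary inclusively: a point exactly at distance ``d0`` is inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

Variant = Literal["cumr", "kd", "gauss", "gp"]

#: Normalization scopes for the selection probability denominator.
ProbScope = Literal["within_threshold", "all_stations"]

_GAUSS_FLOOR = math.exp(-0.5)


@dataclass(frozen=True)
class DecaySpec:
    """A decay variant and its catchment threshold (km)."""

    variant: Variant
    d0: float

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("threshold d0 must be positive")


@dataclass(frozen=True)
class ChoiceSpec:
    """Parameters of the inverse-power station-selection probability.

    ``lam`` is the trip-friction exponent λ: larger values concentrate the
    choice on nearer stations (λ = 2, the gravity-model convention, is the
    common default; the GP2SFCA grid spans 2.0–3.0).  ``normalization_scope``
    selects whether the denominator sums over in-catchment stations only
    (default; keeps supply conserved through the two-step computation) or
    over every candidate station.  ``epsilon_km`` is a distance floor applied
    before exponentiation so a demand point coincident with a station gets
    essentially all the probability mass instead of a division by zero.
    """

    lam: float = 2.0
    normalization_scope: ProbScope = "within_threshold"
    epsilon_km: float = 0.001

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.epsilon_km <= 0:
            raise ValueError("epsilon_km must be positive")
        if self.normalization_scope not in ("within_threshold", "all_stations"):
            raise ValueError(
                f"unknown normalization_scope {self.normalization_scope!r}"
            )


def _check_d(d, d0: float):
    if d0 <= 0:
        raise ValueError("threshold d0 must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return d


def gaussian_weight(d, d0: float):
    """Truncated Gaussian decay, rescaled to hit 1 at d=0 and 0 at d=d0.

    ``(exp(-(d/d0)²/2) - exp(-1/2)) / (1 - exp(-1/2))`` for d ≤ d0, else 0.
    Strictly decreasing on [0, d0] and continuous everywhere.
    """
    d = _check_d(d, d0)
    w = (np.exp(-0.5 * (d / d0) ** 2) - _GAUSS_FLOOR) / (1.0 - _GAUSS_FLOOR)
    w = np.where(d <= d0, w, 0.0)
    return w if w.ndim else float(w)


def kernel_density_weight(d, d0: float):
    """Epanechnikov kernel weight ``(3/4)(1 - (d/d0)²)`` for d ≤ d0, else 0."""
    d = _check_d(d, d0)
    w = 0.75 * (1.0 - (d / d0) ** 2)
    w = np.where(d <= d0, w, 0.0)
    return w if w.ndim else float(w)


def rectangular_weight(d, d0: float):
    """Binary catchment weight: 1 inside the threshold (inclusive), 0 beyond."""
    d = _check_d(d, d0)
    w = np.where(d <= d0, 1.0, 0.0)
    return w if w.ndim else float(w)


def selection_probability(distances, spec: ChoiceSpec) -> np.ndarray:
    """Huff-type choice probabilities over one demand point's candidates.

    ``P_j = d_j^{-λ} / Σ_k d_k^{-λ}`` over the candidate stations supplied.
    Distances below ``spec.epsilon_km`` are clamped to it before
    exponentiation.  The caller decides which stations are candidates (this
    is where the normalization scope is realized); an empty candidate set is
    rejected — unreachable demand points must be handled upstream.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1:
        raise ValueError("distances must be a 1-d vector")
    if d.size == 0:
        raise ValueError("empty candidate station set")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    d = np.maximum(d, spec.epsilon_km)
    # Work in log space: d^{-λ} overflows for tiny d and large λ.
    logw = -spec.lam * np.log(d)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


_WEIGHT_FN = {
    "cumr": rectangular_weight,
    "kd": kernel_density_weight,
    "gauss": gaussian_weight,
    "gp": gaussian_weight,  # gp multiplies this by the selection probability
}


def decay_weight(d, d0: float, variant: Variant):
    """Dispatch to the decay weight for ``variant`` (gp uses the Gaussian)."""
    try:
        fn = _WEIGHT_FN[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}") from None
    return fn(d, d0)
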