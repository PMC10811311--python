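"""Quantifying lung edema against the expected normal lung weight.

Experimental lung injury is traditionally reported as lung weight per kg
body weight.  Because the normal lung weight index itself falls with body
weight, that naive normalization inflates the apparent damage of smaller
animals: two pigs whose lungs both double in weight show very different
g/kg indices.  Normalizing instead to the *expected* normal lung weight
(from the reference equation) makes equal damage read equally.

This module implements the damage ratio (measured over expected weight),
the systematic discrepancy of naive body-weight normalization, and the
maximal under/over-estimation of the damage ratio induced by the 95% CI
band of the reference fit ("maximal" is evaluated at the band endpoint
curves, not by optimizing over the joint parameter region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ExponentialModel, FitResult

__all__ = [
    "DamageAssessment",
    "ErrorBound",
    "damage_ratio",
    "naive_normalization_discrepancy",
    "damage_estimation_error",
    "error_bounds_curve",
    "assess_damage",
]

logger = logging.getLogger(__name__)

#: Body-weight range (kg) over which the reference equation is validated.
VALID_BW_RANGE = (16.0, 52.0)


@dataclass(frozen=True)
class DamageAssessment:
    """Measured vs expected lung weight for one animal."""

    measured_lung_weight: float
    expected_lung_weight: float
    damage_ratio: float
    bw_normalized_index: float


@dataclass(frozen=True)
class ErrorBound:
    """Maximal fractional damage mis-estimation at one body weight."""

    bw: float
    max_underestimation: float
    max_overestimation: float


def damage_ratio(measured: float, expected: float) -> float:
    """Measured lung weight over expected normal lung weight (both g)."""
    if not measured > 0:
        raise ValueError(f"measured lung weight must be > 0 g, got {measured}")
    if not expected > 0:
        raise ValueError(f"expected lung weight must be > 0 g, got {expected}")
    return measured / expected


def assess_damage(
    measured_lung_weight: float, body_weight: float, model: ExponentialModel
) -> DamageAssessment:
    """Full damage assessment of one animal against a reference model."""
    expected = model.predict_lung_weight(body_weight)
    return DamageAssessment(
        measured_lung_weight=measured_lung_weight,
        expected_lung_weight=expected,
        damage_ratio=damage_ratio(measured_lung_weight, expected),
        bw_normalized_index=measured_lung_weight / body_weight,
    )


def naive_normalization_discrepancy(
    bw1: float, bw2: float, damage_factor: float, model: ExponentialModel
) -> float:
    """Apparent excess damage of animal 1 under naive g/kg normalization.

    Both animals suffer the same true damage (lung weight multiplied by
    ``damage_factor``); their damaged weights are divided by body weight
    and the relative difference (index1 - index2) / index1 is returned.
    Under expected-weight normalization this discrepancy would be zero;
    algebraically it does not depend on ``damage_factor`` at all.
    """
    if not damage_factor > 0:
        raise ValueError(f"damage_factor must be > 0, got {damage_factor}")
    idx1 = damage_factor * model.predict_lung_weight(bw1) / bw1
    idx2 = damage_factor * model.predict_lung_weight(bw2) / bw2
    return (idx1 - idx2) / idx1


def damage_estimation_error(
    measured: float, expected_used: float, true_ratio: float
) -> float:
    """Signed fractional error of the damage ratio when ``expected_used``
    stands in for the true expected weight.

    Returns ((measured / expected_used) - true_ratio) / true_ratio;
    negative means the damage is underestimated (the expected weight used
    was too large).
    """
    if not measured > 0:
        raise ValueError(f"measured must be > 0 g, got {measured}")
    if not expected_used > 0:
        raise ValueError(f"expected_used must be > 0 g, got {expected_used}")
    if not true_ratio > 0:
        raise ValueError(f"true_ratio must be > 0, got {true_ratio}")
    return (measured / expected_used - true_ratio) / true_ratio


def _bands(fit) -> tuple[ExponentialModel, ExponentialModel, ExponentialModel]:
    if isinstance(fit, FitResult):
        return fit.model, fit.band_upper, fit.band_lower
    point, upper, lower = fit
    return point, upper, lower


def error_bounds_curve(
    fit: FitResult | tuple[ExponentialModel, ExponentialModel, ExponentialModel],
    bw_grid: Sequence[float],
    damage_factor: float = 2.0,
) -> list[ErrorBound]:
    """Maximal damage-ratio errors along a body-weight grid.

    At each body weight the true damaged lung weight is ``damage_factor``
    times the point-model prediction; using the upper CI band as the
    expected weight gives the worst underestimation, the lower band the
    worst overestimation.  ``fit`` is a :class:`FitResult` or an explicit
    (point, upper band, lower band) model triple.  Grid points outside
    the validated 16-52 kg range are computed but logged as a warning.
    """
    if not damage_factor > 0:
        raise ValueError(f"damage_factor must be > 0, got {damage_factor}")
    point, upper, lower = _bands(fit)
    grid = np.asarray(bw_grid, dtype=float).reshape(-1)
    if np.any(grid <= 0):
        raise ValueError("body-weight grid must be > 0 kg")
    outside = (grid < VALID_BW_RANGE[0]) | (grid > VALID_BW_RANGE[1])
    if np.any(outside):
        logger.warning(
            "%d grid points outside the validated %g-%g kg range",
            int(outside.sum()),
            *VALID_BW_RANGE,
        )
    bounds = []
    for bw in grid:
        true_weight = damage_factor * point.predict_lung_weight(bw)
        under = damage_estimation_error(
            true_weight, upper.predict_lung_weight(bw), damage_factor
        )
        over = damage_estimation_error(
            true_weight, lower.predict_lung_weight(bw), damage_factor
        )
        bounds.append(
            ErrorBound(
                bw=float(bw),
                max_underestimation=abs(min(under, 0.0)),
                max_overestimation=max(over, 0.0),
            )
        )
    return bounds
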