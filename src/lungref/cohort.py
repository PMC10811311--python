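"""Synthetic pig cohorts with the allometric lung-weight structure.

The reference equation was derived from 177 healthy female domestic pigs
(16.5-52 kg) pooled from twelve experimental studies; that cohort is not
publicly deposited.  This module generates synthetic cohorts with the
same statistical structure — body weights uniform over the studied range
and lung weight indices scattered multiplicatively about the exponential
curve — so every downstream stage (fitting, splitting, agreement,
error-bound analysis) is testable end to end without animal data.

Noise is Normal on the log10(LWI) scale.  The default dispersion,
sigma = 0.068 log10 units, matches the residual RMSE of the published
training fit; multiplicative noise also guarantees positive lung
weights, which additive g/kg noise would not.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import ExponentialModel, PORCINE_REFERENCE

__all__ = [
    "Method",
    "PigRecord",
    "CohortSpec",
    "generate_cohort",
    "generate_paired_measurements",
]


class Method(str, enum.Enum):
    """How the lung weight of an animal was obtained."""

    CT = "CT"
    SCALE = "scale"


@dataclass(frozen=True)
class PigRecord:
    """One animal: body weight (kg), lung weight (g), measurement method."""

    animal_id: str
    body_weight: float
    lung_weight: float
    method: Method = Method.CT

    def __post_init__(self) -> None:
        if not (np.isfinite(self.body_weight) and self.body_weight > 0):
            raise ValueError(
                f"body_weight must be finite and > 0 kg, got {self.body_weight}"
            )
        if not (np.isfinite(self.lung_weight) and self.lung_weight > 0):
            raise ValueError(
                f"lung_weight must be finite and > 0 g, got {self.lung_weight}"
            )
        object.__setattr__(self, "method", Method(self.method))

    @property
    def lung_weight_index(self) -> float:
        """Lung weight divided by body weight, g/kg."""
        return self.lung_weight / self.body_weight


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    Defaults emulate the published study population: body weights uniform
    on 16.5-52 kg, indices generated from the published reference equation
    with log10-scale noise SD 0.068.
    """

    n: int
    seed: int
    bw_low: float = 16.5
    bw_high: float = 52.0
    true_model: ExponentialModel = PORCINE_REFERENCE
    noise_sigma_log10: float = 0.068
    method: Method = Method.CT

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not self.bw_low < self.bw_high:
            raise ValueError(
                f"bw_low must be < bw_high, got {self.bw_low} >= {self.bw_high}"
            )
        if self.bw_low <= 0:
            raise ValueError(f"bw_low must be > 0 kg, got {self.bw_low}")
        if self.noise_sigma_log10 < 0:
            raise ValueError(
                f"noise_sigma_log10 must be >= 0, got {self.noise_sigma_log10}"
            )


def generate_cohort(spec: CohortSpec) -> list[PigRecord]:
    """Draw a synthetic cohort; deterministic given ``spec.seed``.

    Body weights BW_i ~ Uniform(bw_low, bw_high);
    log10(LWI_i) = log10(a) + b*BW_i + eps_i with eps_i ~ N(0, sigma);
    lung weight = LWI_i * BW_i.
    """
    rng = np.random.default_rng(spec.seed)
    bw = rng.uniform(spec.bw_low, spec.bw_high, spec.n)
    log_lwi = np.log10(spec.true_model.a) + spec.true_model.b * bw
    if spec.noise_sigma_log10 > 0:
        log_lwi = log_lwi + rng.normal(0.0, spec.noise_sigma_log10, spec.n)
    lung_weight = 10.0**log_lwi * bw
    records = [
        PigRecord(f"pig{i:04d}", float(bw[i]), float(lung_weight[i]), spec.method)
        for i in range(spec.n)
    ]
    assert all(r.lung_weight > 0 for r in records)
    return records


def generate_paired_measurements(
    n: int,
    model: ExponentialModel = PORCINE_REFERENCE,
    noise_sigma_log10: float = 0.068,
    seed: int = 0,
    bw_low: float = 16.5,
    bw_high: float = 52.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (measured, expected) lung weight indices at sampled body weights.

    "Expected" is the noiseless model prediction; "measured" multiplies it
    by 10**eps with eps ~ N(0, sigma).  Feeds the Bland-Altman stage the
    same way a validation cohort is compared against the reference curve.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 pairs for agreement analysis, got {n}")
    if noise_sigma_log10 < 0:
        raise ValueError(f"noise_sigma_log10 must be >= 0, got {noise_sigma_log10}")
    rng = np.random.default_rng(seed)
    bw = rng.uniform(bw_low, bw_high, n)
    expected = model.predict_lwi(bw)
    if noise_sigma_log10 > 0:
        measured = expected * 10.0 ** rng.normal(0.0, noise_sigma_log10, n)
    else:
        measured = expected.copy()
    return measured, expected
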