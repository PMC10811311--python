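"""Bland-Altman agreement between measured and model-expected indices.

Quantifies how well the reference equation predicts the actually measured
lung weight index: bias is the mean of the paired differences
(measured - expected), the limits of agreement (LOAs) are bias +/- 1.96
times the SD of the differences, and 95% confidence intervals are
attached to the bias (SE = sd/sqrt(n), t quantile) and to each LOA
(SE = sd*sqrt(3/n), the standard large-sample approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementResult", "bland_altman"]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Bias, limits of agreement and their 95% CIs, all in g/kg."""

    bias: float
    bias_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    sd_diff: float
    n: int

    def to_dict(self) -> dict:
        return {
            "bias_g_per_kg": self.bias,
            "bias_ci": list(self.bias_ci),
            "loa_upper_g_per_kg": self.loa_upper,
            "loa_upper_ci": list(self.loa_upper_ci),
            "loa_lower_g_per_kg": self.loa_lower,
            "loa_lower_ci": list(self.loa_lower_ci),
            "sd_diff_g_per_kg": self.sd_diff,
            "n": self.n,
        }


def bland_altman(measured, expected) -> AgreementResult:
    """Bland-Altman analysis of paired series, differences measured - expected.

    The difference direction is fixed: a negative bias means the measured
    index falls below what the reference equation expects.  The LOA
    multiplier is the conventional 1.96 (not a t quantile); the CIs use
    t quantiles with n - 1 degrees of freedom.
    """
    m = np.asarray(measured, dtype=float).reshape(-1)
    e = np.asarray(expected, dtype=float).reshape(-1)
    if m.shape != e.shape:
        raise ValueError(
            f"measured ({m.size}) and expected ({e.size}) lengths differ"
        )
    n = int(m.size)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(e))):
        raise ValueError("measured and expected must be finite")

    d = m - e
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    tq = float(stats.t.ppf(0.975, df=n - 1))
    half_bias = tq * sd / np.sqrt(n)
    half_loa = tq * sd * np.sqrt(3.0 / n)
    loa_up = bias + LOA_MULTIPLIER * sd
    loa_lo = bias - LOA_MULTIPLIER * sd
    return AgreementResult(
        bias=bias,
        bias_ci=(bias - half_bias, bias + half_bias),
        loa_upper=loa_up,
        loa_upper_ci=(loa_up - half_loa, loa_up + half_loa),
        loa_lower=loa_lo,
        loa_lower_ci=(loa_lo - half_loa, loa_lo + half_loa),
        sd_diff=sd,
        n=n,
    )
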