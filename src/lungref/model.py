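"""Exponential lung-weight-index reference model for growing pigs.

The normal lung weight of a pig does not scale linearly with body weight:
the lung weight index (LWI, lung weight divided by body weight, g/kg)
decreases as the animal grows.  Over the 16-50 kg range this is well
described by a single-exponential (log-linear) relationship

    LWI(BW) = a * 10**(b * BW)

with ``a`` in g/kg (the extrapolated index at zero body weight) and ``b``
in 1/kg (the base-10 decay rate per kilogram).  The published porcine
reference fit is a = 26.26 g/kg, b = -0.011 kg^-1, with parameter-wise
95% CI band curves (28.84, -0.009) above and (23.44, -0.013) below.

This module provides the model container, a scikit-learn style regressor
that fits the relationship by ordinary least squares of log10(LWI) on BW
(with an optional natural-scale nonlinear fit), and the surrounding
train/validation-split, evaluation and cross-validation machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExponentialModel",
    "ExponentialIndexRegressor",
    "FitResult",
    "SplitSpec",
    "PORCINE_REFERENCE",
    "PORCINE_REFERENCE_UPPER",
    "PORCINE_REFERENCE_LOWER",
    "fit_exponential",
    "predict_lwi",
    "predict_lung_weight",
    "split_cohort",
    "evaluate",
    "cross_validate",
]


@dataclass(frozen=True)
class ExponentialModel:
    """LWI = a * 10**(b * BW); ``a`` in g/kg, ``b`` in 1/kg."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("model parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"prefactor a must be > 0, got {self.a}")

    def predict_lwi(self, bw):
        """Predicted lung weight index (g/kg) at body weight ``bw`` (kg)."""
        bw = _check_bw(bw)
        return self.a * 10.0 ** (self.b * bw)

    def predict_lung_weight(self, bw):
        """Predicted absolute lung weight (g) at body weight ``bw`` (kg)."""
        bw = _check_bw(bw)
        return self.predict_lwi(bw) * bw

    def to_dict(self) -> dict:
        return {"a_g_per_kg": self.a, "b_per_kg": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "ExponentialModel":
        return cls(a=d["a_g_per_kg"], b=d["b_per_kg"])


#: Published reference equation for female domestic pigs, 16-50 kg.
PORCINE_REFERENCE = ExponentialModel(a=26.26, b=-0.011)
#: Upper and lower 95% CI band curves of the published fit (parameter-wise).
PORCINE_REFERENCE_UPPER = ExponentialModel(a=28.84, b=-0.009)
PORCINE_REFERENCE_LOWER = ExponentialModel(a=23.44, b=-0.013)


def _check_bw(bw):
    bw = np.asarray(bw, dtype=float)
    if not np.all(np.isfinite(bw)) or np.any(bw <= 0):
        raise ValueError("body weight must be finite and > 0 kg")
    return bw if bw.ndim else float(bw)


def _extract_arrays(cohort) -> tuple[np.ndarray, np.ndarray]:
    """Body weights (kg) and LWIs (g/kg) from records or a (bw, lwi) pair."""
    records = list(cohort)
    if not records:
        raise ValueError("cohort is empty")
    bw = np.array([r.body_weight for r in records], dtype=float)
    lwi = np.array([r.lung_weight / r.body_weight for r in records], dtype=float)
    return bw, lwi


class ExponentialIndexRegressor(RegressorMixin, BaseEstimator):
    """Fit LWI = a * 10**(b * BW) to (body weight, lung weight index) data.

    Parameters
    ----------
    scale : {"log10", "natural"}, default "log10"
        "log10" fits by ordinary least squares of log10(LWI) on BW and
        back-transforms the intercept (the default, matching how the
        reference equation and its residual statistics are defined).
        "natural" fits the exponential directly by nonlinear least
        squares on the g/kg scale; residual summaries are still reported
        on the log10 scale so they stay comparable.
    alpha : float, default 0.05
        Two-sided confidence level for parameter intervals is 1 - alpha.

    Attributes
    ----------
    a_, b_ : float
        Fitted prefactor (g/kg) and exponent coefficient (1/kg).
    a_ci_, b_ci_ : tuple of float
        95% confidence intervals; the ``a`` interval is the
        back-transformed intercept interval under scale="log10".
    band_upper_, band_lower_ : ExponentialModel
        Parameter-wise CI band curves, pairing the upper (resp. lower)
        bounds of ``a`` and ``b``.  These are not pointwise prediction
        bands; see the package methods note.
    rmse_log10_, mae_log10_ : float
        Residual summaries of log10(LWI) about the fitted curve.
    residuals_ : ndarray
        Per-animal log10 residuals, in input order.
    n_ : int
        Number of fitted animals.
    """

    def __init__(self, scale: str = "log10", alpha: float = 0.05):
        self.scale = scale
        self.alpha = alpha

    def fit(self, X, y):
        if self.scale not in ("log10", "natural"):
            raise ValueError(f"scale must be 'log10' or 'natural', got {self.scale!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        bw = np.asarray(X, dtype=float).reshape(-1)
        lwi = np.asarray(y, dtype=float).reshape(-1)
        if bw.shape != lwi.shape:
            raise ValueError("X and y have different lengths")
        if bw.size < 3:
            raise ValueError(f"need at least 3 animals to fit, got {bw.size}")
        if np.any(lwi <= 0) or not np.all(np.isfinite(lwi)):
            raise ValueError("lung weight index must be finite and > 0")
        _check_bw(bw)
        if np.ptp(bw) == 0:
            raise ValueError("body weights are all identical; fit is singular")

        log_lwi = np.log10(lwi)
        ols = sm.OLS(log_lwi, sm.add_constant(bw)).fit()
        if self.scale == "log10":
            intercept, slope = ols.params
            ci = ols.conf_int(alpha=self.alpha)
            a, b = 10.0**intercept, slope
            a_ci = (10.0 ** ci[0, 0], 10.0 ** ci[0, 1])
            b_ci = (ci[1, 0], ci[1, 1])
        else:
            a, b, a_ci, b_ci = self._fit_natural(bw, lwi, ols.params)

        self.a_, self.b_ = float(a), float(b)
        self.a_ci_ = (float(a_ci[0]), float(a_ci[1]))
        self.b_ci_ = (float(b_ci[0]), float(b_ci[1]))
        self.band_upper_ = ExponentialModel(self.a_ci_[1], self.b_ci_[1])
        self.band_lower_ = ExponentialModel(self.a_ci_[0], self.b_ci_[0])
        self.residuals_ = log_lwi - (np.log10(self.a_) + self.b_ * bw)
        self.rmse_log10_ = float(np.sqrt(np.mean(self.residuals_**2)))
        self.mae_log10_ = float(np.mean(np.abs(self.residuals_)))
        self.n_ = int(bw.size)
        return self

    def _fit_natural(self, bw, lwi, log_params):
        p0 = (10.0 ** log_params[0], log_params[1])
        popt, pcov = optimize.curve_fit(
            lambda x, a, b: a * 10.0 ** (b * x), bw, lwi, p0=p0, maxfev=10000
        )
        tq = stats.t.ppf(1 - self.alpha / 2, df=bw.size - 2)
        se = np.sqrt(np.diag(pcov))
        a_ci = (popt[0] - tq * se[0], popt[0] + tq * se[0])
        b_ci = (popt[1] - tq * se[1], popt[1] + tq * se[1])
        return popt[0], popt[1], a_ci, b_ci

    def predict(self, X):
        check_is_fitted(self, "a_")
        bw = np.asarray(X, dtype=float).reshape(-1)
        return self.model_.predict_lwi(bw)

    @property
    def model_(self) -> ExponentialModel:
        check_is_fitted(self, "a_")
        return ExponentialModel(self.a_, self.b_)

    def result_(self) -> "FitResult":
        check_is_fitted(self, "a_")
        return FitResult(
            model=self.model_,
            a_ci=self.a_ci_,
            b_ci=self.b_ci_,
            band_upper=self.band_upper_,
            band_lower=self.band_lower_,
            rmse_log10=self.rmse_log10_,
            mae_log10=self.mae_log10_,
            n=self.n_,
            residuals=np.array(self.residuals_),
        )


@dataclass(frozen=True)
class FitResult:
    """Fitted reference model with CIs, band curves and residual summaries."""

    model: ExponentialModel
    a_ci: tuple[float, float]
    b_ci: tuple[float, float]
    band_upper: ExponentialModel
    band_lower: ExponentialModel
    rmse_log10: float
    mae_log10: float
    n: int
    residuals: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "a_ci": list(self.a_ci),
            "b_ci": list(self.b_ci),
            "band_upper": self.band_upper.to_dict(),
            "band_lower": self.band_lower.to_dict(),
            "rmse_log10": self.rmse_log10,
            "mae_log10": self.mae_log10,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            model=ExponentialModel.from_dict(d["model"]),
            a_ci=tuple(d["a_ci"]),
            b_ci=tuple(d["b_ci"]),
            band_upper=ExponentialModel.from_dict(d["band_upper"]),
            band_lower=ExponentialModel.from_dict(d["band_lower"]),
            rmse_log10=d["rmse_log10"],
            mae_log10=d["mae_log10"],
            n=d["n"],
            residuals=np.array(d.get("residuals", [])),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split: training fraction in (0, 1) plus a seed."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def fit_exponential(cohort: Iterable, scale: str = "log10") -> FitResult:
    """Fit the exponential LWI reference equation to a cohort of pig records."""
    bw, lwi = _extract_arrays(cohort)
    reg = ExponentialIndexRegressor(scale=scale).fit(bw, lwi)
    return reg.result_()


def predict_lwi(model: ExponentialModel, bw):
    """Lung weight index (g/kg) the model predicts at body weight ``bw`` (kg)."""
    return model.predict_lwi(bw)


def predict_lung_weight(model: ExponentialModel, bw):
    """Absolute lung weight (g) the model predicts at body weight ``bw`` (kg)."""
    return model.predict_lung_weight(bw)


def split_cohort(cohort: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Random disjoint train/validation partition, deterministic given seed.

    The training size is floor(n * train_fraction), clamped so both parts
    are non-empty; this reproduces the published 141/36 partition of 177
    animals at an 80% training fraction.
    """
    records = list(cohort)
    n = len(records)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    n_train = int(n * spec.train_fraction)
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    train = [records[i] for i in sorted(perm[:n_train])]
    valid = [records[i] for i in sorted(perm[n_train:])]
    return train, valid


def evaluate(model: ExponentialModel, cohort: Iterable) -> tuple[float, float]:
    """RMSE and MAE of log10(LWI) residuals of ``cohort`` about ``model``."""
    bw, lwi = _extract_arrays(cohort)
    r = np.log10(lwi) - np.log10(model.predict_lwi(bw))
    return float(np.sqrt(np.mean(r**2))), float(np.mean(np.abs(r)))


def cross_validate(cohort: Sequence, k: int = 5, seed: int = 0) -> dict:
    """k-fold cross-validation of the exponential fit.

    Fits on k-1 folds and evaluates on the held-out fold; folds are a
    disjoint, exhaustive shuffle-split, deterministic given ``seed``.
    Returns per-fold RMSE/MAE on the log10 scale plus their means.
    """
    records = list(cohort)
    n = len(records)
    if not 2 <= k <= n:
        raise ValueError(f"fold count k must satisfy 2 <= k <= n={n}, got {k}")
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    rmse, mae = [], []
    for train_idx, test_idx in folds.split(np.arange(n)):
        fit = fit_exponential([records[i] for i in train_idx])
        r, m = evaluate(fit.model, [records[i] for i in test_idx])
        rmse.append(r)
        mae.append(m)
    return {
        "rmse_log10": rmse,
        "mae_log10": mae,
        "mean_rmse_log10": float(np.mean(rmse)),
        "mean_mae_log10": float(np.mean(mae)),
        "k": k,
    }
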