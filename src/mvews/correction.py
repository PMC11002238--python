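"""Index normalization and number-of-observations bias correction.

Indices computed on windows with fewer observations are systematically
biased (e.g. coefficients of variation shrink with n).  Each index is first
transformed toward symmetry if needed, then regressed on a small menu of
n-trends; the best-fitting trend (by AIC) is subtracted, preserving the
overall mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import skew

logger = logging.getLogger(__name__)

#: Candidate bias families, in tie-break order (simplest first).
FAMILIES = ("none", "linear", "log_n", "sqrt_n", "inverse_n")


def _regressor(family: str, n: np.ndarray) -> np.ndarray | None:
    n = np.asarray(n, dtype=float)
    if family == "none":
        return None
    if family == "linear":
        return n
    if family == "log_n":
        return np.log(n)
    if family == "sqrt_n":
        return np.sqrt(n)
    if family == "inverse_n":
        return 1.0 / n
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TransformChoice:
    """Skew-minimizing transform applied to an index before bias fitting."""

    kind: str  # identity | log | sqrt
    shift: float = 0.0
    eps: float = 0.0

    def apply(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return v
        if self.kind == "log":
            return np.log(v - self.shift + self.eps)
        if self.kind == "sqrt":
            return np.sqrt(np.clip(v - self.shift, 0.0, None))
        raise ValueError(f"unknown transform {self.kind!r}")


@dataclass
class CorrectionModel:
    """Fitted n_obs bias trend for one index."""

    index_name: str
    family: str
    coefficients: tuple[float, ...]
    aic: float
    grand_mean: float
    n_range: tuple[float, float] = (0.0, np.inf)

    def predict(self, n_obs: np.ndarray) -> np.ndarray:
        n = np.asarray(n_obs, dtype=float)
        if self.family == "none":
            return np.full(n.shape, self.grand_mean)
        a, b = self.coefficients
        return a + b * _regressor(self.family, n)

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "family": self.family,
            "coefficients": list(self.coefficients),
            "aic": self.aic,
            "grand_mean": self.grand_mean,
            "n_range": list(self.n_range),
        }


def choose_index_transform(values: np.ndarray) -> tuple[TransformChoice, np.ndarray]:
    """Pick the transform (identity / log / sqrt of shifted values) that
    minimizes absolute sample skewness; below 30 values fall back to
    identity with a warning."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    identity = TransformChoice("identity")
    if v.size < 30:
        warnings.warn("fewer than 30 values; keeping identity transform", stacklevel=2)
        return identity, np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("constant values; skewness undefined, keeping identity", stacklevel=2)
        return identity, np.asarray(values, dtype=float)
    eps = 1e-3 * (hi - lo)
    candidates = [
        identity,
        TransformChoice("log", shift=lo, eps=eps),
        TransformChoice("sqrt", shift=lo),
    ]
    best, best_skew = None, np.inf
    for cand in candidates:
        t = cand.apply(v)
        s = abs(float(skew(t)))
        if np.isfinite(s) and s < best_skew - 1e-12:
            best, best_skew = cand, s
    best = best or identity
    return best, best.apply(np.asarray(values, dtype=float))


def fit_nobs_bias(values: np.ndarray, n_obs: np.ndarray, index_name: str = "") -> CorrectionModel:
    """Fit value ~ f(n_obs) for each candidate family and keep the AIC
    minimizer (ties break toward the simpler family)."""
    v = np.asarray(values, dtype=float)
    n = np.asarray(n_obs, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(n))
    v, n = v[ok], n[ok]
    if v.size == 0:
        raise ValueError("no values to fit")
    grand_mean = float(v.mean())
    nr = (float(n.min()), float(n.max())) if n.size else (0.0, np.inf)
    if np.unique(n).size < 3:
        rss0 = float(np.sum((v - grand_mean) ** 2))
        aic0 = _aic(rss0, v.size, 1)
        return CorrectionModel(index_name, "none", (grand_mean,), aic0, grand_mean, nr)
    best = None
    for family in FAMILIES:
        if family == "none":
            rss = float(np.sum((v - grand_mean) ** 2))
            aic = _aic(rss, v.size, 1)
            coef = (grand_mean,)
        else:
            reg = _regressor(family, n)
            x = np.column_stack([np.ones_like(reg), reg])
            beta, *_ = np.linalg.lstsq(x, v, rcond=None)
            rss = float(np.sum((v - x @ beta) ** 2))
            aic = _aic(rss, v.size, 2)
            coef = tuple(float(b) for b in beta)
        if best is None or aic < best.aic - 1e-9:
            best = CorrectionModel(index_name, family, coef, aic, grand_mean, nr)
    return best


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood profile; +1 parameter for the variance
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (k + 1)


def apply_correction(values: np.ndarray, n_obs: np.ndarray, model: CorrectionModel) -> np.ndarray:
    """corrected = value - fitted_trend(n) + grand_mean.

    Preserves the overall mean on the training data exactly (OLS residuals
    sum to zero).  n outside the fitted range extrapolates with a warning.
    """
    n = np.asarray(n_obs, dtype=float)
    lo, hi = model.n_range
    if np.any((n < lo) | (n > hi)):
        logger.warning("n_obs outside fitted range [%g, %g]; extrapolating", lo, hi)
    return np.asarray(values, dtype=float) - model.predict(n) + model.grand_mean


def correct_index_table(
    records: pd.DataFrame, min_values: int = 30
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Transform + bias-correct every index in a long record table.

    Adds a ``corrected_value`` column; returns the table and the per-index
    models (transform choice + bias family) for reuse.
    """
    out = records.copy()
    out["corrected_value"] = np.nan
    models: dict[str, dict] = {}
    for name, grp in records.groupby("index_name"):
        vals = grp["raw_value"].to_numpy(dtype=float)
        ns = grp["n_obs"].to_numpy(dtype=float)
        with warnings.catch_warnings():
            if len(vals) < min_values:
                warnings.simplefilter("ignore")
            choice, tvals = choose_index_transform(vals)
        model = fit_nobs_bias(tvals, ns, index_name=name)
        corrected = apply_correction(tvals, ns, model)
        out.loc[grp.index, "corrected_value"] = corrected
        models[name] = {"transform": choice.kind, "shift": choice.shift, "eps": choice.eps} | model.to_dict()
    return out, models
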