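"""Descriptive comparison of indices: pairwise correlations, pre-death
trend curves, and two-segment change-point fits."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats



@dataclass
class CorrelationMatrix:
    names: list[str]
    r: pd.DataFrame
    p_value: pd.DataFrame
    n_pairs: pd.DataFrame

    def long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.names):
            for b in self.names[i + 1:]:
                rows.append(
                    {
                        "index_a": a,
                        "index_b": b,
                        "r": self.r.loc[a, b],
                        "p_value": self.p_value.loc[a, b],
                        "n_pairs": self.n_pairs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def records_to_wide(records: pd.DataFrame, value_col: str = "corrected_value") -> pd.DataFrame:
    """Pivot a long index-record table to (patient, window) x index."""
    return records.pivot_table(
        index=["patient_id", "window_index"],
        columns="index_name",
        values=value_col,
        aggfunc="first",
    )


def pairwise_correlations(wide: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Cells with fewer than ``min_pairs`` matched records are NaN.
    """
    names = list(wide.columns)
    k = len(names)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    x = wide.to_numpy(dtype=float)
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(np.sum(~np.isnan(x[:, i])))
        for j in range(i + 1, k):
            ok = ~(np.isnan(x[:, i]) | np.isnan(x[:, j]))
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            a, b = x[ok, i], x[ok, j]
            if a.std() == 0 or b.std() == 0:
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    mk = lambda m: pd.DataFrame(m, index=names, columns=names)
    return CorrelationMatrix(names, mk(r), mk(p), mk(n))


@dataclass
class TrendCurve:
    """Binned pre-death mean of a cohort-z-scored index, recentered so the
    earliest (furthest from death) bin sits at zero."""

    index_name: str
    bin_mid_months: np.ndarray  # descending: far from death -> death
    mean_z: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index_name": self.index_name,
                "bin_mid_months": self.bin_mid_months,
                "mean_z": self.mean_z,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "n": self.n,
            }
        )


def trend_before_death(
    records: pd.DataFrame,
    patients: pd.DataFrame,
    horizon_years: float = 5.0,
    bin_months: float = 6.0,
    value_col: str = "corrected_value",
) -> dict[str, TrendCurve]:
    """Per-index binned trend over the years preceding death (uncensored
    patients only), z-scored cohort-wide and centered at the earliest bin."""
    died = set(patients.loc[patients["died"] == 1, "patient_id"])
    sel = records[records["patient_id"].isin(died)].copy()
    horizon = horizon_years * 12.0
    sel = sel[sel["months_before_anchor"] <= horizon]
    n_bins = int(round(horizon / bin_months))
    edges = np.arange(n_bins + 1) * bin_months
    curves: dict[str, TrendCurve] = {}
    for name, grp in sel.groupby("index_name"):
        v = grp[value_col].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd):
            continue
        z = (v - np.nanmean(v)) / sd if sd > 0 else np.zeros_like(v)
        t = grp["months_before_anchor"].to_numpy(dtype=float)
        which = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
        mids, means, los, his, ns = [], [], [], [], []
        for b in range(n_bins - 1, -1, -1):  # far from death first
            mask = which == b
            mids.append((edges[b] + edges[b + 1]) / 2.0)
            ns.append(int(mask.sum()))
            if mask.sum() == 0:
                means.append(np.nan)
                los.append(np.nan)
                his.append(np.nan)
                continue
            m = float(np.nanmean(z[mask]))
            se = float(np.nanstd(z[mask], ddof=1) / np.sqrt(mask.sum())) if mask.sum() > 1 else 0.0
            means.append(m)
            los.append(m - 1.96 * se)
            his.append(m + 1.96 * se)
        means = np.array(means)
        base_idx = next((i for i, m in enumerate(means) if np.isfinite(m)), None)
        if base_idx is None:
            continue
        base = means[base_idx]
        curves[name] = TrendCurve(
            index_name=name,
            bin_mid_months=np.array(mids),
            mean_z=means - base,
            ci95_low=np.array(los) - base,
            ci95_high=np.array(his) - base,
            n=np.array(ns),
        )
    return curves


@dataclass
class ChangePointFit:
    index_name: str
    cp_months: float
    ci95: tuple[float, float]
    slope_before: float  # on the far-from-death segment, per month
    slope_after: float  # on the near-death segment, per month
    n: int

    @property
    def no_change_point(self) -> bool:
        lo, hi = self.ci95
        return not np.isfinite(lo) or not np.isfinite(hi)


def _profile_fit(
    t_levels: np.ndarray,
    grid: np.ndarray,
    w: np.ndarray,
    s: np.ndarray,
    q: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted two-segment hinge fits over a change-point grid.

    ``w, s, q`` are (B, T) per-time-level weights, weighted sums of y and of
    y^2 for B (bootstrap) replicates; returns (best cp per replicate,
    (B, n_grid, 3) coefficient array for the best fit extraction).
    """
    B, T = w.shape
    G = grid.size
    rss = np.full((B, G), np.inf)
    betas = np.zeros((B, G, 3))
    q_tot = q.sum(axis=1)  # (B,)
    for g, cp in enumerate(grid):
        x = np.column_stack([np.ones_like(t_levels), t_levels, np.maximum(cp - t_levels, 0.0)])
        a = np.einsum("ti,bt,tj->bij", x, w, x)
        a += 1e-10 * np.eye(3)
        b = np.einsum("ti,bt->bi", x, s)
        beta = np.linalg.solve(a, b[..., None])[..., 0]
        rss[:, g] = q_tot - 2 * np.einsum("bi,bi->b", beta, b) + np.einsum(
            "bi,bij,bj->b", beta, a, beta
        )
        betas[:, g] = beta
    best = np.argmin(rss, axis=1)
    return best, betas


def fit_change_point(
    months_before_death: np.ndarray,
    values: np.ndarray,
    patient_ids: np.ndarray,
    grid_step: float = 0.5,
    n_boot: int = 500,
    seed: int = 0,
    index_name: str = "",
) -> ChangePointFit:
    """Two-segment continuous piecewise-linear fit by profile least squares
    over a candidate change-point grid, with a patient-resampled bootstrap
    CI.

    The change point is the hinge location (months before death) minimizing
    the residual sum of squares.
    """
    t = np.asarray(months_before_death, dtype=float)
    y = np.asarray(values, dtype=float)
    pids = np.asarray(patient_ids)
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y, pids = t[ok], y[ok], pids[ok]
    levels = np.unique(t)
    if levels.size < 8:
        raise ValueError("need >= 8 distinct time points for a change-point fit")
    g0 = np.ceil(levels.min() / grid_step + 1) * grid_step
    g1 = np.floor(levels.max() / grid_step - 1) * grid_step
    grid = np.arange(g0, g1 + grid_step / 2, grid_step)
    if grid.size == 0:
        raise ValueError("degenerate change-point grid")

    # collapse to sufficient statistics per (patient, time level)
    uniq_pids, pidx = np.unique(pids, return_inverse=True)
    tidx = np.searchsorted(levels, t)
    P, T = uniq_pids.size, levels.size
    c_pt = np.zeros((P, T))
    s_pt = np.zeros((P, T))
    q_pt = np.zeros((P, T))
    np.add.at(c_pt, (pidx, tidx), 1.0)
    np.add.at(s_pt, (pidx, tidx), y)
    np.add.at(q_pt, (pidx, tidx), y**2)

    ones = np.ones((1, P))
    best, betas = _profile_fit(levels, grid, ones @ c_pt, ones @ s_pt, ones @ q_pt)
    cp = float(grid[best[0]])
    beta = betas[0, best[0]]
    slope_before = float(beta[1])
    slope_after = float(beta[1] - beta[2])

    rng = np.random.default_rng(seed)
    if n_boot > 0:
        draws = rng.integers(0, P, size=(n_boot, P))
        mult = np.zeros((n_boot, P))
        for b in range(n_boot):
            np.add.at(mult[b], draws[b], 1.0)
        bbest, _ = _profile_fit(levels, grid, mult @ c_pt, mult @ s_pt, mult @ q_pt)
        cps = grid[bbest]
        lo, hi = np.percentile(cps, [2.5, 97.5])
        lo, hi = min(lo, cp), max(hi, cp)  # CI must contain the estimate
    else:
        lo, hi = np.nan, np.nan
    return ChangePointFit(
        index_name=index_name,
        cp_months=cp,
        ci95=(float(lo), float(hi)),
        slope_before=slope_before,
        slope_after=slope_after,
        n=int(y.size),
    )
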