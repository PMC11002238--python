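"""The 15 multivariate early-warning-signal indices (plus per-visit MMD).

Index registry
--------------
variance-based:          Av_Var, NMV, Max_cov, PC_var, Ex_var, CVPC1
autocorrelation-based:   Av_Ac, Max_ac, MAF_ac, MAF_ev, MI
cross-correlation-based: Av_ab_cc
variance + AC:           Df, MAF_var, MMD (and unaveraged MMD_all)

All window-level indices take a :class:`~mvews.preprocess.WindowSample`
whose matrix is the (transformed, z-scored) observation block; CVPC1 is the
exception and is computed cohort-wide from per-window coefficients of
variation on the transformed but *not* z-scored scale.

Undefined values propagate as NaN / missing records, never as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .correction import apply_correction, fit_nobs_bias
from .preprocess import WindowSample

logger = logging.getLogger(__name__)

VARIANCE_INDICES = ("Av_Var", "NMV", "Max_cov", "PC_var", "Ex_var", "CVPC1")
AC_INDICES = ("Av_Ac", "Max_ac", "MAF_ac", "MAF_ev", "MI")
CROSSCORR_INDICES = ("Av_ab_cc",)
MIXED_INDICES = ("Df", "MAF_var", "MMD")

INDEX_NAMES = VARIANCE_INDICES + AC_INDICES + CROSSCORR_INDICES + MIXED_INDICES + ("MMD_all",)

INDEX_CATEGORY = (
    {n: "variance" for n in VARIANCE_INDICES}
    | {n: "autocorrelation" for n in AC_INDICES}
    | {n: "cross-correlation" for n in CROSSCORR_INDICES}
    | {n: "variance+AC" for n in MIXED_INDICES}
    | {"MMD_all": "variance+AC"}
)

MIN_OBS_MAF = 13
MI_R2_CAP = 1.0 - 1e-12


# ---------------------------------------------------------------------------
# window-level building blocks


def window_covariance(window: WindowSample | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete covariance (ddof=1) and complete-pair counts.

    Entries with fewer than 2 complete pairs are NaN.  The pairwise-complete
    matrix is not guaranteed PSD.
    """
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    counts = (~np.isnan(x)).astype(int).T @ (~np.isnan(x)).astype(int)
    if not np.any(np.diag(counts) >= 2):
        raise ValueError("no variable with >= 2 observations")
    if x.shape[0] >= 2 and not np.isnan(x).any():
        return np.atleast_2d(np.cov(x, rowvar=False, ddof=1)), counts
    cov = pd.DataFrame(x).cov(min_periods=2).to_numpy()
    return cov, counts


def complete_case_submatrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows complete across the columns that have any observation.

    Returns (submatrix, column indices kept).
    """
    x = np.asarray(x, dtype=float)
    cols = np.where((~np.isnan(x)).sum(axis=0) >= 2)[0]
    if cols.size == 0:
        return np.empty((0, 0)), cols
    sub = x[:, cols]
    rows = ~np.isnan(sub).any(axis=1)
    return sub[rows], cols


def lag1_ac(series: np.ndarray) -> float:
    """Lag-1 autocorrelation: Pearson r of consecutive observed values.

    Missing entries are dropped first; needs >= 3 observations.
    """
    s = np.asarray(series, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 3:
        return np.nan
    a, b = s[:-1], s[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# index families


def variance_indices(window: WindowSample | np.ndarray) -> dict[str, float]:
    """Av_Var, NMV, Max_cov, PC_var, Ex_var for one window."""
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    cov, _ = window_covariance(x)
    d = np.diag(cov)
    out = {
        "Av_Var": float(np.nanmean(d)) if np.any(~np.isnan(d)) else np.nan,
        "NMV": float(np.nanmax(d)) if np.any(~np.isnan(d)) else np.nan,
    }
    off = cov[~np.eye(cov.shape[0], dtype=bool)]
    out["Max_cov"] = float(np.nanmax(np.abs(off))) if np.any(~np.isnan(off)) else np.nan

    sub, cols = complete_case_submatrix(x)
    if sub.shape[0] >= 3 and cols.size >= 2:
        c = np.cov(sub, rowvar=False, ddof=1)
        lam = np.linalg.eigvalsh(c)
        lam1 = float(lam[-1])
        tr = float(np.trace(c))
        out["PC_var"] = lam1
        out["Ex_var"] = lam1 / tr if tr > 0 else np.nan
    else:
        out["PC_var"] = np.nan
        out["Ex_var"] = np.nan
    return out


def autocorrelation_indices(window: WindowSample | np.ndarray) -> dict[str, float]:
    """Av_Ac and Max_ac: mean/max per-variable lag-1 autocorrelation."""
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    acs = np.array([lag1_ac(x[:, j]) for j in range(x.shape[1])])
    ok = ~np.isnan(acs)
    if not ok.any():
        return {"Av_Ac": np.nan, "Max_ac": np.nan}
    return {"Av_Ac": float(acs[ok].mean()), "Max_ac": float(acs[ok].max())}


@dataclass
class MafDecomposition:
    """Min/max autocorrelation factors of one window.

    Factors (unit Euclidean norm) are ordered by increasing smoothness
    eigenvalue of the generalized problem  cov(diff) v = lambda cov v;
    implied lag-1 AC per factor is 1 - lambda/2.
    """

    factors: np.ndarray  # (p, p), columns
    eigenvalues: np.ndarray  # ascending, >= 0
    implied_acs: np.ndarray


def maf_indices(
    window: WindowSample | np.ndarray, min_obs: int = MIN_OBS_MAF
) -> tuple[dict[str, float], MafDecomposition | None]:
    """MAF_ac, MAF_var, MAF_ev from the smoothest autocorrelation factor.

    Requires ``min_obs`` complete observation rows; below that every value
    is NaN (not an exception).  A near-singular covariance gets a small
    ridge (1e-8 * trace / p), logged.
    """
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    rows = ~np.isnan(x).any(axis=1)
    xc = x[rows]
    nan = {"MAF_ac": np.nan, "MAF_var": np.nan, "MAF_ev": np.nan}
    if xc.shape[0] < min_obs or xc.shape[1] < 2:
        return nan, None
    sigma = np.cov(xc, rowvar=False, ddof=1)
    sigma_d = np.cov(np.diff(xc, axis=0), rowvar=False, ddof=1)
    p = sigma.shape[0]
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] <= 1e-12 * max(eig[-1], 1e-300):
        ridge = 1e-8 * np.trace(sigma) / p
        logger.info("singular window covariance; adding ridge %.3g", ridge)
        sigma = sigma + ridge * np.eye(p)
    try:
        lam, vec = scipy.linalg.eigh(sigma_d, sigma)
    except scipy.linalg.LinAlgError:
        return nan, None
    lam = np.clip(lam, 0.0, None)
    vec = vec / np.linalg.norm(vec, axis=0)
    scores = (xc - xc.mean(axis=0)) @ vec[:, 0]
    out = {
        "MAF_ac": lag1_ac(scores),
        "MAF_var": float(np.var(scores, ddof=1)),
        "MAF_ev": float(lam[0]),
    }
    decomp = MafDecomposition(factors=vec, eigenvalues=lam, implied_acs=1.0 - lam / 2.0)
    return out, decomp


def df_index(window: WindowSample | np.ndarray) -> float:
    """Degenerate fingerprinting: lag-1 AC of first-PC scores."""
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    sub, cols = complete_case_submatrix(x)
    if sub.shape[0] < 4 or cols.size < 1:
        return np.nan
    c = np.cov(sub, rowvar=False, ddof=1)
    c = np.atleast_2d(c)
    if not np.any(np.diag(c) > 0):
        return np.nan
    lam, vec = np.linalg.eigh(c)
    scores = (sub - sub.mean(axis=0)) @ vec[:, -1]
    return lag1_ac(scores)


def crosscorr_indices(window: WindowSample | np.ndarray) -> dict[str, float]:
    """Av_ab_cc (mean |r| over pairs) and MI (mean Gaussian pairwise MI)."""
    x = window.matrix if isinstance(window, WindowSample) else np.asarray(window, float)
    p = x.shape[1]
    if x.shape[0] >= 3 and not np.isnan(x).any():
        sd = x.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            return {"Av_ab_cc": np.nan, "MI": np.nan}
        c = np.corrcoef(x[:, ok], rowvar=False)
        rs = c[np.triu_indices(ok.sum(), 1)]
        r2 = np.minimum(rs**2, MI_R2_CAP)
        return {
            "Av_ab_cc": float(np.mean(np.abs(rs))),
            "MI": float(np.mean(-0.5 * np.log(1.0 - r2))),
        }
    rs = []
    for i in range(p):
        for j in range(i + 1, p):
            pair = x[:, [i, j]]
            pair = pair[~np.isnan(pair).any(axis=1)]
            if pair.shape[0] < 3:
                continue
            sa, sb = pair[:, 0].std(), pair[:, 1].std()
            if sa == 0 or sb == 0:
                continue
            r = np.mean(
                (pair[:, 0] - pair[:, 0].mean()) * (pair[:, 1] - pair[:, 1].mean())
            ) / (sa * sb)
            rs.append(float(r))
    if not rs:
        return {"Av_ab_cc": np.nan, "MI": np.nan}
    rs = np.array(rs)
    r2 = np.minimum(rs**2, MI_R2_CAP)
    return {
        "Av_ab_cc": float(np.mean(np.abs(rs))),
        "MI": float(np.mean(-0.5 * np.log(1.0 - r2))),
    }


# ---------------------------------------------------------------------------
# MMD (per-visit statistical distance) and CVPC1 (cohort-level)


def cohort_reference_covariance(zscored: pd.DataFrame, panel: tuple[str, ...]) -> np.ndarray:
    """Pairwise-complete covariance of the z-scored markers, cohort-wide."""
    wide = zscored.pivot_table(
        index=["patient_id", "time_days"], columns="biomarker", values="value"
    ).reindex(columns=list(panel))
    return wide.cov(min_periods=2).to_numpy()


def mmd_distances(
    patient_wide: pd.DataFrame, reference_cov: np.ndarray
) -> pd.DataFrame:
    """Per-visit statistical distance to the previous visit of one patient.

    ``patient_wide`` is a time-indexed (rows sorted) visits x markers frame;
    the distance at visit t uses the markers observed at both t and t-1 and
    the matching submatrix of ``reference_cov`` as the metric.
    """
    times = patient_wide.index.to_numpy(dtype=float)
    x = patient_wide.to_numpy(dtype=float)
    out_t, out_d = [], []
    for t in range(1, x.shape[0]):
        shared = ~(np.isnan(x[t]) | np.isnan(x[t - 1]))
        if not shared.any():
            continue
        delta = x[t, shared] - x[t - 1, shared]
        s = reference_cov[np.ix_(shared, shared)]
        try:
            sol = np.linalg.solve(s, delta)
        except np.linalg.LinAlgError:
            logger.info("singular MMD submatrix at t=%s; using pseudo-inverse", times[t])
            sol = np.linalg.pinv(s) @ delta
        out_t.append(times[t])
        out_d.append(float(np.sqrt(max(delta @ sol, 0.0))))
    return pd.DataFrame({"time_days": out_t, "mmd": out_d})


def mmd_window(distances: pd.DataFrame, lo: float, hi: float) -> tuple[float, int]:
    """Mean of the per-visit distances falling in the half-open (lo, hi]."""
    sel = distances[(distances["time_days"] > lo) & (distances["time_days"] <= hi)]
    if sel.empty:
        return np.nan, 0
    return float(sel["mmd"].mean()), int(len(sel))


def window_cvs(window_matrix: np.ndarray, min_obs: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker coefficient of variation sd/mean (transformed scale).

    Markers with fewer than ``min_obs`` observations or non-positive mean
    are NaN.  Returns (cvs, n_obs per marker).
    """
    x = np.asarray(window_matrix, dtype=float)
    n = (~np.isnan(x)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        sd = np.full(x.shape[1], np.nan)
        for j in range(x.shape[1]):
            col = x[:, j][~np.isnan(x[:, j])]
            if col.size >= 2:
                sd[j] = col.std(ddof=1)
    cv = np.where((n >= min_obs) & (mean > 0), sd / mean, np.nan)
    return cv, n


def cvpc1(cv_matrix: pd.DataFrame) -> pd.Series:
    """First-PC scores of the column-standardized CV matrix.

    Rows are (patient, window); columns are markers; the matrix should
    already be bias-corrected for n_obs.  All-missing columns are dropped,
    then incomplete rows.  Scores are sign-oriented so the mean loading is
    positive (higher = more variable).
    """
    m = cv_matrix.dropna(axis=1, how="all").dropna(axis=0, how="any")
    if m.shape[0] < 2 or m.shape[1] < 1:
        raise ValueError("degenerate PCA: not enough complete CV rows")
    sd = m.std(ddof=1)
    if (sd == 0).any() or m.shape[1] == 0:
        raise ValueError("degenerate PCA: constant CV column")
    z = (m - m.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    loading = vt[0]
    sign = 1.0 if loading.mean() >= 0 else -1.0
    scores = sign * u[:, 0] * s[0]
    return pd.Series(scores, index=m.index, name="CVPC1")


# ---------------------------------------------------------------------------
# driver


def _interval(window: WindowSample, anchor: float) -> tuple[float, float]:
    k, w = window.window_index, window.window_days
    return anchor - (k + 1) * w, anchor - k * w


def compute_all_indices(
    windows: list[WindowSample],
    zscored: pd.DataFrame,
    transformed: pd.DataFrame,
    patients: pd.DataFrame,
    anchors: pd.Series,
    panel: tuple[str, ...],
    maf_min_obs: int = MIN_OBS_MAF,
    cv_min_obs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute every index on every window.

    Returns ``(records, mmd_all)`` where ``records`` has one row per
    (patient, window, index) with a defined value and ``mmd_all`` holds the
    per-visit distances.  Window indices other than CVPC1 read the z-scored
    table; CVPC1 reads per-window CVs of the transformed (non-z) table.
    """
    ref_cov = cohort_reference_covariance(zscored, panel)
    zwide = zscored.pivot_table(
        index=["patient_id", "time_days"], columns="biomarker", values="value"
    ).reindex(columns=list(panel))
    twide = transformed.pivot_table(
        index=["patient_id", "time_days"], columns="biomarker", values="value"
    ).reindex(columns=list(panel))

    mmd_parts = []
    for pid, pw in zwide.groupby(level=0):
        d = mmd_distances(pw.droplevel(0).sort_index(), ref_cov)
        if not d.empty:
            d.insert(0, "patient_id", pid)
            mmd_parts.append(d)
    mmd_all = (
        pd.concat(mmd_parts, ignore_index=True)
        if mmd_parts
        else pd.DataFrame(columns=["patient_id", "time_days", "mmd"])
    )

    mmd_by_pid = {pid: grp for pid, grp in mmd_all.groupby("patient_id")}
    twide_by_pid = {pid: grp.droplevel(0) for pid, grp in twide.groupby(level=0)}
    empty_mmd = pd.DataFrame(columns=["patient_id", "time_days", "mmd"])

    records = []

    def emit(win: WindowSample, name: str, value: float, n_obs: int) -> None:
        if value is not None and np.isfinite(value):
            records.append(
                {
                    "patient_id": win.patient_id,
                    "window_index": win.window_index,
                    "months_before_anchor": win.months_before_anchor,
                    "index_name": name,
                    "raw_value": value,
                    "n_obs": n_obs,
                }
            )

    cv_rows, cv_keys, cv_nobs = [], [], []
    for win in windows:
        n = win.n_obs
        for name, val in variance_indices(win).items():
            n_eff = complete_case_submatrix(win.matrix)[0].shape[0] if name in ("PC_var", "Ex_var") else n
            emit(win, name, val, n_eff)
        for name, val in autocorrelation_indices(win).items():
            emit(win, name, val, n)
        maf_vals, _ = maf_indices(win, min_obs=maf_min_obs)
        n_complete = int((~np.isnan(win.matrix).any(axis=1)).sum())
        for name, val in maf_vals.items():
            emit(win, name, val, n_complete)
        emit(win, "Df", df_index(win), complete_case_submatrix(win.matrix)[0].shape[0])
        for name, val in crosscorr_indices(win).items():
            emit(win, name, val, n)

        anchor = anchors[win.patient_id]
        lo, hi = _interval(win, anchor)
        pd_dist = mmd_by_pid.get(win.patient_id, empty_mmd)
        mval, mcount = mmd_window(pd_dist, lo, hi)
        emit(win, "MMD", mval, mcount)

        # CV row on the transformed (non-z) scale
        if win.patient_id in twide_by_pid:
            tmat = (
                twide_by_pid[win.patient_id]
                .reindex(pd.Index(win.times, name="time_days"))
                .to_numpy(dtype=float)
            )
            cvs, nper = window_cvs(tmat, min_obs=cv_min_obs)
            cv_rows.append(cvs)
            cv_nobs.append(nper)
            cv_keys.append((win.patient_id, win.window_index, win.months_before_anchor, n))

    if cv_rows:
        idx = pd.MultiIndex.from_tuples(
            [(k[0], k[1]) for k in cv_keys], names=["patient_id", "window_index"]
        )
        cv_df = pd.DataFrame(np.vstack(cv_rows), index=idx, columns=list(panel))
        n_df = pd.DataFrame(np.vstack(cv_nobs), index=idx, columns=list(panel))
        corrected = correct_cv_matrix(cv_df, n_df)
        try:
            scores = cvpc1(corrected)
        except ValueError as exc:
            logger.warning("CVPC1 skipped: %s", exc)
            scores = pd.Series(dtype=float)
        meta = {(k[0], k[1]): (k[2], k[3]) for k in cv_keys}
        for (pid, widx), score in scores.items():
            months, n = meta[(pid, widx)]
            if np.isfinite(score):
                records.append(
                    {
                        "patient_id": pid,
                        "window_index": widx,
                        "months_before_anchor": months,
                        "index_name": "CVPC1",
                        "raw_value": float(score),
                        "n_obs": n,
                    }
                )

    cols = ["patient_id", "window_index", "months_before_anchor", "index_name", "raw_value", "n_obs"]
    rec_df = pd.DataFrame(records, columns=cols)
    rec_df = rec_df.sort_values(["patient_id", "window_index", "index_name"]).reset_index(drop=True)
    return rec_df, mmd_all


def correct_cv_matrix(cv_df: pd.DataFrame, n_df: pd.DataFrame) -> pd.DataFrame:
    """Remove the n_obs bias from each marker's CV column.

    CVs from windows with fewer observations are systematically smaller;
    each column is corrected with the best-fitting n-trend before the PCA.
    """
    out = cv_df.copy()
    for col in cv_df.columns:
        vals = cv_df[col].to_numpy(dtype=float)
        ns = n_df[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < 10 or len(np.unique(ns[ok])) < 3:
            continue
        model = fit_nobs_bias(vals[ok], ns[ok], index_name=f"CV:{col}")
        out.loc[ok, col] = apply_correction(vals[ok], ns[ok], model)
    return out
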