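"""Mortality prediction: clustered weighted Cox models, HR95, ROC/AUC and
sequential index addition.

HR95 is a scale-invariant effect size: the hazard ratio contrasting an
individual at the 97.5th percentile of an index with one at the 2.5th.
Repeated windows per patient enter as counting-process rows (entry, stop]
with cluster-robust variance by patient and sqrt(n_obs) weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.cluster.hierarchy import average, leaves_list
from scipy.interpolate import BSpline
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score, roc_curve

from .cohort import DAYS_PER_MONTH
from .comparison import pairwise_correlations, records_to_wide

logger = logging.getLogger(__name__)

CONTROL_TERMS = ("sex", "diabetes", "followup_years")


def build_survival_rows(
    records: pd.DataFrame,
    patients: pd.DataFrame,
    anchors: pd.Series,
    window_days: float,
    value_col: str = "corrected_value",
) -> pd.DataFrame:
    """Counting-process rows: one per (patient, window), indices as columns.

    The interval is the window's span in follow-up time; the event sits on
    a died patient's final (anchor-adjacent) interval only.
    """
    wide = records.pivot_table(
        index=["patient_id", "window_index"],
        columns="index_name",
        values=value_col,
        aggfunc="first",
    )
    nobs = records.pivot_table(
        index=["patient_id", "window_index"], columns="index_name", values="n_obs", aggfunc="first"
    )
    wide = wide.reset_index()
    wide["n_obs"] = nobs.max(axis=1).to_numpy()
    pat = patients.set_index("patient_id")
    k = wide["window_index"].to_numpy()
    anchor = anchors.loc[wide["patient_id"]].to_numpy(dtype=float)
    wide["entry"] = np.maximum(0.0, anchor - (k + 1) * window_days)
    wide["stop"] = anchor - k * window_days
    died = pat.loc[wide["patient_id"], "died"].to_numpy()
    wide["event"] = ((k == 0) & (died == 1)).astype(int)
    wide["died"] = died
    for col in ("age_years", "sex", "diabetes", "followup_days"):
        wide[col] = pat.loc[wide["patient_id"], col].to_numpy()
    wide["followup_years"] = wide["followup_days"] / 365.25
    wide["weight"] = np.sqrt(wide["n_obs"].to_numpy(dtype=float))
    bad = wide["entry"] >= wide["stop"]
    if bad.any():
        raise ValueError("degenerate survival interval(s)")
    counts = wide.groupby("patient_id")["event"].sum()
    if (counts > 1).any():
        raise ValueError("more than one event row for a patient")
    return wide


def age_spline_basis(
    age: np.ndarray, df: int = 5, boundary: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Cubic B-spline basis with ``df`` columns (internal knots at
    quantiles), intercept column dropped."""
    a = np.asarray(age, dtype=float)
    if boundary is None:
        boundary = (float(a.min()), float(a.max()))
    lo, hi = boundary
    n_internal = df - 3
    qs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.quantile(a, qs)
    knots = np.r_[[lo] * 4, internal, [hi] * 4]
    basis = BSpline.design_matrix(np.clip(a, lo, hi), knots, 3).toarray()
    basis = basis[:, 1:]  # drop one column: the full basis sums to 1
    return pd.DataFrame(basis, columns=[f"age_sp{i+1}" for i in range(basis.shape[1])])


@dataclass
class CoxResult:
    terms: list[str]
    index_terms: list[str]
    summary: pd.DataFrame  # coef, se(coef), HR95 columns for index terms
    aic: float
    n_rows: int
    n_patients: int
    spans: dict[str, float]
    fitter: CoxPHFitter = field(repr=False)

    def hr95(self, term: str) -> tuple[float, float, float]:
        row = self.summary.loc[term]
        return float(row["hr95"]), float(row["hr95_ci_low"]), float(row["hr95_ci_high"])

    def linear_predictor(self, rows: pd.DataFrame) -> np.ndarray:
        return self.fitter.predict_log_partial_hazard(rows[self.terms]).to_numpy()


def fit_cox_hr95(
    rows: pd.DataFrame,
    index_terms: list[str],
    controls: tuple[str, ...] = CONTROL_TERMS,
    age_df: int = 5,
    weighted: bool = True,
    penalizer: float = 0.0,
    control_penalizer: float = 0.05,
) -> CoxResult:
    """Weighted, patient-clustered proportional-hazards fit.

    Index terms are z-scored over the analysis rows; age enters through a
    cubic spline basis (``age_df`` functions); HR95 and its CI come from
    the cluster-robust SE and the 2.5/97.5 percentile span of each term.

    ``penalizer`` applies a ridge to the index terms (default none);
    ``control_penalizer`` ridges the control terms.  The latter is needed
    because follow-up length strictly separates the partial likelihood
    under death-anchored windows (the dying patient always has the minimal
    follow-up in its risk set), so its unpenalized coefficient diverges.
    """
    df = rows.dropna(subset=[t for t in index_terms if t in rows.columns]).copy()
    spans = {}
    for term in index_terms:
        v = df[term].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant index term {term!r}")
        z = (v - v.mean()) / sd
        df[term] = z
        spans[term] = float(np.quantile(z, 0.975) - np.quantile(z, 0.025))
    terms = list(index_terms) + [c for c in controls]
    if "age_years" in df.columns and age_df > 0:
        basis = age_spline_basis(df["age_years"].to_numpy(), df=age_df)
        for col in basis.columns:
            df[col] = basis[col].to_numpy()
        terms += list(basis.columns)
    fit_cols = terms + ["entry", "stop", "event", "weight", "patient_id"]
    pen = np.array(
        [penalizer] * len(index_terms) + [control_penalizer] * (len(terms) - len(index_terms))
    )
    cph = CoxPHFitter(penalizer=pen if pen.any() else 0.0)
    try:
        cph.fit(
            df[fit_cols],
            duration_col="stop",
            event_col="event",
            entry_col="entry",
            weights_col="weight" if weighted else None,
            cluster_col="patient_id",
            robust=True,
            fit_options={"step_size": 0.5, "max_steps": 500},
        )
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary.copy()
    summ["hr95"] = np.nan
    summ["hr95_ci_low"] = np.nan
    summ["hr95_ci_high"] = np.nan
    for term in index_terms:
        beta = summ.loc[term, "coef"]
        se = summ.loc[term, "se(coef)"]
        span = spans[term]
        summ.loc[term, "hr95"] = np.exp(beta * span)
        summ.loc[term, "hr95_ci_low"] = np.exp((beta - 1.96 * se) * span)
        summ.loc[term, "hr95_ci_high"] = np.exp((beta + 1.96 * se) * span)
    return CoxResult(
        terms=terms,
        index_terms=list(index_terms),
        summary=summ,
        aic=float(cph.AIC_partial_),
        n_rows=int(len(df)),
        n_patients=int(df["patient_id"].nunique()),
        spans=spans,
        fitter=cph,
    )


def roc_auc(
    rows: pd.DataFrame,
    result: CoxResult,
    outcome_horizon_months: float = 12.0,
) -> tuple[float, pd.DataFrame]:
    """AUC for death within ``outcome_horizon_months`` after window end,
    using the fitted model's linear predictor."""
    df = rows.dropna(subset=[t for t in result.index_terms if t in rows.columns]).copy()
    horizon_days = outcome_horizon_months * DAYS_PER_MONTH
    outcome = (
        (df["died"] == 1) & (df["followup_days"] - df["stop"] <= horizon_days)
    ).to_numpy()
    if outcome.all() or not outcome.any():
        raise ValueError("single-class outcome; cannot compute ROC")
    for term in result.index_terms:
        v = df[term].to_numpy(dtype=float)
        df[term] = (v - v.mean()) / v.std(ddof=1)
    if any(c.startswith("age_sp") for c in result.terms):
        basis = age_spline_basis(df["age_years"].to_numpy(), df=5)
        for col in basis.columns:
            df[col] = basis[col].to_numpy()
    lp = result.linear_predictor(df)
    auc = float(roc_auc_score(outcome, lp))
    fpr, tpr, thr = roc_curve(outcome, lp)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def seriation_order(r: pd.DataFrame) -> list[str]:
    """Deterministic index ordering by average-linkage leaf order on 1 - r."""
    names = sorted(r.columns)
    m = r.loc[names, names].to_numpy(dtype=float)
    m = np.where(np.isnan(m), 0.0, m)
    d = np.clip(1.0 - m, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = average(squareform(d, checks=False))
    return [names[i] for i in leaves_list(z)]


def sequential_auc(
    rows: pd.DataFrame,
    ordering: list[str],
    controls: tuple[str, ...] = CONTROL_TERMS,
    outcome_horizon_months: float = 12.0,
    weighted: bool = True,
    penalizer: float = 0.0,
    control_penalizer: float = 0.05,
) -> pd.DataFrame:
    """AUC as indices are added one at a time to the controls-only model."""
    steps = []
    included: list[str] = []
    if controls or "age_years" in rows.columns:
        base = fit_cox_hr95(
            rows, [], controls=controls, weighted=weighted,
            penalizer=penalizer, control_penalizer=control_penalizer,
        )
        auc_prev, _ = roc_auc(rows, base, outcome_horizon_months)
        n_base = base.n_rows
    else:
        auc_prev, n_base = 0.5, len(rows)  # no covariates: chance-level baseline
    steps.append({"step": 0, "index_added": "", "auc": auc_prev, "delta_auc": 0.0, "n_rows": n_base})
    for i, name in enumerate(ordering, start=1):
        if name not in rows.columns:
            logger.warning("index %r absent from survival rows; skipped", name)
            continue
        included.append(name)
        try:
            res = fit_cox_hr95(
                rows, included, controls=controls, weighted=weighted,
                penalizer=penalizer, control_penalizer=control_penalizer,
            )
            auc, _ = roc_auc(rows, res, outcome_horizon_months)
        except (RuntimeError, ValueError) as exc:
            logger.warning("sequential step %r failed: %s", name, exc)
            included.pop()
            continue
        steps.append(
            {
                "step": i,
                "index_added": name,
                "auc": auc,
                "delta_auc": auc - auc_prev,
                "n_rows": res.n_rows,
            }
        )
        auc_prev = auc
    return pd.DataFrame(steps)


def index_ordering_from_records(records: pd.DataFrame) -> list[str]:
    """Seriation ordering computed from the corrected index records."""
    wide = records_to_wide(records)
    corr = pairwise_correlations(wide)
    return seriation_order(corr.r)
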