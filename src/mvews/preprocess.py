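"""Ingest, biomarker transformation, z-scoring, and backward windowing."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

WINDOW_DAYS_6M = 182.62

OBS_COLUMNS = ["patient_id", "time_days", "biomarker", "value"]
PATIENT_COLUMNS = ["patient_id", "age_years", "sex", "diabetes", "followup_days", "died"]


@dataclass
class TransformRules:
    """Which biomarkers get log or square-root transformed at ingest."""

    log_markers: frozenset[str] = field(
        default_factory=lambda: frozenset({"RDW", "WBC", "glucose"})
    )
    sqrt_markers: frozenset[str] = field(default_factory=lambda: frozenset({"platelet_count"}))

    def __post_init__(self) -> None:
        if self.log_markers & self.sqrt_markers:
            raise ValueError("log_markers and sqrt_markers must be disjoint")


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation CSV; duplicate rows are averaged."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty observation file: {path}")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation file missing column(s): {', '.join(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()]
    if len(bad):
        raise ValueError(f"non-numeric values at rows {list(bad[:10])}")
    df = df.assign(value=values)
    if (df["time_days"] < 0).any():
        raise ValueError("negative time_days")
    df = (
        df.groupby(["patient_id", "time_days", "biomarker"], as_index=False, sort=True)["value"]
        .mean()
    )
    return df[OBS_COLUMNS]


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient file missing column(s): {', '.join(missing)}")
    if (df["followup_days"] <= 0).any():
        raise ValueError("followup_days must be positive")
    if not df["died"].isin([0, 1]).all():
        raise ValueError("died must be 0/1")
    return df[PATIENT_COLUMNS]


def transform_biomarkers(table: pd.DataFrame, rules: TransformRules | None = None) -> pd.DataFrame:
    """Apply ln / sqrt per the transform rules; other markers untouched."""
    rules = rules or TransformRules()
    present = set(table["biomarker"].unique())
    for name in (rules.log_markers | rules.sqrt_markers) - present:
        logger.warning("transform rule for absent marker %r ignored", name)
    out = table.copy()
    is_log = out["biomarker"].isin(rules.log_markers)
    is_sqrt = out["biomarker"].isin(rules.sqrt_markers)
    bad_log = is_log & (out["value"] <= 0)
    if bad_log.any():
        raise ValueError(
            f"non-positive value(s) for log marker at rows {list(out.index[bad_log][:10])}"
        )
    if (is_sqrt & (out["value"] < 0)).any():
        raise ValueError("negative value(s) for sqrt marker")
    out.loc[is_log, "value"] = np.log(out.loc[is_log, "value"])
    out.loc[is_sqrt, "value"] = np.sqrt(out.loc[is_sqrt, "value"])
    return out


def zscore_biomarkers(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-wide per-marker z-transform (mean 0, SD 1, ddof=1)."""
    out = table.copy()
    for name, grp in out.groupby("biomarker"):
        sd = grp["value"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"constant biomarker {name!r} cannot be z-scored")
        out.loc[grp.index, "value"] = (grp["value"] - grp["value"].mean()) / sd
    return out


@dataclass
class WindowSample:
    """One patient-window: time-ordered observation matrix with missingness.

    ``window_index`` 0 is the window ending at the anchor (death or last
    observation) and increases backwards in time.  Interval covered is the
    half-open ``(anchor - (k+1)*window_days, anchor - k*window_days]``.
    """

    patient_id: str
    window_index: int
    months_before_anchor: float
    times: np.ndarray  # strictly increasing, days since entry
    matrix: np.ndarray  # (n_obs, p), NaN = missing
    panel: tuple[str, ...]
    window_days: float

    @property
    def n_obs(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_obs_per_var(self) -> np.ndarray:
        return (~np.isnan(self.matrix)).sum(axis=0)


def patient_anchors(table: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Anchor time per patient: death time if died, else last observation."""
    last_obs = table.groupby("patient_id")["time_days"].max()
    anchors = {}
    for row in patients.itertuples(index=False):
        if row.died:
            anchors[row.patient_id] = float(row.followup_days)
        else:
            anchors[row.patient_id] = float(last_obs.get(row.patient_id, row.followup_days))
    return pd.Series(anchors, name="anchor_days")


def build_windows(
    table: pd.DataFrame,
    patients: pd.DataFrame,
    window_days: float = WINDOW_DAYS_6M,
    min_obs: int = 3,
    panel: tuple[str, ...] | None = None,
) -> list[WindowSample]:
    """Cut backward-anchored half-open windows for every patient.

    A window is emitted only if at least ``min_obs`` distinct time points
    carry at least one non-missing marker value.
    """
    known = set(patients["patient_id"])
    unknown = set(table["patient_id"]) - known
    if unknown:
        raise ValueError(f"unknown patient id(s) in observations: {sorted(unknown)[:5]}")
    if panel is None:
        panel = tuple(sorted(table["biomarker"].unique()))
    anchors = patient_anchors(table, patients)
    windows: list[WindowSample] = []
    for pid, grp in table.groupby("patient_id", sort=True):
        anchor = anchors[pid]
        wide = grp.pivot_table(index="time_days", columns="biomarker", values="value")
        wide = wide.reindex(columns=list(panel)).sort_index()
        before = anchor - wide.index.to_numpy(dtype=float)  # days before anchor, >= 0
        n_windows = int(np.ceil(np.max(before) / window_days)) if len(wide) else 0
        for k in range(max(n_windows, 1) if len(wide) else 0):
            inwin = (before >= k * window_days) & (before < (k + 1) * window_days)
            sub = wide.iloc[inwin]
            sub = sub.loc[sub.notna().any(axis=1)]
            if len(sub) < min_obs:
                continue
            windows.append(
                WindowSample(
                    patient_id=pid,
                    window_index=k,
                    months_before_anchor=(k + 0.5) * window_days / DAYS_PER_MONTH,
                    times=sub.index.to_numpy(dtype=float),
                    matrix=sub.to_numpy(dtype=float),
                    panel=panel,
                    window_days=window_days,
                )
            )
    return windows
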