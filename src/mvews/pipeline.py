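"""End-to-end pipeline: simulate/ingest -> preprocess -> indices ->
correction -> comparison -> survival, with a manifest for traceability."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import DAYS_PER_MONTH, SimulationConfig, simulate_cohort
from .comparison import fit_change_point, pairwise_correlations, records_to_wide, trend_before_death
from .correction import correct_index_table
from .indices import INDEX_NAMES, compute_all_indices
from .preprocess import (
    TransformRules,
    build_windows,
    patient_anchors,
    read_observations,
    read_patients,
    transform_biomarkers,
    zscore_biomarkers,
)
from .survival import (
    build_survival_rows,
    fit_cox_hr95,
    index_ordering_from_records,
    roc_auc,
    sequential_auc,
)

logger = logging.getLogger(__name__)

ALLOWED_WINDOW_MONTHS = (2, 3, 4, 6, 12)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    observations_csv: Path | None = None  # None -> simulate
    patients_csv: Path | None = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    window_months: int = 6
    min_obs: int = 3
    indices: tuple[str, ...] = tuple(n for n in INDEX_NAMES if n != "MMD_all")
    correction: bool = True
    horizon_months: float = 12.0
    changepoint_bootstraps: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.window_months not in ALLOWED_WINDOW_MONTHS:
            raise ValueError(
                f"window_months must be one of {ALLOWED_WINDOW_MONTHS}, got {self.window_months}"
            )
        unknown = set(self.indices) - set(INDEX_NAMES)
        if unknown:
            raise ValueError(f"unknown index name(s): {sorted(unknown)}")

    @property
    def window_days(self) -> float:
        return round(self.window_months * DAYS_PER_MONTH, 2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def stage(name: str, outputs: dict[str, Path], t0: float, inputs: dict[str, Path] | None = None):
        manifest["stages"].append(
            {
                "stage": name,
                "seconds": round(time.time() - t0, 3),
                "inputs": {k: _sha256(p) for k, p in (inputs or {}).items()},
                "outputs": {k: _sha256(p) for k, p in outputs.items()},
            }
        )
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    # 1. simulate or ingest -------------------------------------------------
    t0 = time.time()
    if config.observations_csv is None:
        sim = SimulationConfig(**{**config.sim.__dict__, "seed": config.seed})
        observations, patients = simulate_cohort(sim)
        obs_path = _write(observations, out / "observations.csv")
        pat_path = _write(patients, out / "patients.csv")
        stage("simulate", {"observations": obs_path, "patients": pat_path}, t0)
    else:
        observations = read_observations(config.observations_csv)
        patients = read_patients(config.patients_csv)
        obs_path = _write(observations, out / "observations.csv")
        pat_path = _write(patients, out / "patients.csv")
        stage(
            "ingest",
            {"observations": obs_path, "patients": pat_path},
            t0,
            {"observations": Path(config.observations_csv), "patients": Path(config.patients_csv)},
        )

    # 2. preprocess ---------------------------------------------------------
    t0 = time.time()
    panel = tuple(sorted(observations["biomarker"].unique()))
    transformed = transform_biomarkers(observations, TransformRules())
    zscored = zscore_biomarkers(transformed)
    windows = build_windows(
        zscored, patients, window_days=config.window_days, min_obs=config.min_obs, panel=panel
    )
    anchors = patient_anchors(observations, patients)
    win_meta = pd.DataFrame(
        {
            "patient_id": [w.patient_id for w in windows],
            "window_index": [w.window_index for w in windows],
            "months_before_anchor": [w.months_before_anchor for w in windows],
            "n_obs": [w.n_obs for w in windows],
        }
    )
    meta_path = _write(win_meta, out / "windows.csv")
    stage("preprocess", {"windows": meta_path}, t0, {"observations": obs_path})

    # 3. indices ------------------------------------------------------------
    t0 = time.time()
    records, mmd_all = compute_all_indices(
        windows, zscored, transformed, patients, anchors, panel
    )
    records = records[records["index_name"].isin(config.indices)].reset_index(drop=True)
    raw_path = _write(records, out / "indices_raw.csv")
    mmd_path = _write(mmd_all, out / "mmd_all.csv")
    stage("indices", {"indices_raw": raw_path, "mmd_all": mmd_path}, t0, {"windows": meta_path})

    # 4. correction ---------------------------------------------------------
    t0 = time.time()
    if config.correction:
        corrected, models = correct_index_table(records)
    else:
        corrected = records.assign(corrected_value=records["raw_value"])
        models = {}
    corr_path = _write(corrected, out / "indices_corrected.csv")
    models_path = out / "correction_models.json"
    models_path.write_text(json.dumps(models, indent=2, default=float))
    stage(
        "correct",
        {"indices_corrected": corr_path, "models": models_path},
        t0,
        {"indices_raw": raw_path},
    )

    # 5. comparison ---------------------------------------------------------
    t0 = time.time()
    wide = records_to_wide(corrected)
    corr = pairwise_correlations(wide)
    corrm_path = _write(corr.long(), out / "correlations.csv")
    curves = trend_before_death(corrected, patients)
    trends = (
        pd.concat([c.frame() for c in curves.values()], ignore_index=True)
        if curves
        else pd.DataFrame()
    )
    trends_path = _write(trends, out / "trends.csv")
    cp_rows = []
    died_ids = set(patients.loc[patients["died"] == 1, "patient_id"])
    for name in config.indices:
        grp = corrected[
            (corrected["index_name"] == name) & corrected["patient_id"].isin(died_ids)
        ]
        if grp["months_before_anchor"].nunique() < 8:
            continue
        try:
            fit = fit_change_point(
                grp["months_before_anchor"].to_numpy(),
                grp["corrected_value"].to_numpy(),
                grp["patient_id"].to_numpy(),
                n_boot=config.changepoint_bootstraps,
                seed=config.seed,
                index_name=name,
            )
        except ValueError as exc:
            logger.warning("change point for %s skipped: %s", name, exc)
            continue
        cp_rows.append(
            {
                "index_name": name,
                "cp_months": fit.cp_months,
                "ci95_low": fit.ci95[0],
                "ci95_high": fit.ci95[1],
                "slope_before": fit.slope_before,
                "slope_after": fit.slope_after,
                "n": fit.n,
            }
        )
    cp_path = _write(pd.DataFrame(cp_rows), out / "changepoints.csv")
    stage(
        "compare",
        {"correlations": corrm_path, "trends": trends_path, "changepoints": cp_path},
        t0,
        {"indices_corrected": corr_path},
    )

    # 6. survival -----------------------------------------------------------
    t0 = time.time()
    rows = build_survival_rows(corrected, patients, anchors, config.window_days)
    single = []
    for name in config.indices:
        if name not in rows.columns or rows[name].notna().sum() < 30:
            continue
        try:
            res = fit_cox_hr95(rows, [name])
        except (RuntimeError, ValueError) as exc:
            logger.warning("Cox fit for %s failed: %s", name, exc)
            continue
        hr, lo, hi = res.hr95(name)
        single.append(
            {
                "index_name": name,
                "hr95": hr,
                "ci95_low": lo,
                "ci95_high": hi,
                "aic": res.aic,
                "n_rows": res.n_rows,
                "n_patients": res.n_patients,
            }
        )
    single_df = pd.DataFrame(single)
    single_path = _write(single_df, out / "hr95_single.csv")

    def full_model(exclude: tuple[str, ...]) -> pd.DataFrame:
        terms = [
            n
            for n in config.indices
            if n in rows.columns and n not in exclude and rows[n].notna().sum() >= 30
        ]
        try:
            res = fit_cox_hr95(rows, terms, penalizer=1e-3)
        except (RuntimeError, ValueError) as exc:
            logger.warning("full Cox model failed: %s", exc)
            return pd.DataFrame()
        recs = []
        for t in terms:
            hr, lo, hi = res.hr95(t)
            recs.append(
                {"index_name": t, "hr95": hr, "ci95_low": lo, "ci95_high": hi,
                 "aic": res.aic, "n_rows": res.n_rows, "n_patients": res.n_patients}
            )
        return pd.DataFrame(recs)

    full_path = _write(full_model(()), out / "hr95_full.csv")
    nomaf_path = _write(full_model(("MAF_var", "MAF_ac")), out / "hr95_full_nomaf.csv")

    # sequential addition only over indices defined on most rows; sparse
    # (MAF-type) indices would shrink the row set and break AUC deltas
    ordering = [
        n
        for n in index_ordering_from_records(corrected)
        if n in rows.columns and rows[n].notna().mean() >= 0.8
    ]
    seq = sequential_auc(rows, ordering, outcome_horizon_months=config.horizon_months)
    seq_path = _write(seq, out / "auc_sequential.csv")
    stage(
        "survival",
        {
            "hr95_single": single_path,
            "hr95_full": full_path,
            "hr95_full_nomaf": nomaf_path,
            "auc_sequential": seq_path,
        },
        t0,
        {"indices_corrected": corr_path},
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Deterministic toy cohort: 3 patients, 2 markers, hand-checkable.

    Patient T01's window 0 holds x=(1,2,3), y=(1,2,3) so Av_Var=1 and
    PC_var=2 exactly; expected values are bundled in the returned dict.
    """
    rows = []
    # T01: died at day 400; visits 220, 300, 380 land in window 0
    for t, v in zip((220, 300, 380), (1.0, 2.0, 3.0)):
        rows.append(("T01", t, "m1", v))
        rows.append(("T01", t, "m2", v))
    # window 1: visits 40, 120, 200
    for t, v in zip((40, 120, 200), (2.0, 1.0, 3.0)):
        rows.append(("T01", t, "m1", v))
        rows.append(("T01", t, "m2", 4.0 - v))
    # T02: censored, last obs day 365
    for t, v in zip((5, 95, 185, 275, 365), (1.0, 3.0, 2.0, 5.0, 4.0)):
        rows.append(("T02", t, "m1", v))
        rows.append(("T02", t, "m2", v * 0.5 + 1.0))
    # T03: died day 200, single sparse window
    for t, v in zip((20, 90, 160, 195), (4.0, 2.0, 5.0, 3.0)):
        rows.append(("T03", t, "m1", v))
        rows.append(("T03", t, "m2", 6.0 - v))
    obs = pd.DataFrame(rows, columns=["patient_id", "time_days", "biomarker", "value"])
    patients = pd.DataFrame(
        {
            "patient_id": ["T01", "T02", "T03"],
            "age_years": [70.0, 55.0, 62.0],
            "sex": [0, 1, 0],
            "diabetes": [1, 0, 0],
            "followup_days": [400.0, 380.0, 200.0],
            "died": [1, 0, 1],
        }
    )
    expected = {
        "T01_window0": {"Av_Var": 1.0, "PC_var": 2.0, "NMV": 1.0, "Max_cov": 1.0, "Ex_var": 1.0},
    }
    return obs, patients, expected
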