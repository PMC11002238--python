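"""Synthetic cohort generator: irregular multivariate biomarker series.

Patients follow a latent stationary VAR(1) process on a daily grid.  For
patients that die, the recovery parameter ramps linearly toward 1 over the
final months of follow-up, producing rising variance, autocorrelation and
cross-correlation (a controlled approach to a bifurcation).  Observations
are emitted at jittered ~biweekly visits with random gaps, then mapped to
native biomarker scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: The 11-biomarker panel with the highest time resolution in routine
#: hemodialysis follow-up.
DEFAULT_PANEL = (
    "hematocrit",
    "hemoglobin",
    "MCH",
    "MCHC",
    "MCV",
    "platelet_count",
    "potassium",
    "RBC",
    "RDW",
    "sodium",
    "WBC",
)

# Plausible native-scale locations/spreads, expressed on the *transformed*
# scale (log for RDW/WBC, square root for platelet count) so that the
# ingest transformations recover near-Gaussian variables.
DEFAULT_MARKER_MEANS = {
    "hematocrit": 0.33,
    "hemoglobin": 110.0,
    "MCH": 30.0,
    "MCHC": 330.0,
    "MCV": 92.0,
    "platelet_count": 14.8,  # sqrt scale; ~219 on native scale
    "potassium": 4.5,
    "RBC": 3.7,
    "RDW": 2.71,  # log scale; ~15 on native scale
    "sodium": 138.0,
    "WBC": 1.95,  # log scale; ~7 on native scale
}
DEFAULT_MARKER_SDS = {
    "hematocrit": 0.035,
    "hemoglobin": 12.0,
    "MCH": 2.0,
    "MCHC": 10.0,
    "MCV": 5.0,
    "platelet_count": 2.0,
    "potassium": 0.5,
    "RBC": 0.45,
    "RDW": 0.08,
    "sodium": 3.0,
    "WBC": 0.25,
}

#: Markers whose native scale is exp(latent); ingest applies log.
LOG_SCALE_MARKERS = frozenset({"RDW", "WBC", "glucose"})
#: Markers whose native scale is latent**2; ingest applies sqrt.
SQRT_SCALE_MARKERS = frozenset({"platelet_count"})


def _default_coupling(p: int, off: float = 0.1) -> np.ndarray:
    c = np.full((p, p), off)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``phi_base`` is the baseline recovery parameter (spectral radius of the
    latent transition matrix); ``phi_terminal`` is its value at death.
    """

    n_patients: int = 100
    panel: tuple[str, ...] = DEFAULT_PANEL
    dt_days: float = 14.0
    gap_prob: float = 0.15
    followup_years_range: tuple[float, float] = (1.0, 8.0)
    frac_died: float = 0.67
    phi_base: float = 0.3
    phi_terminal: float = 0.95
    ramp_months: float = 3.0
    coupling: np.ndarray | None = None
    noise_cov: np.ndarray | None = None
    marker_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_MEANS))
    marker_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_SDS))
    seed: int = 0

    @property
    def p_vars(self) -> int:
        return len(self.panel)

    def coupling_matrix(self) -> np.ndarray:
        c = self.coupling if self.coupling is not None else _default_coupling(self.p_vars)
        return np.asarray(c, dtype=float)

    def noise_matrix(self) -> np.ndarray:
        q = self.noise_cov if self.noise_cov is not None else np.eye(self.p_vars)
        return np.asarray(q, dtype=float)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 <= self.gap_prob < 1.0):
            raise ValueError("gap_prob must be in [0, 1)")
        if not (0.0 < self.phi_base < self.phi_terminal < 1.0):
            raise ValueError("require 0 < phi_base < phi_terminal < 1")
        if not (0.0 < self.frac_died <= 1.0):
            raise ValueError("frac_died must be in (0, 1]")
        lo, hi = self.followup_years_range
        if not (0.0 < lo <= hi):
            raise ValueError("followup_years_range must satisfy 0 < lo <= hi")
        q = self.noise_matrix()
        if not np.allclose(q, q.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(q)) < -1e-10:
            raise ValueError("noise_cov must be positive semidefinite")
        for name in self.panel:
            if name not in self.marker_means or name not in self.marker_sds:
                raise ValueError(f"missing marker scale for {name!r}")


def _spectral_radius(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(m))))


def stationary_covariance(phi_matrix: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Solve the discrete Lyapunov equation  S = Phi S Phi' + Q.

    Raises ``ValueError("unstable process")`` when the transition matrix is
    not contractive.
    """
    phi = np.atleast_2d(np.asarray(phi_matrix, dtype=float))
    q = np.atleast_2d(np.asarray(noise_cov, dtype=float))
    if _spectral_radius(phi) >= 1.0:
        raise ValueError("unstable process")
    sigma = solve_discrete_lyapunov(phi, q)
    sigma = (sigma + sigma.T) / 2.0
    resid = np.linalg.norm(sigma - phi @ sigma @ phi.T - q, np.inf)
    if resid > 1e-10 * max(np.linalg.norm(sigma, np.inf), 1e-300):
        raise RuntimeError("Lyapunov solve did not converge")
    return sigma


def stationary_lag1_autocov(phi_matrix: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Lag-1 autocovariance Phi @ Sigma of the stationary VAR(1)."""
    phi = np.atleast_2d(np.asarray(phi_matrix, dtype=float))
    return phi @ stationary_covariance(phi, noise_cov)


def stationary_lag1_ac(phi_matrix: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Per-variable stationary lag-1 autocorrelation (oracle)."""
    sigma = stationary_covariance(phi_matrix, noise_cov)
    phi = np.atleast_2d(np.asarray(phi_matrix, dtype=float))
    return np.diag(phi @ sigma) / np.diag(sigma)


def phi_schedule(config: SimulationConfig, died: int, followup_days: float) -> np.ndarray:
    """Daily recovery-parameter schedule phi(t), t = 0..floor(followup)."""
    n_days = int(np.floor(followup_days)) + 1
    phi = np.full(n_days, config.phi_base)
    if died:
        ramp_days = config.ramp_months * DAYS_PER_MONTH
        start = followup_days - ramp_days
        t = np.arange(n_days, dtype=float)
        frac = np.clip((t - start) / ramp_days, 0.0, 1.0)
        phi = config.phi_base + (config.phi_terminal - config.phi_base) * frac
    return phi


def simulate_latent(
    config: SimulationConfig, died: int, followup_days: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the latent daily VAR(1) series, standardized so each
    variable has unit variance in the baseline stationary regime.

    Returns an (n_days, p) array.
    """
    p = config.p_vars
    c = config.coupling_matrix()
    cn = c / _spectral_radius(c)
    q = config.noise_matrix()
    phi = phi_schedule(config, died, followup_days)
    n_days = phi.shape[0]

    sigma0 = stationary_covariance(config.phi_base * cn, q)
    chol_q = np.linalg.cholesky(q + 1e-12 * np.eye(p))
    chol_s = np.linalg.cholesky(sigma0 + 1e-12 * np.eye(p))

    x = np.empty((n_days, p))
    x[0] = chol_s @ rng.standard_normal(p)
    eps = rng.standard_normal((n_days - 1, p)) @ chol_q.T
    for t in range(n_days - 1):
        x[t + 1] = (phi[t] * cn) @ x[t] + eps[t]
    return x / np.sqrt(np.diag(sigma0))


def visit_days(
    config: SimulationConfig, followup_days: float, rng: np.random.Generator
) -> np.ndarray:
    """Visit schedule: multiples of dt_days with signed geometric jitter,
    each visit dropped independently with ``gap_prob``."""
    last_day = int(np.floor(followup_days))
    n_sched = int(np.floor(followup_days / config.dt_days)) + 1
    if n_sched < 2:
        raise ValueError("follow-up too short for 2 visits")
    sched = np.arange(n_sched) * config.dt_days
    jitter = (rng.geometric(0.5, size=n_sched) - 1) * rng.choice([-1, 1], size=n_sched)
    days = np.clip(np.round(sched + jitter), 0, last_day).astype(int)
    for _ in range(100):
        keep = rng.random(n_sched) >= config.gap_prob
        kept = np.unique(days[keep])
        if kept.size >= 2:
            return kept
    return np.unique(days)


def simulate_patient(
    config: SimulationConfig, died: int, followup_days: float, rng: np.random.Generator
) -> pd.DataFrame:
    """One patient's observation rows (time_days, biomarker, value)."""
    config.validate()
    x = simulate_latent(config, died, followup_days, rng)
    days = visit_days(config, followup_days, rng)
    means = np.array([config.marker_means[m] for m in config.panel])
    sds = np.array([config.marker_sds[m] for m in config.panel])
    vals = means + sds * x[days]  # (n_visits, p) on the transformed scale
    for j, name in enumerate(config.panel):
        if name in LOG_SCALE_MARKERS:
            vals[:, j] = np.exp(vals[:, j])
        elif name in SQRT_SCALE_MARKERS:
            vals[:, j] = np.square(vals[:, j])
    n, p = vals.shape
    return pd.DataFrame(
        {
            "time_days": np.repeat(days, p),
            "biomarker": np.tile(np.asarray(config.panel, dtype=object), n),
            "value": np.round(vals.ravel(), 6),
        }
    )


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (observations, patients) tables.

    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.followup_years_range
    obs_parts = []
    pat_rows = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        followup = float(rng.uniform(lo, hi)) * DAYS_PER_YEAR
        died = int(rng.random() < config.frac_died)
        age = float(np.clip(rng.normal(65.0, 12.0), 20.0, 95.0))
        sex = int(rng.integers(0, 2))
        diabetes = int(rng.random() < 0.4)
        rows = simulate_patient(config, died, followup, rng)
        rows.insert(0, "patient_id", pid)
        obs_parts.append(rows)
        pat_rows.append(
            {
                "patient_id": pid,
                "age_years": round(age, 2),
                "sex": sex,
                "diabetes": diabetes,
                "followup_days": round(followup, 2),
                "died": died,
            }
        )
    observations = pd.concat(obs_parts, ignore_index=True)
    patients = pd.DataFrame(pat_rows)
    return observations, patients


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
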