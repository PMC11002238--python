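import numpy as np
import pytest

from mvews.cohort import SimulationConfig, simulate_cohort
from mvews.correction import correct_index_table
from mvews.indices import compute_all_indices
from mvews.pipeline import make_fixtures
from mvews.preprocess import (
    TransformRules,
    build_windows,
    patient_anchors,
    transform_biomarkers,
    zscore_biomarkers,
)


def process_cohort(obs, pat, window_days=182.62, min_obs=3):
    """Shared helper: observations -> corrected index records."""
    panel = tuple(sorted(obs["biomarker"].unique()))
    transformed = transform_biomarkers(obs, TransformRules())
    zscored = zscore_biomarkers(transformed)
    windows = build_windows(zscored, pat, window_days=window_days, min_obs=min_obs, panel=panel)
    anchors = patient_anchors(obs, pat)
    records, mmd_all = compute_all_indices(windows, zscored, transformed, pat, anchors, panel)
    corrected, models = correct_index_table(records)
    return {
        "panel": panel,
        "windows": windows,
        "anchors": anchors,
        "records": records,
        "mmd_all": mmd_all,
        "corrected": corrected,
        "models": models,
        "zscored": zscored,
        "transformed": transformed,
    }


@pytest.fixture(scope="session")
def demo_cohort():
    """Moderate cohort with the default variance-driven ramp."""
    config = SimulationConfig(n_patients=150, seed=42, followup_years_range=(1.0, 5.0))
    obs, pat = simulate_cohort(config)
    return config, obs, pat


@pytest.fixture(scope="session")
def demo_processed(demo_cohort):
    _, obs, pat = demo_cohort
    return process_cohort(obs, pat)


@pytest.fixture(scope="session")
def toy_fixture():
    obs, pat, expected = make_fixtures()
    return obs, pat, expected


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window(rng, n_range=(15, 30), p_range=(3, 5), missing_prob=0.0):
    """A random Gaussian window matrix, optionally with missing cells."""
    n = int(rng.integers(*n_range))
    p = int(rng.integers(*p_range))
    a = rng.normal(size=(p, p)) * 0.5
    cov = a @ a.T + np.eye(p)
    x = rng.multivariate_normal(np.zeros(p), cov, size=n)
    # mild serial structure so AC-type indices are non-degenerate
    x = 0.6 * x + 0.4 * np.cumsum(rng.normal(size=(n, p)) * 0.3, axis=0)
    if missing_prob > 0:
        mask = rng.random((n, p)) < missing_prob
        # never blank a full row or column
        mask[:, mask.all(axis=0)] = False
        mask[mask.all(axis=1), :] = False
        x = np.where(mask, np.nan, x)
    return x
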