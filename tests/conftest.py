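"""Shared fixtures: small deterministic recordings and the desk-scale cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from pulseicp.mlcore import run_cv
from pulseicp.pipeline import PipelineConfig, cohort_feature_table
from pulseicp.synthgen import GeneratorParams, make_subject


@pytest.fixture(scope="session")
def noiseless_params() -> GeneratorParams:
    """Deterministic single-subject config: fixed 120 bpm (integer sample
    period at 50 Hz), no noise, no drift, no artifacts."""
    return GeneratorParams(
        n_subjects=1,
        trials_per_subject=2,
        trial_duration_s=200.0,
        heart_rate_bpm=(120.0, 120.0),
        hr_jitter_sd=0.0,
        icp_drift_mmHg=0.0,
        icp_pulse_mmHg=0.0,
        noise_sd=0.0,
        map_noise_sd=0.0,
        artifact_rate_per_h=0.0,
        outlier_beat_rate=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_subject(noiseless_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_subject(noiseless_params, 0)


@pytest.fixture(scope="session")
def desk_cohort_table():
    """Feature table of the default 8-subject desk-scale cohort (dHbT)."""
    cfg = PipelineConfig(modalities=("dHbT",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_feature_table(cfg)


@pytest.fixture(scope="session")
def noise_sweep_r2():
    """Fivefold-mean dHbT r2 at doubling generator noise levels."""
    out = {}
    for ns in (0.2, 0.4, 0.8):
        cfg = PipelineConfig(
            generator=GeneratorParams(
                n_subjects=3, trial_duration_s=300.0, noise_sd=ns
            ),
            modalities=("dHbT",),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = cohort_feature_table(cfg)
            rep = run_cv(table, "dHbT", cfg.rf, seed=0)
        out[ns] = rep.r2_mean
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
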