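import warnings

import numpy as np
import pytest

import ppgaffect as pa


@pytest.fixture(scope="session")
def stage_params():
    return pa.default_stage_params()


@pytest.fixture(scope="session")
def clean_train(stage_params):
    """Noiseless 10-beat record with fixed beat geometry plus its truth table.

    ST = 200 ms, DT = 650 ms, BVA = 10 mV exactly: 10 beats fill 8.5 s.
    """
    params = pa.StageParams("baseline", bva_mean=10.0, bva_sd=0.0, st_mean=200.0, st_sd=0.0,
                            dt_mean=650.0, dt_sd=0.0)
    subj = pa.SubjectParams("S000", {"baseline": params}, 0)
    record, truth = pa.synthesize_record(
        subj, "baseline", duration_s=8.5, fs=1024.0, noise_sd=0.0, wander_amp=0.0,
        rng=np.random.default_rng(0),
    )
    return record, truth


@pytest.fixture(scope="session")
def long_clean_record(stage_params):
    """Noiseless 10-minute baseline-stage recording (population parameters)."""
    subj = pa.sample_subject_params(stage_params, 0.0, np.random.default_rng(0))
    return pa.synthesize_record(
        subj, "baseline", duration_s=600.0, fs=1024.0, noise_sd=0.0, wander_amp=0.0,
        rng=np.random.default_rng(42),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise 8-subject cohort over all five stages."""
    return pa.synthesize_cohort(8, seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pa.extract_cohort_features(small_cohort)
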