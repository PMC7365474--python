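import numpy as np
import pytest

from bcham.params import ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def paired_run():
    """Medium paired two-arm run shared by the benefit/harm tests.

    10,000 cancer-acquiring patients, 10 replicate pairs each, default
    parameters and the standard two-arm design.
    """
    from bcham import simulator, trial

    p = ModelParams()
    design = trial.cnbss_design()
    arm_bands = {a.name: a.bands for a in design.arms}
    patients = simulator.sample_cancer_patients(10_000, p, seed=424242)
    paired = simulator.simulate_paired_cohort(
        patients, arm_bands, n_pairs=10, params=p, seed=424243)
    return patients, paired
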