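import numpy as np
import pytest

import serdstudy as sd


@pytest.fixture(scope="session")
def truth() -> sd.GroundTruth:
    return sd.default_truth()


@pytest.fixture(scope="session")
def small_design() -> sd.StudyDesign:
    """A cut-down dose-ranging design for fast module tests."""
    return sd.default_design(doses=(3.0, 30.0), n_per_arm=3, duration_days=14.0)


@pytest.fixture(scope="session")
def noiseless() -> sd.NoiseModel:
    return sd.NoiseModel(volume_cv=0.0, conc_cv=0.0, er_cv=0.0, expression_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def small_bundle(small_design, truth) -> sd.StudyBundle:
    return sd.simulate_study(small_design, truth, sd.NoiseModel(seed=11))


def constant_conc_fn(value: float):
    """Constant free-concentration profile for ODE tests."""

    def fn(t):
        t = np.asarray(t, dtype=float)
        return float(value) if t.ndim == 0 else np.full_like(t, float(value))

    return fn
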