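import numpy as np
import pytest

from taptiming import DesignKind, build_default_design
from taptiming.simulate import GeneratorParams, simulate_cohort, sessions_to_frame


@pytest.fixture(scope="session")
def default_design():
    return build_default_design()


@pytest.fixture(scope="session")
def zero_noise_params():
    """Generator that emits taps exactly on target."""
    return GeneratorParams(
        pacing_bias=0.0,
        pacing_sd=0.0,
        continuation_timekeeper_sd=0.0,
        continuation_drift=0.0,
        switch_cost_bias=0.0,
        miss_prob=0.0,
        outlier_prob=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort_frame():
    """A 3+3 participant cohort with the default generator presets."""
    sessions = simulate_cohort(3, 3, seed=42)
    return sessions_to_frame(sessions)


def params_by_group(params: GeneratorParams):
    """Use the same generator parameters for both design groups."""
    return {DesignKind.BLOCKED: params, DesignKind.ALTERNATING: params}
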