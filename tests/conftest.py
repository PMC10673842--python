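import numpy as np
import pytest
from hypothesis import settings

from optowell import workflows

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from optowell.twin import ComponentArray, PlateTwin
from optowell.wells import N_WELLS


def make_noise_free_twin(seed: int = 0, **kwargs) -> PlateTwin:
    """Twin with zero read noise (quantisation still applies)."""
    kwargs.setdefault("noise_sd", 0.0)
    return PlateTwin(seed=seed, **kwargs)


def make_ideal_twin(seed: int = 0, **kwargs) -> PlateTwin:
    """Twin with identical components and no noise: fully deterministic."""
    kwargs.setdefault("noise_sd", 0.0)
    kwargs.setdefault("gain_cv", {r: 0.0 for r in
                                  ("photodiode", "blue_stim", "od_led",
                                   "uv_led")})
    kwargs.setdefault("od_scatter_cv", 0.0)
    return PlateTwin(seed=seed, **kwargs)


@pytest.fixture
def twin() -> PlateTwin:
    return PlateTwin(seed=7)


@pytest.fixture(scope="session")
def calibrated():
    """A default twin with a completed component calibration (shared,
    read-mostly; tests that mutate sample state must reset it)."""
    twin = PlateTwin(seed=11)
    state = workflows.full_calibration(twin)
    return twin, state


def twin_with_gains(role_gains: dict[str, np.ndarray], seed: int = 0,
                    **kwargs) -> PlateTwin:
    """Twin whose listed roles have exactly the given gain vectors."""
    base = PlateTwin(seed=seed, **kwargs)
    components = dict(base.components)
    for role, gains in role_gains.items():
        old = components[role]
        components[role] = ComponentArray(role, np.asarray(gains, float),
                                          noise_sd=old.noise_sd,
                                          nominal_scale=old.nominal_scale)
    return PlateTwin(seed=seed, components=components, **kwargs)


def uniform96(value: float) -> np.ndarray:
    return np.full(N_WELLS, float(value))
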