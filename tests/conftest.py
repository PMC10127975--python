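import numpy as np
import pytest

from radgrowth import (
    GrowthParameters,
    ModelSpec,
    RadiationParameters,
    TreatmentProtocol,
    TumourTimeSeries,
    solve_treated,
    standard_fractionation,
)

A_REF = 0.0118
ALPHA_REF = 0.0222


@pytest.fixture(scope="session")
def exp_growth() -> GrowthParameters:
    return GrowthParameters(law="exponential", a=A_REF)


@pytest.fixture(scope="session")
def radiation() -> RadiationParameters:
    return RadiationParameters.from_alpha(ALPHA_REF)


@pytest.fixture(scope="session")
def exp_spec(exp_growth, radiation) -> ModelSpec:
    return ModelSpec(growth=exp_growth, radiation=radiation, mu=1.0)


@pytest.fixture(scope="session")
def full_protocol() -> TreatmentProtocol:
    """33 weekday fractions of 2 Gy starting on model day 7."""
    return standard_fractionation(66.0, 2.0, start_day=7.0)


@pytest.fixture(scope="session")
def short_protocol() -> TreatmentProtocol:
    """10 weekday fractions of 2 Gy starting on model day 2 (fast tests)."""
    return standard_fractionation(20.0, 2.0, start_day=2.0)


@pytest.fixture(scope="session")
def empty_protocol() -> TreatmentProtocol:
    return TreatmentProtocol(0.0, (), tw=1.0 / 96.0)


def make_synthetic_series(
    spec: ModelSpec,
    proto: TreatmentProtocol,
    v0: float,
    times,
    sigma: float = 0.0,
    seed: int = 0,
    h: float = 1.0 / 288.0,
) -> TumourTimeSeries:
    """Noiseless-or-noisy measurements sampled from the treated model."""
    times = np.asarray(times, dtype=float)
    traj = solve_treated(spec, proto, v0, float(times[-1]), h=h)
    clean = traj.at(times)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean * np.exp(sigma * rng.standard_normal(times.size))
    return TumourTimeSeries(times=times, volumes=clean)


@pytest.fixture(scope="session")
def short_series(exp_spec, short_protocol) -> TumourTimeSeries:
    """Noiseless 8-point series from the exponential treated model."""
    times = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 13.0]
    return make_synthetic_series(exp_spec, short_protocol, 25.0, times)
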