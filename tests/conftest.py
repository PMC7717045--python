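import numpy as np
import pytest

from invasionwaves.model import (
    LogisticKinetic,
    ModelSpec,
    PolynomialDiffusivity,
    TwoRateDiffusivity,
    min_wave_speed,
)


@pytest.fixture(scope="session")
def aggregation_model() -> ModelSpec:
    """The sign-changing reference parameter set: D_i=0.25, D_g=0.05,
    lambda=0.75 (roots alpha=1/2, beta=5/6; c* = 2 sqrt(0.1875))."""
    return ModelSpec(TwoRateDiffusivity(0.25, 0.05), LogisticKinetic(0.75))


@pytest.fixture(scope="session")
def shock_model() -> ModelSpec:
    """Shifted quadratic diffusivity D(u) = (u-0.1)(u-0.3) with the same
    logistic growth: the node/spiral thresholds swap order, so only
    shock-fronted waves survive at the selected speed."""
    return ModelSpec(PolynomialDiffusivity((0.03, -0.4, 1.0)), LogisticKinetic(0.75))


@pytest.fixture(scope="session")
def c_star(aggregation_model) -> float:
    return min_wave_speed(aggregation_model.D, aggregation_model.R)


@pytest.fixture(scope="session")
def reference_wave(aggregation_model, c_star):
    """The assembled minimum-speed travelling wave (built once per session)."""
    from invasionwaves import phaseplane as pp

    orbits = pp.construct_wave_orbits(aggregation_model, c_star)
    profile = pp.assemble_wave(orbits, aggregation_model, c_star)
    return orbits, profile


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
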