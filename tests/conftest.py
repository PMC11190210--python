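import numpy as np
import pytest

from seqsplit import (
    BasisSpec,
    GroundTruth,
    build_task_design,
    generate_basis,
    simulate_session,
)


@pytest.fixture(scope="session")
def design_p1():
    return build_task_design({1}, 40)


@pytest.fixture(scope="session")
def design_full():
    return build_task_design({1, 2}, 40)


@pytest.fixture(scope="session")
def small_design():
    return build_task_design({1, 2}, 10)


@pytest.fixture(scope="session")
def exact_spec():
    return BasisSpec(n_neurons=100, mode="exact-orthogonal")


@pytest.fixture(scope="session")
def exact_basis(exact_spec):
    return generate_basis(exact_spec, seed=123)


@pytest.fixture(scope="session")
def clean_session(small_design, exact_basis, exact_spec):
    """Noise-free session: pair differences are exactly the composed signals."""
    truth = GroundTruth(
        weights=(0.7, 0.7, 0.4, 0.4),
        signal_amplitude=1.0,
        baseline_rate=5.0,
        noise_sd=0.0,
        cue_response_amplitude=0.5,
    )
    return simulate_session(
        small_design, truth, seed=7, basis=exact_basis, spec=exact_spec
    )


@pytest.fixture(scope="session")
def noisy_session(small_design, exact_basis, exact_spec):
    truth = GroundTruth(
        weights=(0.7, 0.7, 0.4, 0.4),
        signal_amplitude=2.0,
        baseline_rate=2.0,
        noise_sd=0.5,
        cue_response_amplitude=0.5,
    )
    return simulate_session(
        small_design, truth, seed=8, basis=exact_basis, spec=exact_spec
    )
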