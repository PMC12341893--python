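import numpy as np
import pytest

from semspace import design, simulate, stimuli


@pytest.fixture(scope="session")
def ws():
    return stimuli.synthesize_word_set(seed=1)


@pytest.fixture(scope="session")
def triad_design(ws):
    return design.build_triad_design(ws, seed=2)


@pytest.fixture(scope="session")
def pair_design(ws):
    return design.build_pair_design(ws, seed=3)


@pytest.fixture(scope="session")
def small_cohort(ws, triad_design, pair_design):
    """6 control-like + 3 sv-like participants with ground truth."""
    gc = simulate.GeneratorConfig(n_control=6, n_sv=3)
    responses, truth = simulate.simulate_cohort(
        ws, triad_design, pair_design, gc, seed=4
    )
    return responses, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
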