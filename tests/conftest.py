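import numpy as np
import pytest
from hypothesis import settings

from partikel.models import ContrastCoding

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from partikel.synthetic import ExperimentDesign, GenerativeParams


@pytest.fixture(scope="session")
def coding() -> ContrastCoding:
    return ContrastCoding()


@pytest.fixture(scope="session")
def paper_design() -> ExperimentDesign:
    """60 participants x 24 items, the scale of the reading experiments."""
    return ExperimentDesign(n_participants=60, n_items=24, seed=101)


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    """Reduced design for fast model smoke tests."""
    return ExperimentDesign(n_participants=12, n_items=8, n_fillers=4, seed=7)


@pytest.fixture(scope="session")
def spr_trials(paper_design):
    from partikel.synthetic import generate_spr_trials

    return generate_spr_trials(paper_design, GenerativeParams.spr_defaults(seed=23))


def design_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    c1 = rng.choice([-0.5, 0.5], n)
    c2 = rng.choice([-0.5, 0.5], n)
    return np.column_stack([np.ones(n), c1, c2, c1 * c2])
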