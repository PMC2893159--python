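import warnings

import numpy as np
import pytest

import covscan as cs


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Degenerate-position and ambiguity warnings are expected in many
    constructions exercised here; keep the output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def toy_alignment():
    """8 sequences x 12 columns, gap-free, with enough variation to fit."""
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = tuple("".join(rng.choice(aa, 12)) for _ in range(8))
    return cs.Alignment(tuple(f"s{i}" for i in range(8)), rows)


@pytest.fixture(scope="session")
def background_alignment():
    """Simulated 150x60 gap-free background, shared across tests."""
    return cs.simulate_background(150, 60, seed=11)


@pytest.fixture(scope="session")
def background_results(background_alignment):
    return cs.CovariationAnalysis(background_alignment).fit()
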