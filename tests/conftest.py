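import numpy as np
import pytest

import trnfit


@pytest.fixture(scope="session")
def bundle():
    """One default-configuration synthetic bundle shared across tests."""
    return trnfit.generate(trnfit.FixtureConfig(seed=11))


@pytest.fixture(scope="session")
def perturbed_bundle():
    """Bundle with the standard 3-TF x100 Kd perturbation planted."""
    b = trnfit.generate(trnfit.FixtureConfig(seed=11))
    targets = trnfit.fixtures.default_perturbation_targets(b)
    trnfit.perturb_reference(b, {t: 100.0 for t in targets}, seed=11)
    return b, targets


@pytest.fixture
def rng():
    return np.random.default_rng(42)
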