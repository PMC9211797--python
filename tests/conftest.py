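import pytest
from hypothesis import HealthCheck, settings

import mptmem as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exp1():
    return m.fixture_experiment1()


@pytest.fixture(scope="session")
def exp2():
    return m.fixture_experiment2()


@pytest.fixture(scope="session")
def exp1_base_fit(exp1):
    return m.fit_mle(exp1.model, exp1.data, exp1.base_restrictions)


@pytest.fixture(scope="session")
def exp2_base_fit(exp2):
    return m.fit_mle(exp2.model, exp2.data, exp2.base_restrictions)


@pytest.fixture(scope="session")
def binomial_model():
    """Single-parameter binomial tree: P(cat1) = p."""
    return m.parse_eqn("2\n1 1 p\n1 2 (1-p)\n")


@pytest.fixture(scope="session")
def one_ht_model():
    """One-high-threshold recognition toy: detect-or-guess for old items,
    pure guessing for new items."""
    text = "\n".join([
        "5",
        "old hit D",
        "old hit (1-D)*g",
        "old miss (1-D)*(1-g)",
        "new fa g",
        "new cr (1-g)",
    ])
    return m.parse_eqn(text)
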