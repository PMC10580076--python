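import pytest

from ggkit import fixtures


@pytest.fixture(scope="session")
def kit6():
    """Six-slot kit, one part per slot plus combined-span parts."""
    return fixtures.make_kit(6, 1, seed=1)


@pytest.fixture(scope="session")
def kit6_multi():
    """Six-slot kit with four alternative promoter-slot parts."""
    return fixtures.make_kit(6, {"5arm": 4}, seed=1)


@pytest.fixture(scope="session")
def kit4():
    return fixtures.make_kit(4, 1, seed=11)
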