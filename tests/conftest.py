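import pytest

from seedqual import synthetic as syn


@pytest.fixture(scope="session")
def bialobrzeskie():
    return syn.fa_profile("Bialobrzeskie")


@pytest.fixture(scope="session")
def henola():
    return syn.fa_profile("Henola")


@pytest.fixture(scope="session", params=syn.VARIETIES)
def variety(request):
    return request.param


@pytest.fixture(scope="session")
def random_profiles():
    """100 seeded random profiles used by the property suites."""
    return [
        syn.random_profile(syn.RandomProfileSpec(n_acids=10, seed=s))
        for s in range(100)
    ]
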