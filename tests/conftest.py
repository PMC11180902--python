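import pytest

from tlmabac import LinguisticScale, breast_cancer


@pytest.fixture(scope="session")
def scale8() -> LinguisticScale:
    return LinguisticScale(8)


@pytest.fixture(scope="session")
def case():
    """The embedded breast-cancer case study (q=6, tau=8, 7x4, 4 experts)."""
    return breast_cancer()
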