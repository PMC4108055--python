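import pytest

from ko2gem import fixtures as fx


@pytest.fixture(scope="session")
def bundle():
    return fx.make_bundle()


@pytest.fixture()
def toy_bif(bundle):
    return bundle.toy_bif.copy()


@pytest.fixture()
def toy_fap(bundle):
    return bundle.toy_fap.copy()
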