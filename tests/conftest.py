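import pytest

from psimi_coop import builtin_registry, cdc6_full, vignette

VIGNETTE_NAMES = ("chey_flim", "skp2_cks1_p27", "plcg1_lat")


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture()
def cdc6():
    return cdc6_full()


@pytest.fixture()
def cdc6_entry(cdc6):
    return cdc6.entries[0]


@pytest.fixture(params=["cdc6", *VIGNETTE_NAMES])
def any_fixture(request):
    if request.param == "cdc6":
        return cdc6_full()
    return vignette(request.param)
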