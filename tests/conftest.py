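import pytest

from regmis import LayerConfig, expand_reaction, make_toggle_fixture, make_toy_gem


@pytest.fixture(scope="session")
def toggle_bundle():
    return make_toggle_fixture()


@pytest.fixture(scope="session")
def toggle_net(toggle_bundle):
    """The 4-node cyclic eGPR: Rx=g1, g1=r1, r1=not r2, r2=not r1."""
    return expand_reaction(toggle_bundle.model, toggle_bundle.regnet, "Rx",
                           LayerConfig(n_layers=2))


@pytest.fixture(scope="session", params=["plain", "activator", "repressor"])
def toy_bundle(request):
    return make_toy_gem(request.param)
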