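import pytest

from ephaptic import CommonParams, ORNSpec, calibrate_resting, default_params


@pytest.fixture(scope="session")
def tables():
    return default_params()


@pytest.fixture(scope="session")
def ab3(tables):
    return tables.model("ab3")


@pytest.fixture(scope="session")
def ab4(tables):
    return tables.model("ab4")


@pytest.fixture(scope="session")
def ab5(tables):
    return tables.model("ab5")


@pytest.fixture(scope="session")
def common(tables):
    return tables.common


@pytest.fixture()
def symmetric_model(common):
    """Two identical neurons: every asymmetry measure must vanish."""
    a = ORNSpec("symA", A_s=100.0, A_d=30.0, k_od=-4.0)
    b = ORNSpec("symB", A_s=100.0, A_d=30.0, k_od=-4.0)
    return calibrate_resting(common, a, b, name="sym")
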