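import pytest

from physchem.synthetic import make_rk_fixture


@pytest.fixture(scope="session")
def rk_fixture():
    """The calibrated raspberry-ketone reference ledger (deterministic)."""
    return make_rk_fixture()


@pytest.fixture(scope="session")
def rk_report(rk_fixture):
    from physchem.report import analyze_rk

    return analyze_rk(rk_fixture, ph=7.4)
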