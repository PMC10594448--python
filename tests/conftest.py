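import numpy as np
import pytest

from adc_target_vault import synth
from adc_target_vault.store import Vault


@pytest.fixture(scope="session")
def fixture_cfg():
    """Default study-condition fixture: 50 proteins, 5 planted targets."""
    return synth.FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def proteome(fixture_cfg):
    return synth.gen_proteome(fixture_cfg)


@pytest.fixture(scope="session")
def expression(fixture_cfg, proteome):
    proteins, _ = proteome
    return synth.gen_expression(fixture_cfg, proteins, "ovarian cancer")


@pytest.fixture()
def vault(proteome, expression):
    proteins, tms = proteome
    healthy, cancer = expression
    v = Vault.create()
    v.ingest_records(proteins, tms, healthy, cancer)
    yield v
    v.close()


@pytest.fixture(scope="session")
def noiseless_corrected():
    """Double-referenced cycles from a noiseless artefact-laden run."""
    from adc_target_vault import spr

    cfg = synth.SimSensorgramConfig(
        seed=0, noise_sd=0.0, drift_slope=0.05, bulk_shift=25.0)
    return cfg, spr.double_reference_series(synth.simulate_sensorgram(cfg))
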