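import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True)
_hyp_settings.load_profile("det")

from mecell import (
    MiniCellConfig,
    assemble_me_model,
    decouple_model,
    generate_minicell,
    maximize_growth,
)
from mecell.organism import Gene, TranscriptionUnit


@pytest.fixture(scope="session")
def config():
    return MiniCellConfig()


@pytest.fixture(scope="session")
def spec(config):
    return generate_minicell(config, seed=7)


@pytest.fixture(scope="session")
def model(spec):
    return assemble_me_model(spec)


@pytest.fixture(scope="session")
def growth(model):
    return maximize_growth(model)


@pytest.fixture(scope="session")
def decoupled(model):
    return decouple_model(model)


@pytest.fixture(scope="session")
def decoupled_growth(decoupled):
    return maximize_growth(decoupled)


@pytest.fixture
def toy_gene():
    # encodes the peptide M-G-K
    return Gene("gA", "ATGGGTAAATAA")


@pytest.fixture
def toy_tu():
    # references a real gene so role lookups resolve; the four-letter
    # sequence makes the NTP bookkeeping trivially checkable
    return TranscriptionUnit("tuA", ("g_glyc",), "ACGT")
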