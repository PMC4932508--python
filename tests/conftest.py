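import numpy as np
import pytest

from drpcore import IsoformRecord, SyntheticConfig, gen_isoform


@pytest.fixture
def toy_record():
    """14-residue loop analogue with four cleavable arginines."""
    return IsoformRecord(id="toy", sequence="RRDPYSPSPYDRRG")


@pytest.fixture
def bonded_record():
    """Small crosslinked record: two Cys joined by one disulphide."""
    return IsoformRecord(
        id="bonded",
        sequence="ACKDEFRCGHIK",
        disulphides=frozenset({(2, 8)}),
    )


@pytest.fixture
def synth_record():
    return gen_isoform(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
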