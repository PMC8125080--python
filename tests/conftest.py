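import numpy as np
import pytest

from viroscope import CommunityConfig, generate_community


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic community, fixed seed, shared across tests."""
    return generate_community(CommunityConfig(seed=1))


@pytest.fixture(scope="session")
def viral_seqs(bundle):
    return {
        cid: seq
        for cid, seq in bundle.contigs.items()
        if bundle.truth.viral_status[cid]
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
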