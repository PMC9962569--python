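import logging

import numpy as np
import pytest

from swarmsr import data as sdata
from swarmsr.network import NetworkSpec, build_network

logging.getLogger("swarmsr").setLevel(logging.ERROR)

#: small architecture for fast training-loop tests
TINY_SPEC = NetworkSpec(scale_factor=2, d=4, s=2, m=1)


@pytest.fixture(scope="session")
def corpus():
    return sdata.generate_corpus(sdata.CorpusSpec(n_images=8, size=32, seed=3))


@pytest.fixture(scope="session")
def tiny_batch():
    """A dozen aligned 6->12 patch pairs from a small synthetic corpus."""
    imgs = sdata.generate_corpus(sdata.CorpusSpec(n_images=3, size=24, seed=5))
    pairs = [sdata.make_pair(im, 2) for im in imgs]
    return sdata.concat_batches(
        [sdata.extract_patch_pairs(p, 6, 6) for p in pairs])


@pytest.fixture
def tiny_net():
    return build_network(TINY_SPEC, init_seed=0)
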