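import logging

import numpy as np
import pytest

import loki

logging.getLogger("loki").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_slide():
    """60-spot, 100-gene, 4-domain synthetic slide with patches and truth."""
    cfg = loki.SynthConfig(n_spots=60, n_genes=100, n_types=4, seed=11)
    return loki.make_slide(cfg)


@pytest.fixture(scope="session")
def medium_slide():
    """200-spot slide used by alignment and query tests."""
    cfg = loki.SynthConfig(n_spots=200, n_genes=200, n_types=4, seed=7)
    return loki.make_slide(cfg)


@pytest.fixture(scope="session")
def hash_backend():
    return loki.HashEncoder(d=96, seed=0)


def unit_rows(m):
    return m / np.linalg.norm(m, axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
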