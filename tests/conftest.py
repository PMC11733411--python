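import dataclasses

import pytest

from tradefd import build_space, gen_ledger, gen_pool, standardize
from tradefd.synth import scaled_config


@pytest.fixture(scope="session")
def pool300():
    """A 300-species synthetic pool with complete truth traits."""
    cfg = scaled_config(300, seed=11)
    return gen_pool(cfg), cfg


@pytest.fixture(scope="session")
def space300(pool300):
    """3-axis functional space of the 300-species pool (true traits)."""
    pool, _ = pool300
    std = standardize(pool.truth)
    return build_space(std, 3), std


@pytest.fixture(scope="session")
def synthetic_run():
    """A full small synthetic study: pool + ledger at 150 species."""
    cfg = dataclasses.replace(scaled_config(150, seed=23), years=(2000, 2009))
    pool = gen_pool(cfg)
    led = gen_ledger(pool, cfg)
    return pool, led, cfg
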