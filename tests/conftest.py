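import numpy as np
import pytest

from gamrec import simulate as sim


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_clean_sim():
    """A small error-free simulation shared across read-level tests.

    High event rate and no observation noise so that planted events are
    plentiful and exactly recoverable.
    """
    cfg = sim.SimulationConfig.tract_study(n_reads=20_000, seed=5)
    rng = np.random.default_rng(5)
    mm = sim.build_marker_map(cfg, rng)
    reads = sim.simulate_reads(mm, cfg, rng)
    return cfg, mm, reads
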