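import zlib

import numpy as np
import pytest

from fretcascade.synthetic import simulate_tcspc, table1_model


@pytest.fixture(scope="session")
def table1_trace():
    """Factory for cached 1e6-count synthetic traces of the published
    fitted-parameter sets (fixed per-name seeds)."""
    cache = {}

    def _make(name, total_counts=1_000_000, seed=None):
        key = (name, total_counts, seed)
        if key not in cache:
            use_seed = seed if seed is not None else zlib.crc32(name.encode()) % (2 ** 31)
            cache[key] = simulate_tcspc(table1_model(name),
                                        total_counts=total_counts,
                                        seed=use_seed)
        return cache[key]

    return _make


@pytest.fixture()
def fine_time_grid():
    """High-resolution time grid for closed-form convolution oracles."""
    n = 2 ** 19
    rep = 12.5
    return np.arange(n) * (rep / n), rep
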