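import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gapkit.formats_io import load_strain_table
from gapkit.simulate import (
    error_free,
    preset,
    simulate_community,
    simulate_references,
    simulate_reads,
)


@pytest.fixture(scope="session")
def strain_table():
    return load_strain_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """Error-free bacterial-style run: 5 single-reference clusters, one
    sample, modest depth; shared across tests as read-only ground truth."""
    cfg = error_free(preset(
        "bacterial448", n_clusters=5, refs_per_cluster=1, n_samples=1,
        depth=2000, gradient_strength=0.0, seed=11,
    ))
    master = np.random.default_rng(cfg.seed)
    refdb = simulate_references(cfg, master)
    community, env = simulate_community(refdb, cfg, master)
    samples = simulate_reads(community, refdb, cfg, master)
    return cfg, refdb, community, env, samples
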