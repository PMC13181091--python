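import numpy as np
import pytest

from crestkit.library_design import (
    DesignConfig,
    TargetWindow,
    normalize_and_filter,
    pair_sequential,
    scan_guide_sites,
)
from crestkit.simulate import make_genome


@pytest.fixture(scope="session")
def small_genome():
    genome, _ = make_genome(100_000, gc=0.41, seed=101)
    return genome


@pytest.fixture(scope="session")
def small_design(small_genome):
    """A 100-kb, 3x design with negative controls, reused across tests."""
    window = TargetWindow(small_genome.name, 0, len(small_genome))
    cfg = DesignConfig(target_coverage=3, deletion_size_window=(2000, 3500), seed=101)
    sites = normalize_and_filter(scan_guide_sites(small_genome, window), cfg)
    pairs = pair_sequential(sites, window, cfg)
    return {"genome": small_genome, "window": window, "cfg": cfg,
            "sites": sites, "pairs": pairs}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
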