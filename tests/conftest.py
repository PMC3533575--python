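import numpy as np
import pytest

from alfasnp.filtering import call_variants
from alfasnp.genotyping import core_set
from alfasnp.simulate import default_panel_config, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """Default 27-genotype panel, 50 contigs x 6 sites, fixed seed."""
    cfg = default_panel_config(seed=123, n_contigs=50, sites_per_contig=6)
    counts, truth, groups, contigs = simulate_panel(cfg)
    return cfg, counts, truth, groups, contigs


@pytest.fixture(scope="session")
def small_calls(small_panel):
    _, counts, _, _, _ = small_panel
    return call_variants(counts)


@pytest.fixture(scope="session")
def small_matrix(small_panel, small_calls):
    _, counts, _, groups, _ = small_panel
    return core_set(small_calls, counts, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
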