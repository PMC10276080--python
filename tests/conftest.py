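import warnings

import numpy as np
import pytest

from ighrep.annotate import GermlineDB, build_junction_pssms
from ighrep.germline import builtin_germlines
from ighrep.simulate import SHM_REGIONS, SimCohortConfig, simulate_clone


@pytest.fixture(scope="session")
def germlines():
    return builtin_germlines()


@pytest.fixture(scope="session")
def v_genes(germlines):
    return germlines[0]


@pytest.fixture(scope="session")
def j_genes(germlines):
    return germlines[1]


@pytest.fixture(scope="session")
def pssms(germlines):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return build_junction_pssms(*germlines)


@pytest.fixture(scope="session")
def db(germlines):
    return GermlineDB(*germlines)


@pytest.fixture(scope="session")
def clean_clones(germlines):
    """200 clones simulated without SHM (sequencing-error-free truth)."""
    v, j = germlines
    rng = np.random.default_rng(101)
    cfg = SimCohortConfig(shm_rate_per_region={r: 0.0 for r in SHM_REGIONS})
    return [simulate_clone(v, j, cfg, rng, clone_id=i) for i in range(200)]


def make_clones(v_genes, j_genes, shm_rate, n, seed):
    rng = np.random.default_rng(seed)
    cfg = SimCohortConfig(shm_rate_per_region={r: shm_rate for r in SHM_REGIONS})
    return [simulate_clone(v_genes, j_genes, cfg, rng, clone_id=i) for i in range(n)]
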