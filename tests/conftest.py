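import numpy as np
import pandas as pd
import pytest

import clonetrack as ct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def branching_bundle():
    """One simulated branching patient with colonies, shared across tests."""
    cfg = ct.SimulationConfig(seed=3, n_clones=3, topology="branching",
                              n_timepoints=5)
    return ct.simulate_patient(cfg)


@pytest.fixture(scope="session")
def branching_results(branching_bundle):
    b = branching_bundle
    model = ct.ClonalEvolution(b.counts, b.sample_sheet, b.segments,
                               b.colonies, variants=b.variants_frame())
    return model.fit()


def make_ccf_matrix(ccf_rows: dict, se: float = 0.01,
                    samples=None) -> ct.CcfMatrix:
    """Small CCF matrix literal for clustering/forest tests."""
    ccf = pd.DataFrame(ccf_rows).T.astype(float)
    if samples is not None:
        ccf.columns = samples
    se_frame = pd.DataFrame(se, index=ccf.index, columns=ccf.columns)
    below = pd.DataFrame(False, index=ccf.index, columns=ccf.columns)
    return ct.CcfMatrix(ccf, se_frame, below)
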