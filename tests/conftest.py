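import numpy as np
import pytest

import splenotrain as st


@pytest.fixture
def tiny_counts():
    """3 genes x 3 cells with distinct totals."""
    vals = np.array([[50, 150, 250],
                     [30, 90, 150],
                     [20, 60, 100]])
    return st.CountMatrix(vals, ["Actb", "Gbp2", "Ly6a"], ["c1", "c2", "c3"])


@pytest.fixture(scope="session")
def sc_sim():
    return st.simulate_sc_counts(st.ScSimSpec(rng_seed=1))


@pytest.fixture(scope="session")
def sc_result(sc_sim):
    """Full single-cell pipeline on the default synthetic dataset."""
    cfg = st.AnalysisConfig(rng_seed=1)
    return st.sc_pipeline(sc_sim.counts, cfg, markers=sc_sim.truth.marker_genes_of)


@pytest.fixture(scope="session")
def bulk_sim_sustained():
    """Bulk time course with sustained-only planted responders."""
    spec = st.BulkSimSpec(profile_shapes=("sustained",), rng_seed=7)
    return st.simulate_bulk_timecourse(spec)
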