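import numpy as np
import pytest

from dynconn import CohortConfig, DynamicEdge, GroundTruth, StaticEdge, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, 7 gray + 12 white nodes, planted static + dynamic edges."""
    cfg = CohortConfig(
        n_cn=20, n_smc=20, n_ci=20, n_gray=7, n_white=12, n_timepoints=150, seed=7
    )
    truth = GroundTruth(
        static_edges=[StaticEdge(0, 7, {"CN": 0.5, "SMC": 0.5, "CI": 0.2})],
        dynamic_edges=[DynamicEdge(1, 8, {"CN": 0.0, "SMC": 0.3, "CI": 0.6}, period_tr=50)],
        scale_loadings={"mmse": 0.4, "cdr_sb": -0.4},
    )
    return generate_cohort(cfg, truth)
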