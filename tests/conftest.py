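import numpy as np
import pytest

import clcgating as cg


@pytest.fixture(scope="session")
def protonated_model():
    return cg.build_reference_model(protonated=True)


@pytest.fixture(scope="session")
def deprotonated_model():
    return cg.build_reference_model(protonated=False)


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down two-condition pipeline shared by several module tests.

    Small enough to run in ~10 s; the full study conditions are exercised
    in the acceptance tests.
    """
    cfg = cg.PipelineConfig(n_traj=30, n_steps=4000, k=80, n_boot=10,
                            kmeans_iter=150, seed=3)
    return cg.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
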