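import numpy as np
import pytest

from rfnclust.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def planted_result(tmp_path_factory):
    """One full pipeline run on the planted two-network study conditions.

    20 subjects, T = 290, 600 in-mask voxels on a 12x10x5 grid; two networks
    (3 sub-networks of 80 / 2 of 100) with within-sub CC 0.6, within-network
    0.4, between-network 0.05, plus 160 unstructured background voxels.
    Session-scoped: generated once and shared by recovery tests.
    """
    cfg = PipelineConfig(
        seed=20260929,
        out_dir=str(tmp_path_factory.mktemp("planted")),
        grid_shape=(12, 10, 5),
        network_sub_sizes=((80, 80, 80), (100, 100)),
        n_subjects=20,
        n_timepoints=290,
        k_initial=8,
        s_min=50,
        s_max=300,
        n_iterations=1000,
        dissect_k_max=40,
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
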