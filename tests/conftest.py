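import numpy as np
import pytest

from cortexflow.io_preprocess import CountMatrix
from cortexflow.pipeline import PipelineConfig, run_pipeline
from cortexflow.synthetic_data import SimConfig, simulate_timecourse


@pytest.fixture(scope="session")
def small_sim():
    """Small but fully structured time course (one per test session)."""
    cfg = SimConfig(n_cells_per_timepoint=400, seed=7)
    cm, meta, gt = simulate_timecourse(cfg)
    return cfg, cm, meta, gt


@pytest.fixture(scope="session")
def default_report():
    """One full pipeline run at the study's default scale."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def tiny_counts():
    counts = np.array([[1, 0, 3, 0],
                       [0, 2, 0, 4],
                       [5, 0, 0, 1]])
    return CountMatrix(counts, [f"c{i}" for i in range(3)],
                       [f"g{j}" for j in range(4)])
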