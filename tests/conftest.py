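import numpy as np
import pytest

from cogreserve import CVConfig, GenConfig, generate_dataset


@pytest.fixture
def small_cv():
    """Fast CV settings for unit tests: tiny penalty grid, few folds."""
    return CVConfig(
        n_outer_folds=5,
        n_inner_folds=3,
        penalty_grid=tuple((l1, a) for l1 in (0.01, 0.5) for a in (0.01, 0.1, 1.0)),
        n_repeats=2,
        seed=7,
    )


@pytest.fixture
def small_dataset():
    """Small two-brain-block dataset with strong, well-separated signals."""
    cfg = GenConfig(
        n_subjects=250,
        block_schema=(("con", 2), ("A", 15), ("B", 15)),
        signal_share={"con": 0.1, "A": 0.3, "B": 0.2},
        shared_share=0.0,
        reliability=0.8,
        feature_noise_sd=0.3,
        seed=11,
    )
    data, truth = generate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
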