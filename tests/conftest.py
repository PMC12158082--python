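import numpy as np
import pytest

import radarfall as rf

# 14-point worked example used to anchor the lexicographic ordering
SORT_EXAMPLE = np.array(
    [
        (1.24, 1.99, 1.57),
        (1.96, 1.99, 1.42),
        (0.48, 0.11, 0.96),
        (1.61, 0.17, 0.69),
        (1.50, 0.58, 1.40),
        (1.96, 1.99, 0.67),
        (0.26, 0.48, 0.12),
        (0.36, 0.48, 1.82),
        (0.36, 0.48, 1.97),
        (0.90, 0.44, 0.55),
        (1.61, 1.60, 0.67),
        (0.90, 1.21, 1.80),
        (1.61, 1.60, 0.55),
        (1.96, 1.99, 1.99),
    ]
)


@pytest.fixture(scope="session")
def gen_cfg():
    return rf.GeneratorConfig(seed=11, distance_m=3.0)


@pytest.fixture(scope="session")
def small_dataset(gen_cfg):
    """30 frames/class, canonicalized — enough for learning-sanity tests."""
    frames, labels = rf.generate_labeled_dataset(30, gen_cfg)
    normalized = rf.standardize_sequence(frames, seed=0)
    return normalized, labels


@pytest.fixture()
def tiny_sequence(gen_cfg):
    rng = np.random.default_rng(5)
    script = rf.MotionScript("fall", 25, 1.8, 0.2, 2.0, bump=False)
    return rf.generate_transition_sequence(script, gen_cfg, rng), script
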