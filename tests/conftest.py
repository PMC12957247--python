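import math

import numpy as np
import pytest

from eegsev.model import ModelSpec
from eegsev.synthetic import CohortSpec, CouplingSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small uniform-severity cohort: 8 subjects x 60 s, default coupling."""
    spec = CohortSpec(n_subjects=8, duration_s=60.0, seed=11)
    return generate_cohort(spec), spec


@pytest.fixture(scope="session")
def coupled_recording_spec():
    """Single strong beta coupling FP1-T3 at quarter-pi lag, no noise."""
    return CohortSpec(
        n_subjects=2, duration_s=60.0, snr_db=None,
        coupling_map=lambda s: [
            CouplingSpec(("FP1", "T3"), "beta", 1.0, math.pi / 2)],
        seed=5)


@pytest.fixture
def toy_model_spec():
    """Small Conv_gMLP dimensions for arithmetic and gradient oracles."""
    return ModelSpec(d_feature=6, d_channel=4, num_layers=2, d_ffn=3,
                     norm="none", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
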