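import numpy as np
import pytest

from golgikin import AcquisitionModel, GroundTruth


@pytest.fixture
def time_grid():
    """Standard 60-frame, 6-s acquisition grid."""
    return np.arange(60) * 6.0


@pytest.fixture
def truth_params():
    """One representative parameter set per curve family (percent scale)."""
    return {
        1: {"y0": 100.0, "b": 0.25},
        2: {"a": 100.0, "k": 0.008, "c": 0.0},
        3: {"y0": 100.0, "t_b": 60.0, "k": 0.01, "c": 0.0},
        4: {"y0": 100.0, "b": 0.15, "t_b": 60.0, "k": 0.01, "c": 0.0},
        5: {"y0": 100.0, "t_b": 60.0, "b": 0.25},
    }


@pytest.fixture
def clean_acquisition():
    """Noise-, fade- and background-free acquisition (identity instrument)."""
    return AcquisitionModel(dt_s=6.0, n_frames=60, seed=0)


def make_truth(family_id, params, **kwargs):
    return GroundTruth(family_id=family_id, params=dict(params), **kwargs)
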