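import numpy as np
import pytest

from carotidseg import EcgVideoSpec, PhantomSpec, make_artery_phantom, make_ecg_video


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def clean_phantom():
    """Noiseless artery phantom with default geometry."""
    spec = PhantomSpec()
    frame, gt = make_artery_phantom(spec)
    return spec, frame, gt


@pytest.fixture
def plaque_phantom():
    """Noiseless phantom with a plaque bump on the right side."""
    spec = PhantomSpec(plaque_bump=(0.0, 10.0))
    frame, gt = make_artery_phantom(spec)
    return spec, frame, gt


@pytest.fixture
def ecg_video():
    """Letter-free ECG video with four well-separated beats."""
    spec = EcgVideoSpec(seed=4, qrs_columns_global=(30, 75, 120, 170), n_frames=20)
    frames, gt = make_ecg_video(spec)
    return spec, frames, gt
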