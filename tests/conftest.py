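import numpy as np
import pytest

from fretkin.fret_core import CorrectionConfig, compute_efficiency
from fretkin.synthetic_scene import (SceneSpec, build_pouch_labels,
                                     make_ground_truth, render_frames)


@pytest.fixture(scope="session")
def noiseless_scene():
    """Small noiseless scene with default regional kinetics (45 vs 30 min)."""
    spec = SceneSpec(height_px=64, width_px=64, pixel_size_um=1.0,
                     n_frames=40, drug_time_min=5.0, noise_sigma=0.0, seed=11)
    labels = build_pouch_labels(spec)
    truth = make_ground_truth(spec, labels)
    raw = render_frames(spec, truth)
    return spec, labels, truth, raw


@pytest.fixture(scope="session")
def noiseless_eta(noiseless_scene):
    """Efficiency stack recovered from the noiseless scene, no smoothing."""
    spec, labels, truth, raw = noiseless_scene
    cfg = CorrectionConfig(beta=spec.beta, kernel_size=1,
                           bg_donor=spec.bg_donor, bg_fret=spec.bg_fret)
    return compute_efficiency(raw, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
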