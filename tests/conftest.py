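import numpy as np
import pytest

import cardiomap as cm


@pytest.fixture(scope="session")
def default_phantom():
    return cm.make_phantom(seed=3)


@pytest.fixture(scope="session")
def noisefree_stack(default_phantom):
    return cm.render_mri_stack(default_phantom, si_normal_sd=0.0, seed=4)


@pytest.fixture(scope="session")
def exact_model():
    """Voltage model with noise and spatial summation switched off."""
    return cm.VoltageModel(noise_sd_mV=0.0, neighborhood_cells=0)


@pytest.fixture(scope="session")
def noisefree_cohort(exact_model):
    """30 varied phantoms with exact transmurality and dense bipolar maps."""
    rng = np.random.default_rng(42)
    phantoms, tmaps, bmaps = [], [], []
    for s in range(30):
        ph = cm.make_phantom(rng.uniform(0.25, 0.45), rng.uniform(0.25, 0.55),
                             seed=1000 + s)
        phantoms.append(ph)
        tmaps.append(cm.TransmuralityPolarMap(
            values=ph.transmurality_field,
            valid=np.ones_like(ph.transmurality_field, dtype=bool)))
        bmaps.append(cm.build_polar_map(
            cm.dense_sample_points(ph, exact_model), "bipv",
            fibrous_ring_frac=0.0))
    return phantoms, tmaps, bmaps
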