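import warnings

import numpy as np
import pytest

from ba_diag.synthetic import CohortConfig, default_scene_configs, generate_dataset

# constant-feature warnings from tiny fixtures are expected noise
warnings.filterwarnings("ignore", message="dropping .* constant feature")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 25-patient on-disk dataset with some views missing."""
    out = tmp_path_factory.mktemp("dataset")
    cfg = CohortConfig(n_patients=25, prevalence=0.4, seed=7, missing_view_rate=0.15)
    manifest = generate_dataset(cfg, default_scene_configs((96, 96)), out)
    return out, cfg, manifest


def speckle_image(shape=(128, 128), mean=90.0, std=12.0, seed=0):
    """Seeded Gaussian-speckle phantom used across tests."""
    g = np.random.default_rng(seed)
    return np.clip(g.normal(mean, std, size=shape), 0, 255)
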