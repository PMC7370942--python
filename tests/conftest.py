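import numpy as np
import pytest

from capreg.io import default_reference_mni_path, read_fiducials_csv
from capreg.registration import register_model_cap
from capreg.synthetic import make_model_head


@pytest.fixture(scope="session")
def model_scene():
    """Reference ellipsoid head (the 'model cap' capture)."""
    return make_model_head(semi_axes=(80.0, 95.0, 90.0),
                           n_surface_points=2000, seed=1)


@pytest.fixture(scope="session")
def model_cap(model_scene):
    return register_model_cap(model_scene.true_fiducials,
                              model_scene.true_probes)


@pytest.fixture(scope="session")
def reference_mni():
    return read_fiducials_csv(default_reference_mni_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
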