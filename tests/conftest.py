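import numpy as np
import pytest

from growthchart import fda as fda_mod
from growthchart import synthetic as syn


@pytest.fixture(scope="session")
def atlas_spec():
    return syn.default_atlas_spec()


@pytest.fixture(scope="session")
def volume(atlas_spec):
    return syn.generate_label_volume(atlas_spec)


@pytest.fixture(scope="session")
def ontology(atlas_spec):
    return syn.build_ontology(atlas_spec)


@pytest.fixture(scope="session")
def small_bundle():
    """Two samples per age, stochastic detection."""
    return syn.generate_study(n_per_age=2, seed=11)


@pytest.fixture(scope="session")
def ideal_bundle():
    """Two samples per age, ideal (deterministic 2D counting) detection."""
    det = syn.DetectionSimSpec(mode="ideal")
    return syn.generate_study(detection=det, n_per_age=2, seed=7)


@pytest.fixture(scope="session")
def cortical_centroids(volume, atlas_spec):
    cents = fda_mod.compute_region_centroids(volume, atlas_spec.cortical_ids)
    return cents[["x_um", "y_um", "z_um"]].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
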