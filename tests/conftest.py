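import numpy as np
import pytest

from redoxscope.optics import default_optical_model, noise_free
from redoxscope.synthetic import SceneSpec, StrainSpec, generate_scene


@pytest.fixture(scope="session")
def nf_optics():
    """Default optical model with all noise switched off."""
    return noise_free(default_optical_model())


def small_scene_spec(seed=1, **overrides):
    kwargs = dict(
        image_shape=(256, 256),
        n_frames=3,
        strains=[
            StrainSpec(name="WT", compartment="wt", n_cells=5),
            StrainSpec(name="cyt", compartment="cytosol", n_cells=5, oxd_air=0.3),
            StrainSpec(
                name="carb", compartment="carboxysome", n_cells=5, oxd_air=0.8,
                puncta_per_cell=2, puncta_area_px=75,
            ),
        ],
        rng_seed=seed,
        burn_in_offset=0.0,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


@pytest.fixture(scope="session")
def small_scene(nf_optics):
    """Small noise-free mixed-strain scene shared across read-only tests."""
    return generate_scene(small_scene_spec(), nf_optics)


def majority_overlap(seg_labels: np.ndarray, oracle: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the oracle label it mostly overlaps."""
    out = {}
    for lab in np.unique(seg_labels[seg_labels > 0]):
        ids, counts = np.unique(oracle[seg_labels == lab], return_counts=True)
        nz = ids != 0
        if nz.any():
            out[int(lab)] = int(ids[nz][np.argmax(counts[nz])])
    return out
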