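"""Generator contracts: endmember recovery, determinism, ground-truth
consistency, spectra, dataset round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redoxscope.optics import (
    OpticalModel,
    SpectralEndmembers,
    WAVELENGTHS_NM,
    default_optical_model,
    noise_free,
)
from redoxscope.ratiometrics import add_ratios, estimate_background, measure_objects
from redoxscope.segmentation import LabelMap
from redoxscope.synthetic import (
    SceneSpec,
    ScenePlacementError,
    StrainSpec,
    generate_scene,
    generate_spectrum,
    read_stack,
    replay_manifest,
    write_dataset,
)

from conftest import small_scene_spec


def _one_cell_spec(oxd, seed=3, **strain_kw):
    return SceneSpec(
        image_shape=(128, 128),
        n_frames=1,
        strains=[
            StrainSpec(name="cyt", compartment="cytosol", n_cells=1,
                       oxd_air=oxd, oxd_sd=0.0, **strain_kw)
        ],
        rng_seed=seed,
        burn_in_offset=0.0,
    )


def _measured_ratio(res):
    """Object-mean ratio using the known background (autofluor + camera)."""
    optics = res.optics
    cm = LabelMap(res.cell_labels[0], "cell", 0)
    m = measure_objects(res.stack.channel("ex395", 0), res.stack.channel("ex470", 0), cm)
    b = optics.autofluor_mean + optics.background_mean
    return float((m.i_395 - b) / (m.i_470 - b))


@pytest.mark.parametrize("oxd,attr", [(0.0, "red"), (1.0, "ox")])
def test_noise_free_endmember_ratio_is_exact(nf_optics, oxd, attr):
    """A noise-free pure-endmember cell yields exactly s_x_395/s_x_470."""
    res = generate_scene(_one_cell_spec(oxd), nf_optics)
    expected = getattr(nf_optics, f"s_{attr}_395") / getattr(nf_optics, f"s_{attr}_470")
    assert _measured_ratio(res) == pytest.approx(expected, abs=1e-12)


def test_same_seed_is_bit_identical(nf_optics):
    spec = small_scene_spec(seed=11)
    a = generate_scene(spec, nf_optics)
    b = generate_scene(spec, nf_optics)
    np.testing.assert_array_equal(a.stack.data, b.stack.data)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_concentration_invariance_of_truth_and_measurement(nf_optics):
    """Doubling probe abundance changes intensities but not the ratio."""
    r1 = generate_scene(_one_cell_spec(0.6, probe_level=1000.0), nf_optics)
    r2 = generate_scene(_one_cell_spec(0.6, probe_level=2000.0), nf_optics)
    assert r2.stack.data[0, 0].max() > r1.stack.data[0, 0].max()
    np.testing.assert_allclose(
        r1.truth.true_ratio.dropna(), r2.truth.true_ratio.dropna()
    )
    assert _measured_ratio(r1) == pytest.approx(_measured_ratio(r2), abs=1e-12)


def test_wt_objects_have_no_probe_signal(nf_optics):
    spec = SceneSpec(
        image_shape=(128, 128), n_frames=1,
        strains=[StrainSpec(name="WT", compartment="wt", n_cells=4)],
        rng_seed=5, burn_in_offset=0.0,
    )
    res = generate_scene(spec, nf_optics)
    mask = res.cell_labels[0] > 0
    expected = nf_optics.background_mean + nf_optics.autofluor_mean
    for ch in ("ex395", "ex470"):
        img = res.stack.channel(ch, 0)
        np.testing.assert_allclose(img[mask], expected)
        np.testing.assert_allclose(img[~mask], nf_optics.background_mean)
    assert res.truth.true_ratio.isna().all()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    lo=st.floats(0.0, 1.0, exclude_max=True),
    delta=st.floats(1e-3, 1.0),
)
def test_true_ratio_strictly_increasing_in_oxd(lo, delta):
    optics = default_optical_model()
    hi = min(lo + delta, 1.0)
    if hi > lo:
        assert optics.ratio_from_oxd(hi) > optics.ratio_from_oxd(lo)


def test_invalid_optical_model_rejected():
    with pytest.raises(ValueError):
        OpticalModel(s_ox_395=0.1, s_ox_470=1.0, s_red_395=0.5, s_red_470=1.0)
    with pytest.raises(ValueError):
        OpticalModel(s_ox_395=1.0, s_ox_470=-1.0, s_red_395=0.1, s_red_470=1.0)


def test_crowded_scene_raises_placement_error(nf_optics):
    spec = SceneSpec(
        image_shape=(80, 80), n_frames=1,
        strains=[StrainSpec(name="cyt", compartment="cytosol", n_cells=60, oxd_air=0.5)],
        rng_seed=1, placement_retries=30,
    )
    with pytest.raises(ScenePlacementError):
        generate_scene(spec, nf_optics)


def test_labelmaps_and_truth_are_consistent(small_scene):
    """Every labeled object appears exactly once in the truth per frame, with
    matching pixel counts."""
    truth = small_scene.truth
    for f in range(small_scene.spec.n_frames):
        tf = truth[truth.frame == f]
        for kind, labmap in (
            ("cell", small_scene.cell_labels[f]),
            ("punctum", small_scene.puncta_labels[f]),
        ):
            ids = set(np.unique(labmap[labmap > 0]).tolist())
            rows = tf[tf.kind == kind]
            assert set(rows.object_id) == ids
            assert not rows.object_id.duplicated().any()
            for r in rows.itertuples():
                assert int((labmap == r.object_id).sum()) == r.area_px


def test_division_creates_new_object_ids(nf_optics):
    spec = SceneSpec(
        image_shape=(256, 256), n_frames=8,
        strains=[StrainSpec(name="cyt", compartment="cytosol", n_cells=10,
                            oxd_air=0.4, division_rate=0.3)],
        rng_seed=2, burn_in_offset=0.0,
    )
    res = generate_scene(spec, nf_optics)
    per_frame = res.truth.groupby("frame").object_id.nunique()
    assert per_frame.iloc[-1] > per_frame.iloc[0]  # divisions occurred
    first = set(res.truth[res.truth.frame == 0].object_id)
    last = set(res.truth[res.truth.frame == spec.n_frames - 1].object_id)
    assert last - first  # daughters carry fresh ids


# --- spectra ---------------------------------------------------------------


def test_spectrum_pure_oxidized_is_endmember_plus_blank():
    em = SpectralEndmembers()
    traces, blanks = generate_spectrum(1.0, em, amplitude=100.0, blank_level=5.0,
                                       n_replicates=1, noise_sd=0.0)
    np.testing.assert_allclose(traces[0].intensity, 100.0 * em.oxidized() + 5.0)
    np.testing.assert_allclose(blanks[0].intensity, 5.0)
    assert traces[0].intensity.size == 131


def test_spectrum_half_oxidized_is_exact_midpoint():
    em = SpectralEndmembers()
    (t0,), _ = generate_spectrum(0.0, em, n_replicates=1)
    (t1,), _ = generate_spectrum(1.0, em, n_replicates=1)
    (tm,), _ = generate_spectrum(0.5, em, n_replicates=1)
    np.testing.assert_allclose(tm.intensity, (t0.intensity + t1.intensity) / 2.0)


def test_spectrum_replicates_differ_only_by_noise():
    traces, _ = generate_spectrum(0.5, n_replicates=3, noise_sd=2.0, seed=4)
    base, _ = generate_spectrum(0.5, n_replicates=1, noise_sd=0.0)
    for t in traces:
        resid = t.intensity - base[0].intensity
        assert 0 < np.abs(resid).max() < 20.0
    assert not np.array_equal(traces[0].intensity, traces[1].intensity)


def test_spectrum_rejects_invalid_oxd():
    with pytest.raises(ValueError):
        generate_spectrum(1.5)


def test_oxidized_endmember_peaks_near_395_reduced_near_470():
    em = SpectralEndmembers()
    assert abs(WAVELENGTHS_NM[np.argmax(em.oxidized())] - 395) <= 5
    assert abs(WAVELENGTHS_NM[np.argmax(em.reduced())] - 470) <= 5


# --- dataset io ------------------------------------------------------------


def test_dataset_roundtrip_and_manifest_replay(small_scene, tmp_path):
    paths = write_dataset(small_scene, tmp_path / "ds")
    arr = read_stack(paths["stack"])
    np.testing.assert_array_equal(arr, small_scene.stack.data.astype(np.float32))

    replayed = replay_manifest(paths["manifest"])
    pd.testing.assert_frame_equal(replayed.truth, small_scene.truth)
    np.testing.assert_array_equal(replayed.stack.data, small_scene.stack.data)

    # truth row count equals total labeled objects over frames
    n_expected = sum(
        np.unique(m[m > 0]).size
        for maps in (small_scene.cell_labels, small_scene.puncta_labels)
        for m in maps
    )
    assert len(small_scene.truth) == n_expected
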