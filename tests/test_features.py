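"""Preprocessing, first-order, shape and full-vector extraction tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ball_mask, random_blob
from oracles import first_order_reference, resample_nn_bruteforce
from rimshrink.features import (
    CLASS_SIZES,
    PreprocessConfig,
    apply_window,
    discretize,
    extract_all,
    feature_names,
    first_order,
    names_by_class,
    resample_nn,
    shape_features,
)
from rimshrink.io import CTVolume, LesionMask


# ---------------------------------------------------------------------------
# windowing

def test_window_identity_inside_and_clamps_outside():
    vals = np.array([[[10.0, 500.0, -400.0, 40.0]]])
    vol = CTVolume(values=vals, spacing=(1, 1, 1))
    out = apply_window(vol, 40.0, 400.0)
    np.testing.assert_allclose(out.values[0, 0], [10.0, 240.0, -160.0, 40.0])


# ---------------------------------------------------------------------------
# resampling

def test_resample_identity_at_target_spacing(rng):
    vals = rng.normal(size=(9, 9, 9))
    vol = CTVolume(values=vals, spacing=(3, 3, 3))
    mask = LesionMask(labels=np.ones((9, 9, 9), dtype=np.uint8))
    out_vol, out_mask = resample_nn(vol, mask, (3, 3, 3))
    np.testing.assert_array_equal(out_vol.values, vals)
    assert out_mask.shape == (9, 9, 9)


def test_resample_ceil_sizing():
    vals = np.zeros((60, 30, 10))
    vol = CTVolume(values=vals, spacing=(1.0, 1.0, 3.75))
    mask = LesionMask(labels=np.ones_like(vals, dtype=np.uint8))
    out_vol, _ = resample_nn(vol, mask, (3, 3, 3))
    assert out_vol.shape == (20, 10, 13)  # ceil(60/3), ceil(30/3), ceil(37.5/3)


def test_resample_matches_bruteforce_nearest_centre(rng):
    vals = rng.normal(size=(7, 6, 5))
    spacing = (1.0, 1.3, 3.75)
    target = (3.0, 3.0, 3.0)
    vol = CTVolume(values=vals, spacing=spacing)
    mask = LesionMask(labels=(rng.random(vals.shape) > 0.4).astype(np.uint8) | 1)
    out_vol, _ = resample_nn(vol, mask, target)
    expected = resample_nn_bruteforce(vals, spacing, target)
    np.testing.assert_array_equal(out_vol.values, expected)


def test_resample_mask_stays_binary(rng):
    vals = rng.normal(size=(10, 10, 6))
    mask = LesionMask(labels=(rng.random((10, 10, 6)) > 0.5).astype(np.uint8))
    _, out_mask = resample_nn(CTVolume(values=vals, spacing=(1, 1, 2)), mask, (3, 3, 3))
    assert set(np.unique(out_mask.labels)) <= {0, 1}


# ---------------------------------------------------------------------------
# discretization

def test_discretize_constant_and_hand_example():
    vals = np.full((3, 1, 1), 55.0)
    mask = LesionMask(labels=np.ones((3, 1, 1), dtype=np.uint8))
    grey = discretize(CTVolume(values=vals, spacing=(1, 1, 1)), mask, 25.0)
    assert grey.ng == 1 and set(grey.levels) == {1}

    vals = np.array([10.0, 34.0, 60.0]).reshape(3, 1, 1)
    grey = discretize(CTVolume(values=vals, spacing=(1, 1, 1)), mask, 25.0)
    assert sorted(grey.levels.tolist()) == [1, 1, 3]
    assert grey.ng == 3


@settings(max_examples=25, deadline=None)
@given(shift=st.floats(-500, 500, allow_nan=False))
def test_discretize_translation_invariance(shift):
    rng = np.random.default_rng(0)
    vals = rng.normal(20, 30, size=(4, 4, 3))
    mask = LesionMask(labels=np.ones((4, 4, 3), dtype=np.uint8))
    a = discretize(CTVolume(values=vals, spacing=(1, 1, 1)), mask, 25.0)
    b = discretize(CTVolume(values=vals + shift, spacing=(1, 1, 1)), mask, 25.0)
    np.testing.assert_array_equal(a.level_grid, b.level_grid)
    assert a.ng == b.ng


# ---------------------------------------------------------------------------
# first order

def _grey(vals, mask, spacing=(1, 1, 1), bw=25.0):
    return discretize(CTVolume(values=vals, spacing=spacing),
                      LesionMask(labels=mask), bw)


def test_first_order_constant_roi_conventions():
    vals = np.full((3, 3, 1), 42.0)
    mask = np.ones((3, 3, 1), dtype=np.uint8)
    f = first_order(_grey(vals, mask), voxel_volume=1.0)
    assert f["firstorder_Mean"] == 42.0
    assert f["firstorder_Variance"] == 0.0
    assert f["firstorder_Entropy"] == 0.0
    assert f["firstorder_Uniformity"] == 1.0
    assert f["firstorder_Skewness"] == 0.0
    assert f["firstorder_Kurtosis"] == 0.0


def test_first_order_two_voxel_hand_arithmetic():
    vals = np.array([0.0, 10.0]).reshape(2, 1, 1)
    mask = np.ones((2, 1, 1), dtype=np.uint8)
    f = first_order(_grey(vals, mask), voxel_volume=2.0)
    assert f["firstorder_Mean"] == 5.0
    assert f["firstorder_Range"] == 10.0
    assert f["firstorder_Energy"] == 100.0
    assert f["firstorder_TotalEnergy"] == 200.0
    assert f["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt(50.0))


def test_first_order_matches_reference_implementation(rng):
    vals = rng.normal(30, 20, size=(6, 6, 4))
    mask = random_blob(rng, (6, 6, 4)).astype(np.uint8)
    grey = _grey(vals, mask)
    got = first_order(grey, voxel_volume=1.7)
    expected = first_order_reference(grey.raw_values, grey.levels.tolist(), 1.7)
    for k, v in expected.items():
        assert got[k] == pytest.approx(v, rel=1e-9), k


# ---------------------------------------------------------------------------
# shape

def test_shape_cube_voxel_volume_exact():
    mask = np.zeros((14, 14, 14), dtype=np.uint8)
    mask[2:12, 2:12, 2:12] = 1
    f = shape_features(LesionMask(labels=mask), (1, 1, 1))
    assert f["shape_VoxelVolume"] == 1000.0
    assert f["shape_MeshVolume"] == pytest.approx(1000.0, rel=0.1)


def test_shape_large_ball_sphericity_near_one():
    mask = ball_mask((60, 60, 60), (1, 1, 1), 25.0)
    f = shape_features(LesionMask(labels=mask), (1, 1, 1))
    assert f["shape_Sphericity"] == pytest.approx(1.0, abs=0.05)
    assert f["shape_Maximum3DDiameter"] == pytest.approx(50.0, rel=0.06)
    assert f["shape_Elongation"] == pytest.approx(1.0, abs=0.05)
    assert f["shape_Flatness"] == pytest.approx(1.0, abs=0.05)


def test_shape_spacing_scaling_dimensional_analysis(rng):
    mask = random_blob(rng, (10, 10, 8)).astype(np.uint8)
    f1 = shape_features(LesionMask(labels=mask), (1.0, 1.0, 2.0))
    f2 = shape_features(LesionMask(labels=mask), (2.0, 2.0, 4.0))
    assert f2["shape_MeshVolume"] == pytest.approx(8 * f1["shape_MeshVolume"], rel=1e-6)
    assert f2["shape_SurfaceArea"] == pytest.approx(4 * f1["shape_SurfaceArea"], rel=1e-6)
    assert f2["shape_Sphericity"] == pytest.approx(f1["shape_Sphericity"], rel=1e-6)


def test_shape_single_voxel_falls_back_to_box_forms():
    mask = np.zeros((5, 5, 5), dtype=np.uint8)
    mask[2, 2, 2] = 1
    f = shape_features(LesionMask(labels=mask), (1.0, 1.0, 2.0))
    assert f["shape_VoxelVolume"] == 2.0
    assert f["shape_MeshVolume"] == 2.0
    assert f["shape_SurfaceArea"] == pytest.approx(2 * (1 + 2 + 2))


# ---------------------------------------------------------------------------
# full vector

def test_extract_all_yields_104_partitioned_features(small_volume_mask):
    vol, mask = small_volume_mask
    vec = extract_all(vol, mask, PreprocessConfig())
    assert len(vec) == 104
    by_class = names_by_class()
    assert [len(by_class[c]) for c in ("FF", "MF", "TF")] == [18, 14, 72]
    assert list(vec.keys()) == feature_names()
    assert all(np.isfinite(v) for v in vec.values())


def test_extract_all_is_deterministic(small_volume_mask):
    vol, mask = small_volume_mask
    a = extract_all(vol, mask)
    b = extract_all(vol, mask)
    assert a == b


def test_registry_partition_sizes():
    assert CLASS_SIZES == {"FF": 18, "MF": 14, "TF": 72}
    fams = {}
    for n in feature_names():
        fams[n.split("_")[0]] = fams.get(n.split("_")[0], 0) + 1
    assert fams == {"firstorder": 18, "shape": 14, "glcm": 21, "glrlm": 16,
                    "glszm": 16, "gldm": 14, "ngtdm": 5}
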