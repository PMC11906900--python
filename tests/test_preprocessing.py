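"""Thresholding, component filtering, fibula removal, cropping, z-scoring."""

import numpy as np
import pytest
from scipy import ndimage

from dbahnet import (BinaryMask, IntensityVolume, PreprocessConfig,
                     autocrop_to_bone, keep_largest_component_3d,
                     otsu_threshold_value, otsu_threshold_with_margin,
                     preprocess_pipeline, remove_fibula_per_slice,
                     rescale_to_8bit, zscore_normalize)
from dbahnet.phantom import PhantomParams, generate_phantom, phantom_foreign_masks


def brute_force_otsu(vol8):
    """Exhaustive between-class-variance maximisation over all 256 splits."""
    hist = np.bincount(vol8.ravel(), minlength=256)
    total = hist.sum()
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t] * np.arange(t)).sum() / w0
        mu1 = (hist[t:] * np.arange(t, 256)).sum() / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def bimodal_volume(rng, means=(60, 180), sigma=10, shape=(16, 16, 16)):
    half = np.prod(shape) // 2
    vals = np.concatenate([
        rng.normal(means[0], sigma, half),
        rng.normal(means[1], sigma, np.prod(shape) - half)])
    rng.shuffle(vals)
    return IntensityVolume(np.clip(vals, 0, 255).reshape(shape).astype(np.float32))


def test_otsu_matches_exhaustive_bruteforce(rng):
    for _ in range(10):
        vol = bimodal_volume(rng)
        vol8 = rescale_to_8bit(vol)
        assert otsu_threshold_value(vol8) == brute_force_otsu(vol8)


def test_margin_shifts_threshold_and_zero_margin_is_plain_otsu(rng):
    vol = bimodal_volume(rng)
    vol8 = rescale_to_8bit(vol)
    t = otsu_threshold_value(vol8)
    mask5 = otsu_threshold_with_margin(vol, PreprocessConfig(margin=5))
    np.testing.assert_array_equal(mask5.voxels, vol8 >= t - 5)
    mask0 = otsu_threshold_with_margin(vol, PreprocessConfig(margin=0))
    np.testing.assert_array_equal(mask0.voxels, vol8 >= t)


def test_foreground_monotone_in_margin(rng):
    vol = bimodal_volume(rng)
    counts = [otsu_threshold_with_margin(vol, PreprocessConfig(margin=m)).count()
              for m in range(11)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_constant_volume_rejected():
    with pytest.raises(ValueError):
        otsu_threshold_with_margin(
            IntensityVolume(np.full((4, 4, 4), 7.0)), PreprocessConfig())


def test_largest_component_selected_by_bruteforce_count():
    m = np.zeros((20, 10, 10), bool)
    m[:6, :4, :4] = True     # 96 voxels
    m[12:, :2, :2] = True    # 32 voxels
    out = keep_largest_component_3d(BinaryMask(m))
    assert out.count() == 96
    lab, n = ndimage.label(out.voxels, structure=np.ones((3, 3, 3)))
    assert n == 1
    assert not (out.voxels & ~m).any()


def test_largest_component_idempotent_and_tie_break():
    m = np.zeros((20, 4, 4), bool)
    m[0:2, :2, :2] = True    # 8 voxels, smaller min linear index
    m[10:12, :2, :2] = True  # 8 voxels
    out = keep_largest_component_3d(BinaryMask(m))
    assert out.voxels[0, 0, 0] and not out.voxels[10, 0, 0]
    again = keep_largest_component_3d(out)
    np.testing.assert_array_equal(again.voxels, out.voxels)


def test_fibula_removal_per_slice_cases():
    m = np.zeros((30, 30, 3), bool)
    # slice 0: tibia-ish blob (500 px) + fibula blob (60 px)
    m[2:22, 2:27, 0] = True
    m[25:29, 2:17, 0] = True
    big = m[:, :, 0].sum() - 60
    # slice 1: single component
    m[5:15, 5:15, 1] = True
    # slice 2: three components 500 / 60 / 5 px
    m[2:22, 2:27, 2] = True
    m[25:29, 2:17, 2] = True
    m[25:29, 25:30, 2] = False
    m[27:28, 22:27, 2] = True
    out = remove_fibula_per_slice(BinaryMask(m))
    lab0, n0 = ndimage.label(out.voxels[:, :, 0], structure=np.ones((3, 3)))
    assert n0 == 1
    np.testing.assert_array_equal(out.voxels[:, :, 1], m[:, :, 1])
    lab2, n2 = ndimage.label(out.voxels[:, :, 2], structure=np.ones((3, 3)))
    # literal rule: only the second-largest is removed; the 5-px one survives
    sizes2 = sorted(np.bincount(lab2.ravel())[1:])
    assert n2 == 2 and sizes2[0] == 5
    assert not (out.voxels & ~m).any()


def test_autocrop_bounding_box_and_margin(rng):
    vol = IntensityVolume(rng.normal(size=(64, 64, 64)).astype(np.float32))
    m = np.zeros((64, 64, 64), bool)
    m[10:21, 10:21, 10:21] = True
    out_vol, out_mask = autocrop_to_bone(vol, BinaryMask(m),
                                         PreprocessConfig(crop_margin=2))
    assert out_vol.shape == (15, 15, 15)
    assert out_mask.count() == m.sum()
    fill = vol.voxels.min()
    assert np.all(out_vol.voxels[~out_mask.voxels] == fill)
    # mask covering everything leaves shape unchanged
    full = BinaryMask(np.ones((64, 64, 64), bool))
    v2, _ = autocrop_to_bone(vol, full, PreprocessConfig(crop_margin=5))
    assert v2.shape == vol.shape


def test_zscore_values_and_idempotence():
    vol = IntensityVolume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4))
    z = zscore_normalize(vol)
    np.testing.assert_allclose(
        z.voxels.ravel(), [-1.3416, -0.4472, 0.4472, 1.3416], atol=1e-4)
    z2 = zscore_normalize(z)
    np.testing.assert_allclose(z2.voxels, z.voxels, atol=1e-5)
    with pytest.raises(ValueError):
        zscore_normalize(IntensityVolume(np.ones((2, 2, 2))))


def test_pipeline_keeps_all_bone_and_removes_foreign_structures():
    params = PhantomParams(seed=21, noise_sigma=0.0)
    vol, labels = generate_phantom(params)
    cvol, mask, clab = preprocess_pipeline(vol, PreprocessConfig(), labels)
    bone = clab.voxels > 0
    assert (mask.voxels & bone).sum() == bone.sum()          # 100% recall
    assert abs(float(cvol.voxels.mean())) < 1e-4
    assert abs(float(cvol.voxels.std()) - 1.0) < 1e-4
    # fibula and holder must be gone from the full-frame mask
    from dbahnet import (keep_largest_component_3d, otsu_threshold_with_margin,
                         remove_fibula_per_slice)
    fib, hold = phantom_foreign_masks(params)
    m = remove_fibula_per_slice(keep_largest_component_3d(
        otsu_threshold_with_margin(vol, PreprocessConfig())))
    assert (m.voxels & fib).sum() == 0
    assert (m.voxels & hold).sum() == 0


def test_pipeline_noisy_recall_above_99(noisy_phantom):
    _, vol, labels = noisy_phantom
    _, mask, clab = preprocess_pipeline(vol, PreprocessConfig(), labels)
    bone = clab.voxels > 0
    assert (mask.voxels & bone).sum() / bone.sum() >= 0.99


def test_all_background_volume_fails_at_threshold_stage():
    vol = IntensityVolume(np.zeros((8, 8, 8), np.float32))
    with pytest.raises(ValueError):
        preprocess_pipeline(vol, PreprocessConfig())
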