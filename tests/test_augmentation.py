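"""Live augmentation transforms: formulas, joint geometry, determinism."""

import numpy as np
import pytest

from dbahnet import (AugmentConfig, IntensityVolume, LabelMap, Sample,
                     add_gaussian_noise, adjust_contrast, apply_augmentations,
                     elastic_deform, random_affine, scale_intensity)


def make_sample(rng, shape=(24, 24, 12)):
    img = rng.normal(size=shape).astype(np.float32)
    lab = (rng.random(shape) < 0.3).astype(np.uint8)
    lab[rng.random(shape) < 0.1] = 2
    return Sample(IntensityVolume(img, (5, 5, 5), "z-scored"),
                  LabelMap(lab, (5, 5, 5)))


def centered_sphere_sample(shape=(32, 32, 32), radius=8):
    c = (np.asarray(shape) - 1) / 2
    grid = np.indices(shape).astype(np.float32)
    r = np.sqrt(((grid - c[:, None, None, None]) ** 2).sum(axis=0))
    lab = (r < radius).astype(np.uint8)
    img = np.where(lab, 1.0, -1.0).astype(np.float32)
    return Sample(IntensityVolume(img, (5, 5, 5), "z-scored"), LabelMap(lab))


def test_affine_identity_parameters_are_bit_exact(rng):
    s = make_sample(rng)
    out = random_affine(s, AugmentConfig(), rng, angle=0.0, scale=1.0)
    np.testing.assert_array_equal(out.image.voxels, s.image.voxels)
    np.testing.assert_array_equal(out.labels.voxels, s.labels.voxels)


def test_affine_half_turn_matches_index_flip(rng):
    s = make_sample(rng, shape=(21, 21, 5))
    out = random_affine(s, AugmentConfig(), rng, angle=np.pi, scale=1.0)
    flipped = s.image.voxels[::-1, ::-1, :]
    # the outermost ring can fall out of bounds by float rounding; compare
    # the interior
    core = (slice(1, -1), slice(1, -1), slice(None))
    np.testing.assert_allclose(out.image.voxels[core], flipped[core], atol=1e-3)
    np.testing.assert_array_equal(out.labels.voxels[core],
                                  s.labels.voxels[::-1, ::-1, :][core])


def test_affine_scaling_grows_label_volume_cubically(rng):
    s = centered_sphere_sample()
    out = random_affine(s, AugmentConfig(), rng, angle=0.0, scale=1.25)
    # in-plane (x, y) scaling only happens via the full 3D matrix; a z-axis
    # rotation with isotropic scale enlarges the sphere in x and y and z
    ratio = out.labels.voxels.sum() / s.labels.voxels.sum()
    assert ratio == pytest.approx(1.25 ** 3, rel=0.05)


def test_elastic_zero_magnitude_is_identity(rng):
    s = make_sample(rng)
    out = elastic_deform(s, AugmentConfig(), rng, alpha=0.0)
    np.testing.assert_array_equal(out.image.voxels, s.image.voxels)


def test_elastic_deterministic_and_label_preserving(rng):
    s = make_sample(rng)
    a = elastic_deform(s, AugmentConfig(), np.random.default_rng(5))
    b = elastic_deform(s, AugmentConfig(), np.random.default_rng(5))
    np.testing.assert_array_equal(a.image.voxels, b.image.voxels)
    assert set(np.unique(a.labels.voxels)) <= {0, 1, 2}


def test_small_elastic_deformation_roughly_conserves_foreground(rng):
    s = centered_sphere_sample()
    out = elastic_deform(s, AugmentConfig(), rng, sigma=11.0, alpha=50.0)
    before = s.labels.voxels.astype(bool).sum()
    after = out.labels.voxels.astype(bool).sum()
    assert abs(after - before) / before < 0.05


def test_noise_moments_and_label_immutability(rng):
    shape = (64, 64, 64)
    s = Sample(IntensityVolume(np.zeros(shape, np.float32)),
               LabelMap(np.zeros(shape, np.uint8)))
    out = add_gaussian_noise(s, AugmentConfig(), rng)
    n = np.prod(shape)
    se_mean = np.sqrt(0.1 / n)
    assert abs(out.image.voxels.mean()) < 3 * se_mean
    var = out.image.voxels.var()
    se_var = 0.1 * np.sqrt(2.0 / n)
    assert abs(var - 0.1) < 3 * se_var
    np.testing.assert_array_equal(out.labels.voxels, s.labels.voxels)
    zero_cfg = AugmentConfig(noise_variance=0.0)
    same = add_gaussian_noise(s, zero_cfg, rng)
    np.testing.assert_array_equal(same.image.voxels, s.image.voxels)


def test_intensity_scaling_formula(rng):
    s = make_sample(rng)
    out = scale_intensity(s, AugmentConfig(), rng, f=0.1)
    np.testing.assert_allclose(out.image.voxels, s.image.voxels * 1.1, rtol=1e-6)
    ident = scale_intensity(s, AugmentConfig(), rng, f=0.0)
    np.testing.assert_array_equal(ident.image.voxels, s.image.voxels)


def test_gamma_formula_on_rescaled_copy_and_monotonicity(rng):
    img = np.linspace(0, 2, 27, dtype=np.float32).reshape(3, 3, 3)
    s = Sample(IntensityVolume(img), LabelMap(np.zeros((3, 3, 3), np.uint8)))
    out = adjust_contrast(s, AugmentConfig(), rng, gamma=2.0)
    unit = (img - img.min()) / (img.max() - img.min())
    expected = unit ** 2 * (img.max() - img.min()) + img.min()
    np.testing.assert_allclose(out.image.voxels, expected, atol=1e-5)
    # value 0.5 on the unit scale maps to 0.25 before range restoration
    assert (0.5 ** 2) == 0.25
    flat = out.image.voxels.ravel()
    assert np.all(np.diff(flat) >= 0)          # ordering preserved
    ident = adjust_contrast(s, AugmentConfig(), rng, gamma=1.0)
    np.testing.assert_allclose(ident.image.voxels, img, atol=1e-6)


def test_apply_all_or_nothing_and_determinism(rng):
    s = make_sample(rng)
    none = apply_augmentations(s, AugmentConfig(p=0.0), np.random.default_rng(1))
    np.testing.assert_array_equal(none.image.voxels, s.image.voxels)
    a = apply_augmentations(s, AugmentConfig(p=1.0), np.random.default_rng(2))
    b = apply_augmentations(s, AugmentConfig(p=1.0), np.random.default_rng(2))
    np.testing.assert_array_equal(a.image.voxels, b.image.voxels)
    np.testing.assert_array_equal(a.labels.voxels, b.labels.voxels)
    assert not np.array_equal(a.image.voxels, s.image.voxels)


def test_transforms_preserve_shape_spacing_and_label_set(rng):
    s = make_sample(rng)
    out = apply_augmentations(s, AugmentConfig(p=1.0), np.random.default_rng(3))
    assert out.image.shape == s.image.shape
    assert out.image.spacing == s.image.spacing
    assert set(np.unique(out.labels.voxels)) <= {0, 1, 2}


def test_empirical_application_frequency(rng):
    p = 0.1
    draws = 2000
    cfg = AugmentConfig(p=p, noise_variance=0.1)
    gen = np.random.default_rng(7)
    tiny = Sample(IntensityVolume(np.zeros((2, 2, 2), np.float32)),
                  LabelMap(np.zeros((2, 2, 2), np.uint8)))
    hits = 0
    for _ in range(draws):
        out = apply_augmentations(tiny, cfg, gen)
        # on a zero image only the additive-noise transform changes voxels
        if not np.array_equal(out.image.voxels, tiny.image.voxels):
            hits += 1
    se = np.sqrt(p * (1 - p) / draws)
    assert abs(hits / draws - p) < 3 * se


def test_geometric_transform_shared_between_image_and_labels(rng):
    """Transforming a label-derived binary image must match the transformed
    labels (nearest-neighbour on both paths)."""
    s = centered_sphere_sample()
    out = random_affine(s, AugmentConfig(), rng, angle=0.7, scale=1.1)
    as_image = Sample(
        IntensityVolume(s.labels.voxels.astype(np.float32), (5, 5, 5),
                        "z-scored"),
        s.labels.copy())
    out2 = random_affine(as_image, AugmentConfig(), rng, angle=0.7, scale=1.1)
    np.testing.assert_array_equal(out.labels.voxels, out2.labels.voxels)
    # trilinear image of a binary sphere thresholded at 0.5 ~ nearest labels
    mismatch = (out2.image.voxels > 0.5) != out2.labels.voxels.astype(bool)
    assert mismatch.mean() < 0.02
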