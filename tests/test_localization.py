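"""Rule-based lung / air / spine localization."""

import numpy as np
import pytest
from scipy import ndimage

import dixonct as dx
from dixonct.localization import filter_small_2d


# ---------------------------------------------------------------- low mask

def test_low_intensity_mask_covers_lungs_and_air(noisy_run):
    run = noisy_run
    low = run.result.masks["low"]
    lungs_t = run.truth.class_mask("lungs")
    air_t = run.truth.class_mask("air")
    fat_t = run.truth.class_mask("fat")
    assert (low.voxels & lungs_t.voxels).sum() / lungs_t.count() > 0.99
    assert (low.voxels & air_t.voxels).sum() / air_t.count() > 0.99
    assert (low.voxels & fat_t.voxels).sum() / fat_t.count() < 0.02
    # low mask is a subset of the body by construction
    assert not np.any(low.voxels & ~run.result.body.voxels)


def test_low_intensity_threshold_out_of_range():
    vol = dx.ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
    body = dx.BinaryMask.from_volume(vol, np.ones((4, 4, 4), bool))
    with pytest.raises(dx.PreconditionError):
        dx.extract_low_intensity(vol, 5.0, body)


# ------------------------------------------------------------------- lungs

def test_area_filter_strictly_below_cutoff():
    """A 2D component of exactly the cutoff area is retained (strict <)."""
    mask = np.zeros((80, 60, 3), bool)
    mask[5:75, 5:55, 1] = True  # 70 x 50 = 3500 voxels
    kept = filter_small_2d(mask, 3500)
    assert kept.sum() == 3500
    mask2 = np.zeros((80, 60, 3), bool)
    mask2[5:75, 5:55, 1] = True
    mask2[5, 5, 1] = False  # 3499 voxels
    assert filter_small_2d(mask2, 3500).sum() == 0


def test_area_filter_monotone_in_cutoff():
    rng = np.random.default_rng(11)
    mask = ndimage.binary_dilation(rng.random((40, 40, 4)) > 0.9,
                                   iterations=2)
    prev = filter_small_2d(mask, 1)
    for cutoff in (5, 20, 80, 200):
        cur = filter_small_2d(mask, cutoff)
        assert not np.any(cur & ~prev)  # raising the cutoff never adds voxels
        prev = cur


def test_lungs_recovered_air_pockets_excluded(noisy_run):
    run = noisy_run
    lungs = run.result.masks["lungs"]
    lungs_t = run.truth.class_mask("lungs")
    air_t = run.truth.class_mask("air")
    assert dx.dice(lungs, lungs_t) >= 0.95
    assert not np.any(lungs.voxels & air_t.voxels)


def test_empty_low_mask_gives_empty_lungs():
    vol = dx.ImageVolume(np.ones((10, 10, 4)), (1, 1, 1))
    empty = dx.BinaryMask.from_volume(vol, np.zeros((10, 10, 4), bool))
    with pytest.warns(RuntimeWarning):
        lungs, residual = dx.segment_lungs(empty, vol)
    assert lungs.count() == 0 and residual.count() == 0


# --------------------------------------------------------------------- air

def test_air_pocket_recovered_bone_shell_excluded():
    """A 3 cm gas ellipsoid survives the erosion/regrow cycle; a 2 mm
    cortical-bone shell contributes no air voxels."""
    shape, spacing = (60, 60, 20), (1.0, 1.0, 2.0)
    vol = dx.ImageVolume(np.zeros(shape), spacing)
    xs, ys, zs = np.meshgrid(np.arange(60), np.arange(60), np.arange(20) * 2.0,
                             indexing="ij")
    pocket = ((xs - 20) ** 2 + (ys - 20) ** 2 + ((zs - 20) / 2) ** 2) <= 15 ** 2
    r = np.sqrt((xs - 45) ** 2 + (ys - 45) ** 2)
    shell = (r >= 8) & (r <= 10) & (zs >= 10) & (zs <= 30)  # 2 mm thick ring
    residual = dx.BinaryMask.from_volume(vol, pocket | shell)
    air, bone = dx.segment_air(residual)
    assert dx.dice(air, dx.BinaryMask.from_volume(vol, pocket)) >= 0.8
    assert not np.any(air.voxels & shell)
    assert np.all(bone.voxels[shell])


def test_air_empty_residual():
    vol = dx.ImageVolume(np.zeros((6, 6, 6)), (1, 1, 1))
    empty = dx.BinaryMask.from_volume(vol, np.zeros((6, 6, 6), bool))
    air, bone = dx.segment_air(empty)
    assert air.count() == 0 and bone.count() == 0


# ------------------------------------------------------------------- spine

def test_spine_prior_covers_vertebral_bodies(noise_free_run):
    run = noise_free_run
    prior = run.result.masks["prior"]
    body = run.result.body
    assert not np.any(prior.voxels & ~body.voxels)
    vb = run.truth.class_mask("spine").voxels.copy()
    # restrict to the vertebral-body column (exclude the spinous process fin)
    ys = np.nonzero(vb.any(axis=(0, 2)))[0]
    vb[:, ys.max() - 3:, :] = False
    covered = 0
    slices = 0
    for k in range(vb.shape[2]):
        if vb[:, :, k].any():
            slices += 1
            if np.all(prior.voxels[:, :, k][vb[:, :, k]]):
                covered += 1
    assert covered / slices >= 0.95


def test_spine_prior_symmetric_for_symmetric_body():
    body_vox = np.zeros((40, 30, 4), bool)
    xs, ys = np.meshgrid(np.arange(40), np.arange(30), indexing="ij")
    ellipse = ((xs - 19.5) / 18) ** 2 + ((ys - 14.5) / 13) ** 2 <= 1
    body_vox[:, :, :] = ellipse[:, :, None]
    body = dx.BinaryMask(body_vox, (1, 1, 1))
    prior = dx.build_spine_prior(body)
    np.testing.assert_array_equal(prior.voxels, prior.voxels[::-1])


def test_spine_segmentation_accuracy(noise_free_run):
    run = noise_free_run
    spine = run.result.masks["spine"]
    spine_t = run.truth.class_mask("spine")
    assert dx.dice(spine, spine_t) >= 0.7


def test_spinal_cord_removed(noise_free_run):
    """The cord (labeled high-density in truth) must stay out of the spine."""
    run = noise_free_run
    spine = run.result.masks["spine"].voxels
    spec = run.spec
    # reconstruct the cord cylinder from the phantom geometry
    X, Y, _ = run.inphase.coords_mm()
    cord_y = (spec.vb_offset_y_mm + spec.vb_radius_mm + spec.cord_gap_mm
              + spec.cord_radius_mm)
    cord = (X ** 2 + (Y - cord_y) ** 2 <= spec.cord_radius_mm ** 2) \
        & run.body_truth.voxels
    assert cord.sum() > 0
    assert (spine & cord).sum() / cord.sum() <= 0.10


def test_spine_prior_covered_by_lungs_yields_empty(noise_free_run):
    run = noise_free_run
    prior = run.result.masks["prior"]
    full = prior.replace_voxels(np.ones(prior.shape, bool))
    fatv = run.fat
    empty = prior.replace_voxels(np.zeros(prior.shape, bool))
    with pytest.warns(RuntimeWarning):
        spine = dx.segment_spine(fatv, prior, empty, full, empty, empty)
    assert spine.count() == 0


def test_cord_like_blob_removed_from_grown_mask():
    """Direct check of the cord-removal rule: a circular low-fat component
    posterior to the vertebral body is subtracted from the spine mask."""
    from dixonct.localization import _remove_cord_2d, LocalizationConfig
    shape = (40, 40, 1)
    fat_vox = np.full(shape, 160.0)
    xs, ys = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
    vb = (xs - 20) ** 2 + (ys - 15) ** 2 <= 8 ** 2
    cord = (xs - 20) ** 2 + (ys - 28) ** 2 <= 4 ** 2
    fat_vox[cord, 0] = 40.0  # low fat signal
    grown = np.zeros(shape, bool)
    grown[:, :, 0] = vb | cord
    out = _remove_cord_2d(grown, fat_vox, med=160.0,
                          config=LocalizationConfig(cord_radius_mm=6.0),
                          spacing=(1.0, 1.0, 1.0))
    assert not np.any(out[cord, 0])
    assert np.all(out[vb, 0])


# -------------------------------------------------------------- invariants

def test_masks_disjoint_and_inside_body(noisy_run):
    run = noisy_run
    lungs = run.result.masks["lungs"].voxels
    air = run.result.masks["air"].voxels
    spine = run.result.masks["spine"].voxels
    body = run.result.body.voxels
    assert not np.any(lungs & air)
    assert not np.any(lungs & spine)
    assert not np.any(air & spine)
    for m in (lungs, air, spine):
        assert not np.any(m & ~body)


def test_localization_is_deterministic(noisy_run):
    run = noisy_run
    low = run.result.masks["low"]
    lungs1, res1 = dx.segment_lungs(low, run.inphase)
    lungs2, res2 = dx.segment_lungs(low, run.inphase)
    np.testing.assert_array_equal(lungs1.voxels, lungs2.voxels)
    np.testing.assert_array_equal(res1.voxels, res2.voxels)
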