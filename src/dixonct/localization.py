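"""Rule-based partition of the mixed low-signal cluster into lungs, air and spine.

The mixed cluster of the fuzzy classification lumps together everything
with weak signal on both Dixon channels: lungs, bowel gas, solid bone
and bone marrow.  These are told apart by where they are and how big
they are rather than by intensity alone:

* lungs — large low-intensity 2D cross-sections (the per-slice area
  filter) grown into full 3D components;
* air pockets — compact low-intensity blobs surviving a morphological
  erosion that wipes out thin cortical-bone shells;
* spine — a posterior-central prior box, cleaned of air/lungs/fat,
  restricted to the fat-bright bone marrow, then grown slice-by-slice
  under intensity and distance constraints, with the spinal cord
  removed by its circular low-fat-signal cross-section.

Ribs are deliberately not segmented; they end up as a fat/high-density
mixture downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .errors import PreconditionError
from .io import BinaryMask, ImageVolume
from .morphology import ellipse_footprint_2d, ellipsoid_footprint


@dataclass
class LocalizationConfig:
    """Parameters of the rule-based localization.

    ``min_lung_area_voxels`` is the per-slice 2D area below which a
    low-intensity component cannot be lung (a raw voxel count at the
    acquisition's in-plane resolution; removal is strict ``<``).  The
    spine prior is given as fractional bands of the per-slice body
    bounding box: ``spine_posterior_band`` along the anteroposterior
    extent measured from the posterior edge, ``spine_lateral_band``
    along the left-right extent.
    """

    min_lung_area_voxels: int = 3500
    air_erosion_radius_mm: float = 2.0
    air_min_component_voxels: int = 50
    spine_posterior_band: tuple[float, float] = (0.12, 0.45)
    spine_lateral_band: tuple[float, float] = (0.35, 0.65)
    spine_opening_radius_mm: float = 3.0
    region_grow_intensity_band: float = 0.5
    region_grow_max_distance_mm: float = 15.0
    cord_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.min_lung_area_voxels < 1:
            raise PreconditionError("min_lung_area_voxels must be >= 1")
        for r in (self.air_erosion_radius_mm, self.spine_opening_radius_mm,
                  self.region_grow_max_distance_mm, self.cord_radius_mm):
            if r < 0:
                raise PreconditionError("radii must be >= 0")
        for band in (self.spine_posterior_band, self.spine_lateral_band):
            lo, hi = band
            if not (0 <= lo <= hi <= 1):
                raise PreconditionError("fractional bands must be ordered within [0, 1]")


def extract_low_intensity(inphase: ImageVolume, otsu_threshold: float,
                          body: BinaryMask) -> BinaryMask:
    """Body voxels whose in-phase intensity falls below the Otsu threshold.

    These belong mostly to lungs, air pockets, or solid bone.
    """
    vox = inphase.voxels
    if not (vox.min() <= otsu_threshold <= vox.max()):
        raise PreconditionError(
            f"threshold {otsu_threshold} outside intensity range "
            f"[{vox.min()}, {vox.max()}]")
    return body.replace_voxels(body.voxels & (vox < otsu_threshold))


def filter_small_2d(mask: np.ndarray, min_area_voxels: int) -> np.ndarray:
    """Remove, per axial slice, 2D components with area strictly below the cutoff."""
    out = np.zeros_like(mask, dtype=bool)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area_voxels) + 1
        if keep.size:
            out[:, :, k] = np.isin(labels, keep)
    return out


def segment_lungs(low_mask: BinaryMask, inphase: ImageVolume,
                  config: LocalizationConfig | None = None):
    """Identify the lungs inside the low-intensity mask.

    Per-slice components smaller than ``min_lung_area_voxels`` (air
    pockets, bone) are removed; what survives seeds a 3D growth over the
    low-intensity band — realized as the union of 3D connected components
    of the low mask that contain surviving voxels — followed by closing
    and hole filling.  Returns ``(lungs, residual_low)`` where
    ``residual_low`` is the low mask with the lungs removed.
    """
    config = config or LocalizationConfig()
    low = low_mask.voxels
    candidates = filter_small_2d(low, config.min_lung_area_voxels)
    if not candidates.any():
        warnings.warn("no lung candidate survived the 2D area filter; "
                      "returning empty lungs", RuntimeWarning)
        return (low_mask.replace_voxels(np.zeros_like(low)),
                low_mask.replace_voxels(low.copy()))

    labels, n = ndimage.label(low)
    seed_labels = np.unique(labels[candidates])
    seed_labels = seed_labels[seed_labels > 0]
    lungs = np.isin(labels, seed_labels)

    footprint = ellipsoid_footprint(2.0, low_mask.spacing)
    lungs = ndimage.binary_closing(lungs, structure=footprint)
    lungs = ndimage.binary_fill_holes(lungs)
    lungs &= low  # growth and cleanup stay within the low-intensity band
    residual = low & ~lungs
    return low_mask.replace_voxels(lungs), low_mask.replace_voxels(residual)


def segment_air(residual_low: BinaryMask,
                config: LocalizationConfig | None = None):
    """Separate bulk air pockets from thin solid bone in the residual mask.

    Erosion removes structures thinner than ``air_erosion_radius_mm``
    (mostly cortical bone shells); the survivors are grown back within the
    residual mask to reconstitute whole pockets, then cleaned by opening
    and small-component removal.  Returns ``(air, bone_candidates)`` with
    ``bone_candidates`` the residual voxels not claimed as air.
    """
    config = config or LocalizationConfig()
    residual = residual_low.voxels
    empty = residual_low.replace_voxels(np.zeros_like(residual))
    if not residual.any():
        return empty, empty.replace_voxels(np.zeros_like(residual))

    footprint = ellipsoid_footprint(config.air_erosion_radius_mm, residual_low.spacing)
    seeds = ndimage.binary_erosion(residual, structure=footprint)
    if not seeds.any():
        return empty, residual_low.replace_voxels(residual.copy())

    air = ndimage.binary_propagation(seeds, mask=residual)
    air = ndimage.binary_opening(air, structure=footprint)
    labels, n = ndimage.label(air)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= config.air_min_component_voxels) + 1
        air = np.isin(labels, keep)
    bone = residual & ~air
    return residual_low.replace_voxels(air), residual_low.replace_voxels(bone)


def build_spine_prior(body: BinaryMask,
                      config: LocalizationConfig | None = None) -> BinaryMask:
    """Posterior-central box prior for the spine, per axial slice.

    For each slice, the band ``spine_posterior_band`` of the body bounding
    box measured from the posterior edge is intersected with the central
    ``spine_lateral_band`` of the left-right extent and with the body.
    """
    config = config or LocalizationConfig()
    if body.count() == 0:
        raise PreconditionError("body mask is empty")
    bvox = body.voxels
    prior = np.zeros_like(bvox)
    p_lo, p_hi = config.spine_posterior_band
    l_lo, l_hi = config.spine_lateral_band
    for k in range(bvox.shape[2]):
        sl = bvox[:, :, k]
        if not sl.any():
            continue
        xs, ys = np.nonzero(sl)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
        xext, yext = x1 - x0, y1 - y0
        # posterior = +y in the canonical frame, so the posterior edge is y1
        ya = y1 - p_hi * yext
        yb = y1 - p_lo * yext
        xa = x0 + l_lo * xext
        xb = x0 + l_hi * xext
        box = np.zeros_like(sl)
        xi = np.arange(sl.shape[0])[:, None]
        yi = np.arange(sl.shape[1])[None, :]
        box = (xi >= xa) & (xi <= xb) & (yi >= ya) & (yi <= yb)
        prior[:, :, k] = box & sl
    return body.replace_voxels(prior)


def _marrow_mask(fat_vox, prior, air, lungs, fat_mask, config, spacing):
    """Step (a): prior minus air/lungs/fat, marrow-bright selection, 2D opening."""
    marrow = prior & ~(air | lungs | fat_mask)
    if not marrow.any():
        return marrow
    # Bone marrow is bright on the fat channel relative to the muscle and
    # organ tissue sharing the prior box; an Otsu split of the fat-channel
    # intensities inside the candidate mask isolates it.  The split is only
    # applied when it actually separates two populations.
    vals = fat_vox[marrow]
    if np.unique(vals).size > 2:
        thr = threshold_otsu(vals, nbins=128)
        lo, hi = vals[vals < thr], vals[vals >= thr]
        if lo.size and hi.size and hi.mean() > 1.5 * max(lo.mean(), 1e-12):
            marrow &= fat_vox >= thr
    fp = ellipse_footprint_2d(config.spine_opening_radius_mm, spacing[:2])
    opened = np.zeros_like(marrow)
    for k in range(marrow.shape[2]):
        sl = marrow[:, :, k]
        if not sl.any():
            continue
        sl_open = ndimage.binary_opening(sl, structure=fp)
        if not sl_open.any():
            continue
        # keep components overlapping the prior's center column
        pr = prior[:, :, k]
        if pr.any():
            xc = 0.5 * (np.nonzero(pr)[0].min() + np.nonzero(pr)[0].max())
        else:
            xc = 0.5 * sl.shape[0]
        labels, n = ndimage.label(sl_open)
        keep = np.zeros_like(sl_open)
        half = max(2.0, 5.0 / spacing[0])  # tolerance around the center column
        for lab in range(1, n + 1):
            xs = np.nonzero(labels == lab)[0]
            if np.any(np.abs(xs - xc) <= half):
                keep |= labels == lab
        opened[:, :, k] = keep
    return opened


def _remove_cord_2d(grown, fat_vox, med, config, spacing):
    """Step (c): subtract the per-slice circular low-fat-signal cord."""
    band = config.region_grow_intensity_band
    pix_area = spacing[0] * spacing[1]
    max_area = np.pi * config.cord_radius_mm ** 2 / pix_area * 1.2
    search_fp = ellipse_footprint_2d(2.0 * config.cord_radius_mm, spacing[:2])
    out = grown.copy()
    for k in range(grown.shape[2]):
        sl = grown[:, :, k]
        if not sl.any():
            continue
        ys_sl = np.nonzero(sl)[1]
        vb_y = ys_sl.mean()
        region = ndimage.binary_dilation(sl, structure=search_fp)
        lowfat = region & (fat_vox[:, :, k] < med * (1.0 - band))
        if not lowfat.any():
            continue
        labels, n = ndimage.label(lowfat)
        for prop in regionprops(labels):
            if prop.area > max_area:
                continue
            perim = max(prop.perimeter, 1e-9)
            circularity = 4.0 * np.pi * prop.area / perim ** 2
            if circularity < 0.6:
                continue
            if prop.centroid[1] <= vb_y:  # must be posterior to the vertebral body
                continue
            out[:, :, k] &= labels != prop.label
    return out


def segment_spine(fat: ImageVolume, prior: BinaryMask, air: BinaryMask,
                  lungs: BinaryMask, fat_mask: BinaryMask,
                  bone_candidates: BinaryMask,
                  config: LocalizationConfig | None = None,
                  body: BinaryMask | None = None) -> BinaryMask:
    """Spine segmentation from the fat channel and the prior box.

    (a) marrow mask: prior minus air/lungs/fat, restricted to fat-bright
    voxels, opened in 2D, keeping components near the prior's center
    column; (b) per-slice region growing from marrow and from solid-bone
    candidates inside the prior, accepting voxels whose fat-channel
    intensity lies within ``region_grow_intensity_band`` of the seed
    median and within ``region_grow_max_distance_mm`` of a seed;
    (c) spinal-cord removal by its circular low-fat cross-section
    posterior to the vertebral-body centroid; (d) largest 3D component,
    hole-filled.
    """
    config = config or LocalizationConfig()
    grids = {prior.grid(), air.grid(), lungs.grid(), fat_mask.grid(),
             bone_candidates.grid(), (fat.shape, fat.spacing, fat.origin, fat.direction)}
    if len(grids) != 1:
        raise PreconditionError("all masks and the fat volume must share one grid")
    spacing = fat.spacing
    fat_vox = fat.voxels
    empty = prior.replace_voxels(np.zeros(prior.shape, dtype=bool))

    marrow = _marrow_mask(fat_vox, prior.voxels, air.voxels, lungs.voxels,
                          fat_mask.voxels, config, spacing)
    seeds = marrow | (bone_candidates.voxels & prior.voxels)
    if not seeds.any():
        warnings.warn("spine prior left no marrow/bone seeds; returning empty spine",
                      RuntimeWarning)
        return empty

    med = float(np.median(fat_vox[seeds]))
    band = config.region_grow_intensity_band
    lo_i, hi_i = med * (1.0 - band), med * (1.0 + band)
    allowed = ~(air.voxels | lungs.voxels | fat_mask.voxels)
    if body is not None:
        allowed &= body.voxels

    grown = np.zeros_like(seeds)
    for k in range(seeds.shape[2]):
        seed_sl = seeds[:, :, k]
        if not seed_sl.any():
            continue
        dist = ndimage.distance_transform_edt(~seed_sl, sampling=spacing[:2])
        cand = (allowed[:, :, k] & (fat_vox[:, :, k] >= lo_i)
                & (fat_vox[:, :, k] <= hi_i)
                & (dist <= config.region_grow_max_distance_mm))
        cand |= seed_sl
        grown[:, :, k] = ndimage.binary_propagation(seed_sl, mask=cand)

    grown = _remove_cord_2d(grown, fat_vox, med, config, spacing)

    labels, n = ndimage.label(grown)
    if n == 0:
        warnings.warn("spine growth produced no voxels; returning empty spine",
                      RuntimeWarning)
        return empty
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    spine = labels == (int(np.argmax(sizes)) + 1)
    spine = ndimage.binary_fill_holes(spine)
    spine &= allowed  # hole filling must not claim air/lung/fat voxels
    return prior.replace_voxels(spine)
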