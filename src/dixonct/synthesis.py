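"""Five-class probability maps, population-HU assignment, and synthetic CT.

Each tissue class carries a single population-based Hounsfield unit;
the synthetic CT is the membership-weighted sum of these values, so the
HU at a voxel is a convex combination of the class table (bulk density
assignment with soft class boundaries).  A crisp variant assigns each
voxel the HU of its label, which is what a defuzzified or a manually
contoured segmentation produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DixonCTError, PreconditionError
from .fcm import CODE_TO_CLASS, FIVE_CLASSES, LabelMap, MembershipMaps
from .io import BinaryMask, ImageVolume


@dataclass
class HuTable:
    """Population-based Hounsfield units per tissue class.

    Defaults are abdominal population values: air −1000, lungs −708,
    fat −89, high-density tissue 39, spine 354.  Voxels outside the body
    default to air.
    """

    air: float = -1000.0
    lungs: float = -708.0
    fat: float = -89.0
    high_density: float = 39.0
    spine: float = 354.0
    background_hu: float = -1000.0

    def __post_init__(self) -> None:
        for name in FIVE_CLASSES + ("background_hu",):
            v = getattr(self, name if name != "background_hu" else "background_hu")
            if not np.isfinite(v):
                raise PreconditionError(f"HU for {name} must be finite")

    def value(self, class_name: str) -> float:
        return float(getattr(self, class_name))

    def as_dict(self) -> dict[str, float]:
        d = {name: self.value(name) for name in FIVE_CLASSES}
        d["background"] = float(self.background_hu)
        return d


@dataclass
class SyntheticCT:
    """An HU-valued volume plus the provenance of its values."""

    volume: ImageVolume
    provenance: str  # "probability-weighted" | "crisp-bulk"


def refine_to_five_classes(memberships3: MembershipMaps, cluster_labels: dict[int, str],
                           lungs: BinaryMask, air: BinaryMask,
                           spine: BinaryMask) -> MembershipMaps:
    """Expand the three-cluster partition into five tissue classes.

    Inside the lungs/air/spine masks the corresponding class membership is
    set to 1.  Elsewhere the mixed low-signal membership mass is
    redistributed to fat and high-density tissue proportionally to their
    existing memberships (split equally when both are zero), which realizes
    the treatment of unresolved low-signal tissue such as ribs as a
    fat/high-density mixture.  Total membership mass per voxel is conserved.
    """
    masks = {"lungs": lungs.voxels, "air": air.voxels, "spine": spine.voxels}
    pairs = [("lungs", "air"), ("lungs", "spine"), ("air", "spine")]
    for a, b in pairs:
        if (masks[a] & masks[b]).any():
            raise PreconditionError(f"masks '{a}' and '{b}' overlap")
    domain = memberships3.domain
    for name, m in masks.items():
        if (m & ~domain.voxels).any():
            raise PreconditionError(f"mask '{name}' extends outside the membership domain")

    by_name = {cluster_labels[i]: memberships3.maps[i] for i in cluster_labels}
    fat_m = by_name["fat"].copy()
    hd_m = by_name["high_density"].copy()
    mixed = by_name["mixed_low_signal"]

    denom = fat_m + hd_m
    inside = domain.voxels
    prop = inside & (denom > 0)
    even = inside & (denom == 0)
    fat_m[prop] += mixed[prop] * fat_m[prop] / denom[prop]
    hd_m[prop] += mixed[prop] * hd_m[prop] / denom[prop]
    fat_m[even] += 0.5 * mixed[even]
    hd_m[even] += 0.5 * mixed[even]

    maps = np.zeros((5,) + domain.shape)
    maps[FIVE_CLASSES.index("fat")] = fat_m
    maps[FIVE_CLASSES.index("high_density")] = hd_m
    for name in ("air", "lungs", "spine"):
        j = FIVE_CLASSES.index(name)
        m = masks[name]
        maps[:, m] = 0.0
        maps[j][m] = 1.0
    maps[:, ~inside] = 0.0
    return MembershipMaps(FIVE_CLASSES, maps, domain)


def synthesize_ct(memberships5: MembershipMaps, hu: HuTable | None = None,
                  body: BinaryMask | None = None) -> SyntheticCT:
    """Probability-weighted synthetic CT: HU(k) = sum_j u_jk * HU_j.

    Voxels outside ``body`` (the membership domain when no body is given)
    receive ``background_hu``.  Values are convex combinations of the
    table, hence bounded by its extremes.
    """
    hu = hu or HuTable()
    memberships5.validate()
    if set(memberships5.classes) != set(FIVE_CLASSES):
        raise PreconditionError("five-class memberships required")
    weights = np.array([hu.value(c) for c in memberships5.classes])
    ct = np.tensordot(weights, memberships5.maps, axes=(0, 0))
    inside = body.voxels if body is not None else memberships5.domain.voxels
    ct[~inside] = hu.background_hu
    dom = memberships5.domain
    vol = ImageVolume(ct, dom.spacing, dom.origin, dom.direction)
    return SyntheticCT(vol, "probability-weighted")


def bulk_ct_from_labels(labels: LabelMap, hu: HuTable | None = None) -> SyntheticCT:
    """Crisp bulk-density CT: each voxel gets the HU of its class label."""
    hu = hu or HuTable()
    lab = labels.labels
    known = set(CODE_TO_CLASS)
    present = set(np.unique(lab).tolist())
    unknown = present - known
    if unknown:
        raise DixonCTError(f"unknown label codes: {sorted(unknown)}")
    lut = np.full(max(known) + 1, hu.background_hu)
    for code, name in CODE_TO_CLASS.items():
        lut[code] = hu.background_hu if name == "background" else hu.value(name)
    vol = ImageVolume(lut[lab], labels.spacing, labels.origin, labels.direction)
    return SyntheticCT(vol, "crisp-bulk")


def expand_margin(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Spacing-aware Euclidean dilation: true where distance to mask <= margin.

    This is how a clinical target volume (CTV) is expanded into a planning
    target volume (PTV).  A zero margin is the identity; larger margins give
    supersets.
    """
    if margin_mm < 0:
        raise PreconditionError("margin_mm must be >= 0")
    if margin_mm == 0 or not mask.voxels.any():
        return mask.replace_voxels(mask.voxels.copy())
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
    return mask.replace_voxels(dist <= margin_mm)
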