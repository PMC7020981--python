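"""Geometric segmentation accuracy: volumes, Dice, weighted Dice, surface distances.

The overall accuracy score is a volume-weighted Dice

    S_bar = sum_i (V_i / V_T) * S_i,   V_T = sum_i V_i,

with weights taken from the ground-truth (manual) volumes so that they do
not depend on the algorithm under evaluation; S_bar is 1 for a perfect
segmentation and always lies between the smallest and largest per-class
Dice.  Surface-distance statistics (mean, SD, max in mm) are computed over
the pooled symmetric set of nearest boundary-to-boundary distances; the
max of that set is the classical symmetric Hausdorff distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DixonCTError, PreconditionError
from .fcm import CLASS_CODES, FIVE_CLASSES, LabelMap
from .io import BinaryMask


def mask_volume_cc(mask: BinaryMask) -> float:
    """Mask volume in cm^3: voxel count times voxel volume."""
    return mask.count() * mask.voxel_volume_mm3 / 1000.0


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1)."""
    if a.grid() != b.grid():
        raise PreconditionError("masks are on different grids")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def volume_ratio(auto: BinaryMask, manual: BinaryMask) -> float:
    """Volume of the automatic mask relative to the manual one."""
    vm = mask_volume_cc(manual)
    if vm == 0:
        raise PreconditionError("manual mask is empty; volume ratio undefined")
    return mask_volume_cc(auto) / vm


def _boundary_coords_mm(mask: BinaryMask) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.voxels, structure=structure, border_value=0)
    boundary = mask.voxels & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    return idx * np.asarray(mask.spacing)


def surface_distance_stats(a: BinaryMask, b: BinaryMask):
    """(mean, SD, max) in mm of pooled symmetric nearest surface distances.

    Boundary voxels of each mask are extracted; the directed nearest
    distances a→b and b→a are pooled and summarized.  SD is the population
    standard deviation of the pooled set; max equals the classical
    symmetric Hausdorff distance.
    """
    if a.grid() != b.grid():
        raise PreconditionError("masks are on different grids")
    if a.count() == 0 or b.count() == 0:
        raise PreconditionError("surface distances undefined for an empty mask")
    pa, pb = _boundary_coords_mm(a), _boundary_coords_mm(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.mean()), float(pooled.std()), float(pooled.max())


def weighted_dice(per_class) -> float:
    """Volume-weighted mean Dice over tissue segments.

    ``per_class`` is a sequence of ``(volume, dice)`` pairs; weights are
    ``V_i / sum(V_i)`` and therefore sum to 1.
    """
    per_class = list(per_class)
    vols = np.array([float(v) for v, _ in per_class])
    dices = np.array([float(s) for _, s in per_class])
    if np.any(vols < 0):
        raise PreconditionError("volumes must be >= 0")
    if np.any((dices < 0) | (dices > 1)):
        raise PreconditionError("Dice values must lie in [0, 1]")
    vt = vols.sum()
    if vt <= 0:
        raise PreconditionError("total volume is zero; weighted Dice undefined")
    return float(np.sum(vols / vt * dices))


@dataclass
class ClassRecord:
    """Per-class row of a segmentation report; distances are None when undefined."""

    class_name: str
    manual_volume_cc: float
    auto_volume_cc: float
    volume_ratio: float | None
    dice: float
    surface_mean_mm: float | None
    surface_sd_mm: float | None
    surface_max_mm: float | None


@dataclass
class SegmentationReport:
    """Per-class accuracy records plus the weighted Dice scalar."""

    records: list[ClassRecord] = field(default_factory=list)
    weighted_dice: float = float("nan")

    def record(self, class_name: str) -> ClassRecord:
        for r in self.records:
            if r.class_name == class_name:
                return r
        raise KeyError(class_name)

    def to_dict(self) -> dict:
        return {
            "classes": {r.class_name: {
                "manual_volume_cc": r.manual_volume_cc,
                "auto_volume_cc": r.auto_volume_cc,
                "volume_ratio": r.volume_ratio,
                "dice": r.dice,
                "surface_mean_mm": r.surface_mean_mm,
                "surface_sd_mm": r.surface_sd_mm,
                "surface_max_mm": r.surface_max_mm,
            } for r in self.records},
            "weighted_dice": self.weighted_dice,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        lines = [f"{'Class':<14}{'V_man(cc)':>10}{'V_auto(cc)':>11}{'Ratio':>8}"
                 f"{'Dice':>8}{'Surf mean±SD (max) mm':>24}"]
        for r in self.records:
            ratio = f"{r.volume_ratio:.2f}" if r.volume_ratio is not None else "n/a"
            if r.surface_mean_mm is None:
                surf = "n/a"
            else:
                surf = (f"{r.surface_mean_mm:.1f}±{r.surface_sd_mm:.1f} "
                        f"({r.surface_max_mm:.1f})")
            lines.append(f"{r.class_name:<14}{r.manual_volume_cc:>10.1f}"
                         f"{r.auto_volume_cc:>11.1f}{ratio:>8}{r.dice:>8.3f}{surf:>24}")
        lines.append(f"Weighted Dice: {self.weighted_dice:.3f}")
        return "\n".join(lines)


def build_report(auto: LabelMap, manual: LabelMap) -> SegmentationReport:
    """Compare an automatic five-class label map against a manual one.

    Per class: manual and auto volumes, volume ratio (None when the manual
    class is empty), Dice, and surface-distance statistics (None when
    either mask is empty).  The weighted Dice uses manual volumes as V_i.
    """
    if auto.grid() != manual.grid():
        raise PreconditionError(
            f"label maps on different grids: {auto.grid()} vs {manual.grid()}")
    for lm, tag in ((auto, "auto"), (manual, "manual")):
        bad = set(np.unique(lm.labels).tolist()) - set(CLASS_CODES.values())
        if bad:
            raise DixonCTError(f"{tag} label map has unknown codes: {sorted(bad)}")

    report = SegmentationReport()
    pairs = []
    for name in FIVE_CLASSES:
        am = auto.class_mask(name)
        mm = manual.class_mask(name)
        v_auto = mask_volume_cc(am)
        v_man = mask_volume_cc(mm)
        ratio = (v_auto / v_man) if v_man > 0 else None
        d = dice(am, mm)
        if am.count() and mm.count():
            smean, ssd, smax = surface_distance_stats(am, mm)
        else:
            smean = ssd = smax = None
        report.records.append(ClassRecord(name, v_man, v_auto, ratio, d,
                                          smean, ssd, smax))
        pairs.append((v_man, d))
    report.weighted_dice = weighted_dice(pairs)
    return report
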