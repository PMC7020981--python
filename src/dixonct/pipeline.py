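"""End-to-end orchestration: preprocess → cluster → localize → synthesize.

Stage order: provisional body mask (for the bias-field support), N4 on
each channel, difference image, edge-preserving denoising of all four
volumes, final body mask + Otsu threshold, three-cluster FCM on the
difference image, low-intensity extraction, lung / air / spine
localization, five-class refinement, probability-weighted synthetic CT
and defuzzified label map.  A run manifest (config, seed, versions) is
always written when an output directory is given; intermediates are
written on request.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import CohortError, PipelineStageError
from .evaluation import SegmentationReport, build_report
from .fcm import (FcmConfig, LabelMap, MembershipMaps, defuzzify, fcm_cluster,
                  label_clusters)
from .io import (BinaryMask, ImageVolume, check_cohort, write_mask, write_volume)
from .localization import (LocalizationConfig, build_spine_prior,
                           extract_low_intensity, segment_air, segment_lungs,
                           segment_spine)
from .preprocess import (PreprocessConfig, compute_difference_image,
                         correct_bias_field, denoise, segment_body)
from .synthesis import HuTable, SyntheticCT, refine_to_five_classes, synthesize_ct

logger = logging.getLogger("dixonct")


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcm: FcmConfig = field(default_factory=FcmConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    hu_table: HuTable = field(default_factory=HuTable)
    output_dir: str | None = None
    save_intermediates: bool = False
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        if "preprocess" in d:
            kwargs["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "fcm" in d:
            kwargs["fcm"] = FcmConfig(**d["fcm"])
        if "localization" in d:
            loc = dict(d["localization"])
            for key in ("spine_posterior_band", "spine_lateral_band"):
                if key in loc:
                    loc[key] = tuple(loc[key])
            kwargs["localization"] = LocalizationConfig(**loc)
        if "hu_table" in d:
            kwargs["hu_table"] = HuTable(**d["hu_table"])
        for key in ("output_dir", "save_intermediates", "log_level", "seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    ct: SyntheticCT
    labels: LabelMap
    memberships5: MembershipMaps
    body: BinaryMask
    otsu_threshold: float
    centroids: np.ndarray
    masks: dict[str, BinaryMask]
    dmri: ImageVolume


def _manifest(config: PipelineConfig) -> dict:
    import scipy
    import skimage
    import SimpleITK

    return {
        "package": {"dixonct": __version__},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "SimpleITK": SimpleITK.__version__ if hasattr(SimpleITK, "__version__")
            else SimpleITK.Version_VersionString(),
        },
        "seed": config.seed,
        "config": config.to_dict(),
    }


def run_pipeline(inphase: ImageVolume, fat: ImageVolume, water: ImageVolume,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic-CT pipeline on one mDixon cohort."""
    config = config or PipelineConfig()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))

    check_cohort(inphase, fat, water)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except CohortError:
            raise
        except Exception as e:
            raise PipelineStageError(f"stage '{name}' failed: {e}") from e
        return result

    pp = config.preprocess

    # Provisional body mask on the raw in-phase image: N4 estimates its
    # field inside the skin surface, which is not known yet at this point.
    body0, _ = stage("body-mask(provisional)", segment_body, inphase, pp)
    logger.info("provisional body mask: %d voxels", body0.count())

    def n4(vol, tag):
        # log-domain bias estimation needs positive intensities; the noise
        # floor of near-zero MR magnitude data is clipped to a small value
        clipped = vol.like(np.clip(vol.voxels, 1e-2, None))
        corrected, _ = stage(f"bias-correction({tag})", correct_bias_field,
                             clipped, body0, pp)
        return corrected

    inphase_c = n4(inphase, "inphase")
    fat_c = n4(fat, "fat")
    water_c = n4(water, "water")

    dmri = stage("difference-image", compute_difference_image, fat_c, water_c)
    inphase_d = stage("denoise(inphase)", denoise, inphase_c, pp, body0)
    fat_d = stage("denoise(fat)", denoise, fat_c, pp, body0)
    water_d = stage("denoise(water)", denoise, water_c, pp, body0)
    dmri_d = stage("denoise(dmri)", denoise, dmri, pp, body0)

    body, otsu_thr = stage("body-mask", segment_body, inphase_d, pp)
    logger.info("body mask: %d voxels, Otsu threshold %.2f", body.count(), otsu_thr)

    fcm_res = stage("fcm", fcm_cluster, dmri_d, body, config.fcm)
    cluster_names = stage("cluster-labeling", label_clusters, fcm_res.centroids)
    logger.info("FCM centroids: %s -> %s",
                np.round(fcm_res.centroids, 2).tolist(), cluster_names)

    crisp3 = np.argmax(fcm_res.memberships.maps, axis=0)
    fat_idx = next(i for i, n in cluster_names.items() if n == "fat")
    fat_mask = body.replace_voxels(body.voxels & (crisp3 == fat_idx))

    low = stage("low-intensity", extract_low_intensity, inphase_d, otsu_thr, body)
    logger.info("low-intensity mask: %d voxels", low.count())
    lungs, residual = stage("lungs", segment_lungs, low, inphase_d,
                            config.localization)
    logger.info("lungs: %d voxels", lungs.count())
    air, bone_cand = stage("air", segment_air, residual, config.localization)
    logger.info("air: %d voxels; bone candidates: %d", air.count(), bone_cand.count())
    prior = stage("spine-prior", build_spine_prior, body, config.localization)
    spine = stage("spine", segment_spine, fat_d, prior, air, lungs, fat_mask,
                  bone_cand, config.localization, body)
    logger.info("spine: %d voxels", spine.count())

    # the three masks must be pairwise disjoint before class refinement
    air = air.replace_voxels(air.voxels & ~lungs.voxels)
    spine = spine.replace_voxels(spine.voxels & ~(air.voxels | lungs.voxels))

    m5 = stage("five-class-refinement", refine_to_five_classes,
               fcm_res.memberships, cluster_names, lungs, air, spine)
    ct = stage("hu-synthesis", synthesize_ct, m5, config.hu_table, body)
    labels = stage("defuzzify", defuzzify, m5)

    result = PipelineResult(ct, labels, m5, body, otsu_thr, fcm_res.centroids,
                            {"lungs": lungs, "air": air, "spine": spine,
                             "fat": fat_mask, "low": low, "prior": prior,
                             "bone_candidates": bone_cand},
                            dmri_d)
    if out_dir is not None:
        write_volume(ct.volume, out_dir / "synthetic_ct.nii.gz")
        _write_labels(labels, out_dir / "labels.nii.gz")
        if config.save_intermediates:
            write_mask(body, out_dir / "body.nii.gz")
            write_volume(dmri_d, out_dir / "dmri.nii.gz")
            for name, mask in result.masks.items():
                write_mask(mask, out_dir / f"mask_{name}.nii.gz")
            for j, cname in enumerate(m5.classes):
                write_volume(ImageVolume(m5.maps[j], body.spacing, body.origin,
                                         body.direction),
                             out_dir / f"membership_{cname}.nii.gz")
    return result


def _write_labels(labels: LabelMap, path) -> None:
    from .fcm import CLASS_CODES
    write_volume(ImageVolume(labels.labels, labels.spacing, labels.origin,
                             labels.direction), path, dtype=np.uint8)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_codes.json")
    sidecar.write_text(json.dumps(CLASS_CODES, indent=2))


def evaluate_labels(auto: LabelMap, manual: LabelMap,
                    out_path=None) -> SegmentationReport:
    """Compare an automatic label map against a manual one; optionally write
    the report as JSON plus a human-readable table."""
    report = build_report(auto, manual)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.write_text(report.to_json(), encoding="utf-8")
        out_path.with_suffix(".txt").write_text(report.to_table() + "\n",
                                                encoding="utf-8")
    return report
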