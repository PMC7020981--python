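"""Shared fixtures: phantom runs reused across the suite.

The full-size phantom pipeline runs (noise-free and noisy) are session
scoped because several modules probe the same end-to-end result; the
small-phantom factory exists for tests that need many independent runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import dixonct as dx


@dataclass
class RunBundle:
    spec: dx.PhantomSpec
    inphase: dx.ImageVolume
    fat: dx.ImageVolume
    water: dx.ImageVolume
    truth: dx.LabelMap
    body_truth: dx.BinaryMask
    result: dx.PipelineResult
    report: dx.SegmentationReport


def fast_config(scale: float = 0.5) -> dx.PipelineConfig:
    """A cheaper configuration for geometrically shrunken phantoms.

    The per-slice lung area cutoff is a raw voxel count at the reference
    in-plane resolution, so it scales with the square of the geometric
    scale factor.
    """
    return dx.PipelineConfig(
        preprocess=dx.PreprocessConfig(n4_iterations=[10, 10], diffusion_iterations=2),
        fcm=dx.FcmConfig(max_iterations=80),
        localization=dx.LocalizationConfig(
            min_lung_area_voxels=max(1, int(3500 * scale ** 2))),
    )


def run_phantom(spec: dx.PhantomSpec, seed: int,
                config: dx.PipelineConfig | None = None) -> RunBundle:
    inphase, fat, water, truth, body = dx.generate_phantom(spec, seed)
    result = dx.run_pipeline(inphase, fat, water, config)
    report = dx.evaluate_labels(result.labels, truth)
    return RunBundle(spec, inphase, fat, water, truth, body, result, report)


@pytest.fixture(scope="session")
def noise_free_run() -> RunBundle:
    return run_phantom(dx.phantom.noise_free(dx.default_spec()), seed=1)


@pytest.fixture(scope="session")
def noisy_run() -> RunBundle:
    return run_phantom(dx.default_spec(), seed=1)


@pytest.fixture(scope="session")
def small_noise_free() -> tuple:
    """A geometrically shrunken noise-free phantom (no pipeline run)."""
    spec = dx.phantom.noise_free(dx.default_spec(0.5))
    return (spec,) + dx.generate_phantom(spec, 3)
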