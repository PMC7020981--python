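"""Digital abdominal phantom emulating a single mDixon acquisition.

The phantom paints a five-class abdomen — an elliptic-cylinder body with
a subcutaneous fat shell, two lung ellipsoids in the superior part of
the volume, a posterior-central spine (vertebral-body column, spinous
process fin, spinal-cord cylinder), randomized bowel-gas ellipsoids in
the mid abdomen, and residual high-density tissue — and renders three
co-registered channels (in-phase, fat-only, water-only) from a
class-intensity table, with optional additive Gaussian noise and a
smooth multiplicative bias field.

The intensity table reproduces the contrast structure the classifier
relies on: fat bright on the fat channel, soft tissue bright on the
water channel, air/lungs near zero everywhere, and marrow with a nearly
balanced fat/water signal, so the fat-minus-water histogram inside the
body has three modes (soft tissue strongly negative, low-signal tissue
near zero, fat strongly positive).  Lung cross-sections exceed — and
bowel-gas pockets stay below — the per-slice lung area filter at the
default in-plane resolution.  The spinal cord is labeled high-density
tissue in the ground truth, because the spine class is defined with the
cord removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PreconditionError
from .fcm import CLASS_CODES, LabelMap
from .io import BinaryMask, ImageVolume

# class -> (in-phase, fat, water) channel means; code 0 is exterior air
DEFAULT_INTENSITIES: dict[str, tuple[float, float, float]] = {
    "exterior": (5.0, 3.0, 3.0),
    "air": (5.0, 3.0, 3.0),
    "lungs": (15.0, 8.0, 8.0),
    "fat": (400.0, 380.0, 40.0),
    "high_density": (380.0, 50.0, 350.0),
    "spine": (300.0, 160.0, 150.0),
}


@dataclass
class PhantomSpec:
    """Geometry, contrast, and noise of the digital phantom.

    All geometric fields are in mm; ``shape`` is in voxels with the slice
    axis last.  ``bias_field_ratio`` is the max/min ratio of the smooth
    multiplicative field (1.0 disables it); ``noise_sd`` is the SD of the
    additive Gaussian noise applied to every channel.
    """

    shape: tuple[int, int, int] = (192, 120, 36)
    spacing: tuple[float, float, float] = (1.29, 1.60, 4.0)
    body_semiaxes_mm: tuple[float, float] = (115.0, 85.0)
    fat_thickness_mm: float = 8.0
    lung_semiaxes_mm: tuple[float, float, float] = (48.0, 55.0, 40.0)
    lung_offset_mm: tuple[float, float, float] = (55.0, 0.0, 28.0)
    vb_radius_mm: float = 16.0
    vb_offset_y_mm: float = 40.0
    cord_radius_mm: float = 5.0
    cord_gap_mm: float = 2.0
    process_length_mm: float = 6.0
    process_halfwidth_mm: float = 5.0
    n_air_pockets: int = 2
    air_radius_range_mm: tuple[float, float] = (10.0, 15.0)
    intensities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 15.0
    bias_field_ratio: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        required = set(DEFAULT_INTENSITIES)
        if set(self.intensities) != required:
            raise PreconditionError(f"intensity table must cover {sorted(required)}")
        if self.noise_sd < 0:
            raise PreconditionError("noise_sd must be >= 0")
        if self.bias_field_ratio < 1:
            raise PreconditionError("bias_field_ratio must be >= 1")
        sx, sy, _ = self.spacing
        nx, ny, _ = self.shape
        ax, ay = self.body_semiaxes_mm
        if 2 * ax >= nx * sx or 2 * ay >= ny * sy:
            raise PreconditionError("body ellipse does not fit inside the grid")


def default_spec(scale: float = 1.0) -> PhantomSpec:
    """The default phantom; ``scale`` < 1 gives a geometrically shrunken
    variant (same spacing) for fast repeated runs.  Note the per-slice lung
    area scales with ``scale**2``."""
    if scale == 1.0:
        return PhantomSpec()
    s = scale
    base = PhantomSpec()
    return replace(
        base,
        shape=tuple(max(8, int(round(n * s))) for n in base.shape),
        body_semiaxes_mm=tuple(a * s for a in base.body_semiaxes_mm),
        fat_thickness_mm=max(base.fat_thickness_mm * s, 3.0),
        lung_semiaxes_mm=tuple(a * s for a in base.lung_semiaxes_mm),
        lung_offset_mm=tuple(a * s for a in base.lung_offset_mm),
        vb_radius_mm=base.vb_radius_mm * s,
        vb_offset_y_mm=base.vb_offset_y_mm * s,
        cord_radius_mm=base.cord_radius_mm * s,
        cord_gap_mm=base.cord_gap_mm * s,
        process_length_mm=base.process_length_mm * s,
        process_halfwidth_mm=base.process_halfwidth_mm * s,
        air_radius_range_mm=tuple(r * s for r in base.air_radius_range_mm),
    )


def noise_free(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom without noise and without a bias field."""
    return replace(spec, noise_sd=0.0, bias_field_ratio=1.0)


def _smooth_bias_field(shape, ratio: float, rng: np.random.Generator) -> np.ndarray:
    if ratio <= 1.0:
        return np.ones(shape)
    # a 2x2x2 coarse grid keeps the log-field trilinear, i.e. as smooth as
    # coil-sensitivity variation and representable by one cubic spline patch
    coarse = rng.normal(size=(2, 2, 2))
    zoom = [n / c for n, c in zip(shape, coarse.shape)]
    g = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    g = g - g.min()
    span = g.max() or 1.0
    g = g / span * np.log(ratio)  # exp(g) spans exactly [1, ratio]
    g = g - g.mean()
    return np.exp(g)


def generate_phantom(spec: PhantomSpec | None = None, seed: int | None = None):
    """Render the phantom.

    Returns ``(inphase, fat, water, truth, body)`` — three channel volumes,
    the ground-truth :class:`LabelMap`, and the true body mask.  The same
    spec and seed give bit-identical output.
    """
    spec = spec or PhantomSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    origin = (-(nx - 1) / 2.0 * sx, -(ny - 1) / 2.0 * sy, 0.0)
    xs = origin[0] + sx * np.arange(nx)
    ys = origin[1] + sy * np.arange(ny)
    zs = origin[2] + sz * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    z_mid = zs.mean()

    ax, ay = spec.body_semiaxes_mm
    body = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[body] = CLASS_CODES["high_density"]

    # subcutaneous fat shell: between the body ellipse and an inner ellipse
    axi, ayi = ax - spec.fat_thickness_mm, ay - spec.fat_thickness_mm
    inner = (X / axi) ** 2 + (Y / ayi) ** 2 <= 1.0
    labels[body & ~inner] = CLASS_CODES["fat"]

    # lungs: two ellipsoids mirrored in x, superior part of the volume
    lx, ly, lz = spec.lung_semiaxes_mm
    ox, oy, oz = spec.lung_offset_mm
    for sgn in (+1.0, -1.0):
        lung = ((X - sgn * ox) / lx) ** 2 + ((Y - oy) / ly) ** 2 \
            + ((Z - (z_mid + oz)) / lz) ** 2 < 1.0
        labels[lung & inner] = CLASS_CODES["lungs"]

    # spine: vertebral-body column + spinous-process fin; cord stays high-density
    vb = (X ** 2 + (Y - spec.vb_offset_y_mm) ** 2 <= spec.vb_radius_mm ** 2) & inner
    labels[vb] = CLASS_CODES["spine"]
    cord_y = spec.vb_offset_y_mm + spec.vb_radius_mm + spec.cord_gap_mm \
        + spec.cord_radius_mm
    cord = (X ** 2 + (Y - cord_y) ** 2 <= spec.cord_radius_mm ** 2) & inner
    labels[cord] = CLASS_CODES["high_density"]
    p0 = cord_y + spec.cord_radius_mm + 1.0
    process = (np.abs(X) <= spec.process_halfwidth_mm) \
        & (Y >= p0) & (Y <= p0 + spec.process_length_mm) & inner
    labels[process] = CLASS_CODES["spine"]

    # randomized bowel-gas pockets, kept clear of lungs/spine/fat by rejection
    margin = 6.0
    rmin, rmax = spec.air_radius_range_mm
    hd = CLASS_CODES["high_density"]
    placed = 0
    for _ in range(200 * max(spec.n_air_pockets, 1)):
        if placed >= spec.n_air_pockets:
            break
        cx = rng.uniform(-0.5 * ax, 0.5 * ax)
        cy = rng.uniform(-0.55 * ay, -0.15 * ay)
        cz = rng.uniform(zs[0] + 0.2 * (zs[-1] - zs[0]), zs[0] + 0.6 * (zs[-1] - zs[0]))
        rx, ry, rz = rng.uniform(rmin, rmax, size=3)
        rz = max(rz, 1.5 * sz)
        pocket = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0
        guard = ((X - cx) / (rx + margin)) ** 2 + ((Y - cy) / (ry + margin)) ** 2 \
            + ((Z - cz) / (rz + margin)) ** 2 <= 1.0
        if not pocket.any() or np.any(labels[guard] != hd):
            continue
        labels[pocket] = CLASS_CODES["air"]
        placed += 1
    if placed < spec.n_air_pockets:
        raise PreconditionError(
            f"could only place {placed}/{spec.n_air_pockets} air pockets; "
            "geometry too crowded")

    # render channels
    code_order = ["exterior", "air", "lungs", "fat", "high_density", "spine"]
    lut = {CLASS_CODES.get(n, 0): spec.intensities[n] for n in code_order}
    bias = _smooth_bias_field(spec.shape, spec.bias_field_ratio, rng)
    channels = []
    for ch in range(3):
        means = np.zeros(max(CLASS_CODES.values()) + 1)
        for code, triple in lut.items():
            means[code] = triple[ch]
        vox = means[labels] * bias
        if spec.noise_sd > 0:
            vox = vox + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        channels.append(ImageVolume(vox, spec.spacing, origin))

    truth = LabelMap(labels, spec.spacing, origin)
    body_mask = BinaryMask(body, spec.spacing, origin)
    return channels[0], channels[1], channels[2], truth, body_mask


def spherical_target(center_mm, radius_mm: float, grid) -> BinaryMask:
    """Voxelize a sphere (e.g. a clinical target volume) on ``grid``.

    ``grid`` is any object with ``shape``, ``spacing`` and ``origin``
    (an :class:`ImageVolume`, mask or label map).  A voxel is inside when
    its center lies within ``radius_mm`` of ``center_mm``.  Raises when the
    sphere does not fit inside the grid extent.
    """
    if radius_mm <= 0:
        raise PreconditionError("radius_mm must be > 0")
    center = np.asarray(center_mm, dtype=float)
    spacing = np.asarray(grid.spacing, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    shape = np.asarray(grid.shape)
    lo = origin
    hi = origin + (shape - 1) * spacing
    if np.any(center - radius_mm < lo - spacing / 2) or np.any(center + radius_mm > hi + spacing / 2):
        raise PreconditionError("sphere extends outside the grid")
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 \
        <= radius_mm ** 2
    direction = getattr(grid, "direction", (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0))
    return BinaryMask(inside, tuple(grid.spacing), tuple(grid.origin), direction)
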