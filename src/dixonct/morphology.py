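"""Spacing-aware morphological footprints shared by several stages."""

from __future__ import annotations

import numpy as np


def ellipsoid_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Boolean structuring element covering a physical ball of ``radius_mm``.

    The footprint is an ellipsoid in index space so that morphology with it
    acts isotropically in mm on anisotropic grids.  A zero radius yields the
    single-voxel identity footprint.
    """
    spacing = np.asarray(spacing, dtype=float)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm ** 2 + 1e-9


def ellipse_footprint_2d(radius_mm: float, spacing_xy) -> np.ndarray:
    """In-plane (2D) analogue of :func:`ellipsoid_footprint`."""
    return ellipsoid_footprint(radius_mm, list(spacing_xy))
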