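"""Spatially constrained fuzzy c-means clustering and defuzzification.

The difference image (fat minus water) is clustered into three tissue
classes — water-dominant high-density tissue (strongly negative),
a mixed low-signal class (air, lungs, bone marrow, solid bone; near
zero), and fat (strongly positive).  Memberships are computed only on
body voxels.  A spatial constraint regularizes the memberships each
iteration by blending every voxel's membership with the mean membership
of its cubic neighborhood, which suppresses speckle in noisy data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AmbiguityError, DegenerateInputError, PreconditionError
from .io import BinaryMask, ImageVolume

# Crisp label codes shared across the package.
CLASS_CODES: dict[str, int] = {
    "background": 0,
    "air": 1,
    "lungs": 2,
    "fat": 3,
    "high_density": 4,
    "spine": 5,
}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}
FIVE_CLASSES = ("air", "lungs", "fat", "high_density", "spine")

# Semantic names of the three primary clusters, in ascending-centroid order.
THREE_CLUSTER_NAMES = ("high_density", "mixed_low_signal", "fat")


@dataclass
class FcmConfig:
    """Fuzzy c-means parameters.

    ``spatial_weight`` (lambda) blends each membership with its neighborhood
    mean; 0 disables the constraint and recovers classic FCM.  Initialization
    is deterministic (intensity percentiles), so ``seed`` only matters if
    stochastic restarts are ever enabled.
    """

    n_clusters: int = 3
    fuzzifier_m: float = 2.0
    spatial_weight: float = 0.3
    neighborhood_radius_voxels: int = 1
    max_iterations: int = 200
    tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise PreconditionError("n_clusters must be >= 1")
        if self.fuzzifier_m <= 1:
            raise PreconditionError("fuzzifier_m must be > 1")
        if self.tolerance <= 0:
            raise PreconditionError("tolerance must be > 0")
        if self.spatial_weight < 0:
            raise PreconditionError("spatial_weight must be >= 0")


@dataclass
class MembershipMaps:
    """Per-class probability volumes over a shared grid.

    ``maps[j]`` holds the membership of every voxel in class ``classes[j]``.
    Memberships live in [0, 1], sum to 1 inside ``domain`` and are 0 outside.
    """

    classes: tuple[str, ...]
    maps: np.ndarray  # (n_classes, nx, ny, nz)
    domain: BinaryMask

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.shape[0] != len(self.classes):
            raise PreconditionError("one map per class required")
        if self.maps.shape[1:] != self.domain.shape:
            raise PreconditionError("maps and domain shapes differ")

    def validate(self, atol: float = 1e-6) -> None:
        if self.maps.min() < -atol or self.maps.max() > 1 + atol:
            raise PreconditionError("memberships outside [0, 1]")
        sums = self.maps.sum(axis=0)
        inside = self.domain.voxels
        if inside.any() and np.max(np.abs(sums[inside] - 1.0)) > atol:
            raise PreconditionError("memberships do not sum to 1 inside the domain")
        if (~inside).any() and np.max(np.abs(sums[~inside])) > atol:
            raise PreconditionError("nonzero membership outside the domain")

    def get(self, name: str) -> np.ndarray:
        return self.maps[self.classes.index(name)]


@dataclass
class LabelMap:
    """Crisp per-voxel class assignment using :data:`CLASS_CODES`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.uint8)
        if self.labels.ndim != 3:
            raise PreconditionError("label map must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = tuple(float(d) for d in self.direction)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def grid(self) -> tuple:
        return (self.shape, self.spacing, self.origin, self.direction)

    def class_mask(self, name: str) -> BinaryMask:
        return BinaryMask(self.labels == CLASS_CODES[name], self.spacing,
                          self.origin, self.direction)


@dataclass
class FcmResult:
    """Clustering output: memberships, sorted centroids, and diagnostics."""

    memberships: MembershipMaps
    centroids: np.ndarray
    objective_history: list[float]
    n_iterations: int
    converged: bool

    def __iter__(self):  # allow (memberships, centroids) unpacking
        return iter((self.memberships, self.centroids))


def _neighborhood_mean(u_flat: np.ndarray, body: np.ndarray, idx, size: int) -> np.ndarray:
    """Mean membership over the cubic neighborhood, counting body voxels only."""
    vol = np.zeros(body.shape)
    vol[idx] = u_flat
    num = ndimage.uniform_filter(vol, size=size, mode="constant")
    den = ndimage.uniform_filter(body.astype(np.float64), size=size, mode="constant")
    return num[idx] / den[idx]


def fcm_objective(x: np.ndarray, u: np.ndarray, centroids: np.ndarray, m: float) -> float:
    """The FCM objective J = sum_k sum_j u_jk^m (x_k - c_j)^2."""
    d2 = (x[:, None] - centroids[None, :]) ** 2
    return float(np.sum(u ** m * d2))


def fcm_cluster(dmri: ImageVolume, body: BinaryMask,
                config: FcmConfig | None = None) -> FcmResult:
    """Cluster body voxels of the difference image by fuzzy c-means.

    Alternating optimization of the standard FCM objective restricted to
    body voxels, with the spatial constraint applied as a post-step each
    iteration (lambda-blend with the neighborhood mean membership, then
    renormalization).  Iteration stops when the maximum membership change
    drops below ``tolerance`` or ``max_iterations`` is reached; in the
    latter case a warning is emitted and the result returned anyway.
    Centroids are returned sorted ascending, with their maps reordered to
    match.
    """
    config = config or FcmConfig()
    inside = body.voxels
    x = dmri.voxels[inside].astype(np.float64)
    if np.unique(x).size < config.n_clusters:
        raise DegenerateInputError(
            f"body contains fewer than {config.n_clusters} distinct intensities")

    c = config.n_clusters
    m = config.fuzzifier_m
    if c == 3:
        centroids = np.percentile(x, [10, 50, 90])
    else:
        q = 100.0 * (np.arange(c) + 0.5) / c
        centroids = np.percentile(x, q)
    centroids = np.sort(np.asarray(centroids, dtype=np.float64))

    scale = float(np.ptp(x)) or 1.0
    eps2 = (1e-9 * scale) ** 2
    idx = np.nonzero(inside)
    size = 2 * config.neighborhood_radius_voxels + 1
    lam = config.spatial_weight

    u = np.full((x.size, c), 1.0 / c)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        d2 = (x[:, None] - centroids[None, :]) ** 2
        # Voxels sitting (numerically) on a centroid get a crisp membership.
        on_centroid = d2.min(axis=1) < eps2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            u_new = inv / inv.sum(axis=1, keepdims=True)
        if on_centroid.any():
            rows = np.nonzero(on_centroid)[0]
            u_new[rows] = 0.0
            u_new[rows, d2[rows].argmin(axis=1)] = 1.0

        if lam > 0:
            for j in range(c):
                u_new[:, j] = (1 - lam) * u_new[:, j] + lam * _neighborhood_mean(
                    u_new[:, j], inside, idx, size)
            u_new /= u_new.sum(axis=1, keepdims=True)

        num = (u_new ** m).T @ x
        den = (u_new ** m).sum(axis=0)
        centroids = num / np.maximum(den, 1e-300)

        history.append(fcm_objective(x, u_new, centroids, m))
        delta = float(np.max(np.abs(u_new - u)))
        u = u_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FCM did not converge within {config.max_iterations} iterations",
            RuntimeWarning)

    order = np.argsort(centroids)
    centroids = centroids[order]
    maps = np.zeros((c,) + dmri.shape)
    for j_out, j_in in enumerate(order):
        maps[j_out][inside] = u[:, j_in]
    names = tuple(f"cluster_{j}" for j in range(c))
    memberships = MembershipMaps(names, maps, body)
    return FcmResult(memberships, centroids, history, it, converged)


def label_clusters(centroids) -> dict[int, str]:
    """Map the three sorted-cluster indices to semantic tissue names.

    The lowest centroid (strongly negative difference signal) is
    water-dominant high-density tissue, the middle one the mixed
    low-signal class, and the highest one fat.  The mapping is defined on
    the values, so a shuffled centroid order yields the same semantics.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size != 3:
        raise PreconditionError("exactly three centroids required")
    if np.unique(centroids).size != 3:
        raise AmbiguityError(f"tied centroids: {centroids.tolist()}")
    order = np.argsort(centroids)
    return {int(order[k]): THREE_CLUSTER_NAMES[k] for k in range(3)}


def defuzzify(memberships: MembershipMaps) -> LabelMap:
    """Maximum-membership conversion of a fuzzy partition to a crisp one.

    Every in-domain voxel receives the class of its highest membership;
    ties break toward the lowest class code; out-of-domain voxels become
    background.
    """
    memberships.validate()
    codes = [CLASS_CODES[name] for name in memberships.classes]
    order = np.argsort(codes)  # ascending code => argmax picks lowest on ties
    stacked = memberships.maps[order]
    winner = np.argmax(stacked, axis=0)
    labels = np.asarray(codes)[order][winner].astype(np.uint8)
    labels[~memberships.domain.voxels] = CLASS_CODES["background"]
    dom = memberships.domain
    return LabelMap(labels, dom.spacing, dom.origin, dom.direction)
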