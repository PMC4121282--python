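"""Prior-initialized mixture-model tissue classification and GM binarization.

The classifier assumes the image is a mixture of four tissue clusters
(GM, WM, CSF, other), each with normally distributed intensities described by
a mean, a variance and an effective voxel count. Template-space tissue priors,
mapped through the rigid registration, seed the per-voxel class probabilities;
each iteration then re-estimates the cluster statistics from the current
probabilities, evaluates the class-conditional Gaussian densities, multiplies
them into the probabilities and renormalizes so the four class memberships
sum to one at every voxel.

Transform convention: the ``m`` argument of :func:`map_priors` /
:func:`em_segment` maps *template* world coordinates onto *image* world
coordinates; priors are sampled at ``m^-1 x`` for each image voxel x. This is
the inverse of the matrix returned by ``estimate_rigid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError
from .volume_io import CLASS_NAMES, TissuePriorSet, Volume

GM, WM, CSF, OTHER = 0, 1, 2, 3


@dataclass
class SegmentationConfig:
    """Settings for :func:`em_segment`.

    tol:          stop when the mean absolute per-voxel probability change
                  falls below this (default 1e-4).
    max_iter:     iteration cap (default 30).
    sigma_floor_frac: variance floor as a fraction of the squared intensity
                  range, guarding collapsed clusters.
    mass_floor:   clusters with fewer effective voxels keep their previous
                  statistics and are flagged.
    prior_mode:   'current' multiplies densities into the current
                  probabilities (the printed update); 'initial' multiplies
                  into the fixed initial priors.
    prior_floor:  small floor applied to the initial probabilities so that a
                  zero prior is not absorbing under the multiplicative update.
    """

    tol: float = 1e-4
    max_iter: int = 30
    sigma_floor_frac: float = 1e-4
    mass_floor: float = 10.0
    prior_mode: str = "current"
    prior_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.prior_mode not in ("current", "initial"):
            raise ValueError("prior_mode must be 'current' or 'initial'")


@dataclass
class TissueProbabilities:
    """Per-voxel 4-class membership probabilities, shape (nx, ny, nz, 4)."""

    p: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 4 or self.p.shape[3] != 4:
            raise ValueError("probabilities must have shape (nx, ny, nz, 4)")

    def gray_matter(self) -> np.ndarray:
        return self.p[..., GM]


@dataclass
class ClusterStats:
    """Effective voxel counts, mean intensities and intensity variances per class."""

    m: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    low_mass: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=bool))


@dataclass
class SegmentationResult:
    probabilities: TissueProbabilities
    stats: ClusterStats
    n_iter: int
    converged: bool
    delta_trace: list[float]
    #: max per-voxel |sum_k p - 1| after each iteration (diagnostic)
    sum_dev_trace: list[float] = field(default_factory=list)


@dataclass
class BinaryGMMask:
    """Binarized gray-matter structure with the Otsu cut that produced it."""

    mask: np.ndarray
    threshold: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


def map_priors(
    priors: TissuePriorSet, m: np.ndarray, target: Volume
) -> TissueProbabilities:
    """Seed per-voxel probabilities by pulling the template priors onto the
    image grid: each prior is sampled with trilinear interpolation at
    ``m^-1 x_n`` (``m``: template -> image world coordinates), renormalized per
    voxel; voxels mapping outside the prior field get (0, 0, 0, 1)."""
    m = np.asarray(m, dtype=float)
    if abs(np.linalg.det(m)) < 1e-12:
        raise SegmentationError("singular transform")
    total = np.linalg.inv(priors.affine) @ np.linalg.inv(m) @ target.affine
    idx = np.indices(target.shape, dtype=np.float64).reshape(3, -1)
    src = total[:3, :3] @ idx + total[:3, 3:4]
    shape_arr = np.array(priors.shape, dtype=float)
    inside = np.all((src >= 0) & (src <= shape_arr[:, None] - 1), axis=0)
    out = np.empty((4,) + (idx.shape[1],))
    for k in range(4):
        out[k] = ndimage.map_coordinates(
            priors.priors[..., k], src, order=1, mode="constant", cval=0.0
        )
    out[:, ~inside] = np.array([0.0, 0.0, 0.0, 1.0])[:, None]
    p = out.T.reshape(target.shape + (4,))
    total_p = p.sum(axis=3, keepdims=True)
    empty = total_p[..., 0] <= 1e-12
    p[empty] = (0.0, 0.0, 0.0, 1.0)
    total_p = p.sum(axis=3, keepdims=True)
    return TissueProbabilities(p / total_p, target.affine.copy())


def update_cluster_stats(
    p: TissueProbabilities | np.ndarray,
    image: Volume | np.ndarray,
    prev: ClusterStats | None = None,
    sigma_floor: float = 1e-8,
    mass_floor: float = 0.0,
) -> ClusterStats:
    """Per-cluster effective count, probability-weighted mean and variance.

    ``m_k = sum_n p_nk``; ``mu_k = sum_n p_nk f_n / m_k``;
    ``sigma_k = sum_n p_nk (f_n - mu_k)^2 / m_k`` floored at ``sigma_floor``.
    Clusters with ``m_k < mass_floor`` keep the previous statistics (flagged).
    """
    parr = p.p if isinstance(p, TissueProbabilities) else np.asarray(p, dtype=float)
    f = (
        image.astype_float().reshape(-1)
        if isinstance(image, Volume)
        else np.asarray(image, dtype=float).reshape(-1)
    )
    pk = parr.reshape(-1, 4)
    if pk.shape[0] != f.size:
        raise ValueError("probability field and image have different sizes")
    m = pk.sum(axis=0)
    if np.all(m <= 0):
        raise SegmentationError("all-zero probability field")
    safe_m = np.where(m > 0, m, 1.0)
    mu = (pk * f[:, None]).sum(axis=0) / safe_m
    sigma = (pk * (f[:, None] - mu[None, :]) ** 2).sum(axis=0) / safe_m
    sigma = np.maximum(sigma, sigma_floor)
    low = m < mass_floor
    if prev is not None and np.any(low):
        mu = np.where(low, prev.mu, mu)
        sigma = np.where(low, prev.sigma, sigma)
    return ClusterStats(m=m, mu=mu, sigma=sigma, low_mass=low)


def gaussian_density(
    f: np.ndarray | float, mu: np.ndarray | float, sigma: np.ndarray | float
) -> np.ndarray | float:
    """Normal pdf with ``sigma`` interpreted as a *variance*:
    ``(2 pi sigma)^(-1/2) exp(-(f - mu)^2 / (2 sigma))``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma (variance) must be positive")
    f = np.asarray(f, dtype=float)
    out = np.exp(-((f - mu) ** 2) / (2.0 * sigma)) / np.sqrt(2.0 * np.pi * sigma)
    return out if out.ndim else float(out)


def em_segment(
    image: Volume,
    priors: TissuePriorSet,
    m: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Iterative mixture-model classification seeded by mapped tissue priors.

    Step order per iteration: cluster masses -> weighted means -> variances ->
    class-conditional Gaussian densities -> multiplicative probability update
    -> per-voxel renormalization; stops when the mean absolute probability
    change drops below ``cfg.tol`` or after ``cfg.max_iter`` iterations.

    A constant-intensity image is returned as a flagged non-converged result
    holding the initial probabilities.
    """
    cfg = cfg or SegmentationConfig()
    init = map_priors(priors, m, image)
    f = image.astype_float().reshape(-1)
    frange = float(f.max() - f.min())
    p0 = init.p.reshape(-1, 4)
    if cfg.prior_floor > 0:
        p0 = np.maximum(p0, cfg.prior_floor)
        p0 = p0 / p0.sum(axis=1, keepdims=True)
    if frange <= 0:
        return SegmentationResult(
            probabilities=TissueProbabilities(
                p0.reshape(image.shape + (4,)), image.affine.copy()
            ),
            stats=update_cluster_stats(p0, f),
            n_iter=0,
            converged=False,
            delta_trace=[],
        )
    sigma_floor = cfg.sigma_floor_frac * frange**2

    p = p0.copy()
    stats = None
    delta_trace: list[float] = []
    sum_dev_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        stats = update_cluster_stats(
            p, f, prev=stats, sigma_floor=sigma_floor, mass_floor=cfg.mass_floor
        )
        g = np.exp(-((f[:, None] - stats.mu[None, :]) ** 2) / (2.0 * stats.sigma)) / (
            np.sqrt(2.0 * np.pi * stats.sigma)
        )
        weights = p if cfg.prior_mode == "current" else p0
        q = g * weights
        total = q.sum(axis=1, keepdims=True)
        dead = total[:, 0] <= 0.0  # all densities underflowed: keep previous
        total[dead] = 1.0
        p_new = q / total
        p_new[dead] = p[dead]
        delta = float(np.mean(np.abs(p_new - p)))
        delta_trace.append(delta)
        sum_dev_trace.append(float(np.max(np.abs(p_new.sum(axis=1) - 1.0))))
        p = p_new
        if delta < cfg.tol:
            converged = True
            break
    stats = update_cluster_stats(
        p, f, prev=stats, sigma_floor=sigma_floor, mass_floor=cfg.mass_floor
    )
    return SegmentationResult(
        probabilities=TissueProbabilities(
            p.reshape(image.shape + (4,)), image.affine.copy()
        ),
        stats=stats,
        n_iter=it,
        converged=converged,
        delta_trace=delta_trace,
        sum_dev_trace=sum_dev_trace,
    )


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu cut on probability values using ``nbins`` uniform bins over [0, 1].

    Returns the bin-center threshold maximizing the between-class variance;
    ties break toward the lower threshold. Requires at least two distinct
    values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or np.all(values == values[0]):
        raise SegmentationError("cannot threshold a constant array")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("expected probability values in [0, 1]")
    counts, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    center = float(threshold_otsu(hist=(counts.astype(np.int64), centers)))
    # threshold_otsu reports the centre of the last lower-class bin; the cut
    # itself is that bin's upper edge (values at the lower mode stay below it)
    cut = int(np.argmin(np.abs(centers - center)))
    return float(edges[cut + 1])


def binarize_gray_matter(seg: SegmentationResult) -> BinaryGMMask:
    """Threshold the gray-matter probability map with Otsu's cut.

    Raises if the resulting foreground is empty (segmentation failure)."""
    gm = seg.probabilities.gray_matter()
    if float(gm.max()) <= 0.0:
        raise SegmentationError("empty gray matter: GM probability is zero everywhere")
    thr = otsu_threshold(gm)
    mask = (gm > thr).astype(np.uint8)
    if mask.sum() == 0:
        raise SegmentationError("empty gray matter after thresholding")
    return BinaryGMMask(mask=mask, threshold=thr, affine=seg.probabilities.affine.copy())


__all__ = [
    "CLASS_NAMES",
    "GM",
    "WM",
    "CSF",
    "OTHER",
    "SegmentationConfig",
    "TissueProbabilities",
    "ClusterStats",
    "SegmentationResult",
    "BinaryGMMask",
    "map_priors",
    "update_cluster_stats",
    "gaussian_density",
    "em_segment",
    "otsu_threshold",
    "binarize_gray_matter",
]
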