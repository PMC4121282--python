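"""Alignment-based gray-matter matching: chamfer distance and score normalization.

The matcher compares two binarized gray-matter volumes after bridging them
through their template registrations. The (directed) chamfer distance sums,
over every foreground voxel of the moved mask, the Euclidean distance in mm
to the nearest foreground voxel of the reference mask; it is evaluated with a
Euclidean distance transform of the reference's complement, which equals the
brute-force nearest-neighbour double loop exactly. Distances are mapped to a
[0, 100] similarity by a trained linear normalizer: 100 at the training
minimum, 0 at the maximum, clamped outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage

from .errors import MatchingError
from .registration import (
    RegistrationConfig,
    compose_inter_image_transform,
    estimate_rigid,
    resample,
)
from .segmentation import (
    BinaryGMMask,
    SegmentationConfig,
    binarize_gray_matter,
    em_segment,
)
from .volume_io import TissuePriorSet, Volume


@dataclass
class MatchingConfig:
    """symmetric: average the two directed chamfer sums.
    per_voxel: divide the sum by the moved mask's foreground count.
    Both default off: the directed, unnormalized sum is the primary statistic.
    normalizer_training: 'all_pairs' or 'genuine' distance pool for training.
    """

    symmetric: bool = False
    per_voxel: bool = False
    normalizer_training: str = "all_pairs"

    def __post_init__(self) -> None:
        if self.normalizer_training not in ("all_pairs", "genuine"):
            raise ValueError("normalizer_training must be 'all_pairs' or 'genuine'")


@dataclass(frozen=True)
class ScoreNormalizer:
    """Linear score normalizer with the trained (dmin, dmax) range."""

    dmin: float
    dmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dmin) and np.isfinite(self.dmax)):
            raise ValueError("dmin/dmax must be finite")
        if not 0 <= self.dmin < self.dmax:
            raise ValueError("require 0 <= dmin < dmax")


@dataclass
class MatchResult:
    d: float
    s: float
    n_fg_1: int
    n_fg_2: int
    transform: np.ndarray
    thresholds: tuple[float, float] = (0.0, 0.0)  # Otsu cuts of the two masks


def align_mask(
    b1: BinaryGMMask, m12: np.ndarray, reference: BinaryGMMask
) -> BinaryGMMask:
    """Resample a binary mask onto the reference grid under the rigid world
    transform ``m12`` (mask space -> reference space), nearest-neighbour so the
    output stays strictly binary."""
    v = Volume(b1.mask, b1.affine)
    ref = Volume(reference.mask, reference.affine)
    out = resample(v, m12, ref, mode="nearest")
    return BinaryGMMask(
        mask=(out.data > 0.5).astype(np.uint8),
        threshold=b1.threshold,
        affine=reference.affine.copy(),
    )


def chamfer_distance(b1p: BinaryGMMask, b2p: BinaryGMMask) -> float:
    """Directed chamfer distance: for every foreground voxel of ``b1p``, the
    Euclidean distance in mm (voxel spacing respected) to the nearest
    foreground voxel of ``b2p``, summed."""
    if b1p.mask.shape != b2p.mask.shape:
        raise MatchingError("masks are not on the same grid")
    fg1 = b1p.mask.astype(bool)
    fg2 = b2p.mask.astype(bool)
    if not fg1.any() or not fg2.any():
        raise MatchingError("cannot match empty mask")
    spacing = Volume(b2p.mask, b2p.affine).spacing
    edt = ndimage.distance_transform_edt(~fg2, sampling=spacing)
    return float(edt[fg1].sum())


def fit_normalizer(training_distances: Iterable[float]) -> ScoreNormalizer:
    """Train the linear normalizer: dmin/dmax are the extremes of the training
    distances. Requires at least two distinct values."""
    d = np.asarray(list(training_distances), dtype=float)
    if d.size < 2 or np.all(d == d[0]):
        raise MatchingError("need at least two distinct training distances")
    return ScoreNormalizer(dmin=float(d.min()), dmax=float(d.max()))


def normalize_score(d: float, norm: ScoreNormalizer) -> float:
    """s = (1 - (d - dmin)/(dmax - dmin)) * 100, clamped to [0, 100]."""
    s = (1.0 - (d - norm.dmin) / (norm.dmax - norm.dmin)) * 100.0
    return float(np.clip(s, 0.0, 100.0))


def match_pair(
    i1: Volume,
    i2: Volume,
    template: Volume,
    priors: TissuePriorSet,
    norm: ScoreNormalizer,
    reg_cfg: RegistrationConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    match_cfg: MatchingConfig | None = None,
) -> MatchResult:
    """Full verification pipeline for one image pair.

    Registers both images to the template, classifies tissues and binarizes
    gray matter, composes the inter-image transform through the template
    bridge, aligns the first mask onto the second, and scores the chamfer
    distance through the trained normalizer. Deterministic given fixed inputs.
    """
    match_cfg = match_cfg or MatchingConfig()
    stage = "registration"
    try:
        r1 = estimate_rigid(i1, template, reg_cfg)
        r2 = estimate_rigid(i2, template, reg_cfg)
        stage = "segmentation"
        s1 = em_segment(i1, priors, np.linalg.inv(r1.matrix), seg_cfg)
        s2 = em_segment(i2, priors, np.linalg.inv(r2.matrix), seg_cfg)
        b1 = binarize_gray_matter(s1)
        b2 = binarize_gray_matter(s2)
        stage = "matching"
        # template->image matrices bridged: forward map image1 -> image2
        m12 = compose_inter_image_transform(
            np.linalg.inv(r2.matrix), np.linalg.inv(r1.matrix)
        )
        d = _pair_distance(b1, b2, m12, match_cfg)
        s = normalize_score(d, norm)
    except MatchingError:
        raise
    except Exception as exc:
        raise MatchingError(f"{stage} stage failed: {exc}") from exc
    return MatchResult(
        d=d,
        s=s,
        n_fg_1=b1.foreground_count,
        n_fg_2=b2.foreground_count,
        transform=m12,
        thresholds=(b1.threshold, b2.threshold),
    )


def _pair_distance(
    b1: BinaryGMMask, b2: BinaryGMMask, m12: np.ndarray, cfg: MatchingConfig
) -> float:
    """Directed (optionally symmetrized / per-voxel) chamfer between two masks
    given the forward world transform from mask-1 space to mask-2 space."""
    b1p = align_mask(b1, m12, b2)
    if not b1p.mask.any():
        raise MatchingError("aligned mask left the field of view")
    d = chamfer_distance(b1p, b2)
    if cfg.per_voxel:
        d /= b1p.foreground_count
    if cfg.symmetric:
        b2p = align_mask(b2, np.linalg.inv(m12), b1)
        if not b2p.mask.any():
            raise MatchingError("aligned mask left the field of view")
        d_rev = chamfer_distance(b2p, b1)
        if cfg.per_voxel:
            d_rev /= b2p.foreground_count
        d = 0.5 * (d + d_rev)
    return d
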