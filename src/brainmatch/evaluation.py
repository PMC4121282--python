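"""All-pairs verification experiment: genuine/imposter scores, FAR/FRR, EER.

Genuine pairs are two visits of the same subject; imposter pairs are two
different subjects (first visit each, by default). Standard biometric rates
are used: FRR(t) is the fraction of genuine scores below the threshold,
FAR(t) the fraction of imposter scores at or above it (accept-on-tie), and
the equal error rate is read off where the two empirical step curves cross,
with linear interpolation between the straddling thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MatchingError
from .matching import (
    MatchingConfig,
    ScoreNormalizer,
    _pair_distance,
    fit_normalizer,
    normalize_score,
)
from .registration import (
    RegistrationConfig,
    compose_inter_image_transform,
    estimate_rigid,
    resample,
)
from .segmentation import (
    SegmentationConfig,
    binarize_gray_matter,
    em_segment,
)
from .volume_io import TissuePriorSet, Volume


@dataclass(frozen=True)
class PairScore:
    subject_a: str
    visit_a: str
    subject_b: str
    visit_b: str
    kind: str  # "genuine" | "imposter"
    d: float
    s: float


@dataclass
class ScoreSet:
    genuine: list[PairScore]
    imposter: list[PairScore]
    normalizer: ScoreNormalizer | None = None

    def genuine_scores(self) -> np.ndarray:
        return np.array([p.s for p in self.genuine])

    def imposter_scores(self) -> np.ndarray:
        return np.array([p.s for p in self.imposter])

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(p) for p in self.genuine + self.imposter]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RatePoint:
    threshold: float
    far: float
    frr: float
    tar: float


def enumerate_pairs(
    labels: list[tuple[str, str]], imposter_visits: str = "first"
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Index pairs for a cohort given (subject, visit) labels.

    Genuine: all same-subject cross-visit pairs. Imposter: all cross-subject
    pairs, one visit per subject ('first' by default, or 'all'). Each
    unordered pair appears once.
    """
    genuine: list[tuple[int, int]] = []
    imposter: list[tuple[int, int]] = []
    by_subject: dict[str, list[int]] = {}
    for i, (sid, _vid) in enumerate(labels):
        by_subject.setdefault(sid, []).append(i)
    for members in by_subject.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                genuine.append((members[a], members[b]))
    subjects = list(by_subject)
    for a in range(len(subjects)):
        for b in range(a + 1, len(subjects)):
            if imposter_visits == "first":
                imposter.append((by_subject[subjects[a]][0], by_subject[subjects[b]][0]))
            else:
                for i in by_subject[subjects[a]]:
                    for j in by_subject[subjects[b]]:
                        imposter.append((i, j))
    return genuine, imposter


class CohortScorer:
    """Scores a cohort with one registration + segmentation per volume.

    Each volume is prepared once (template registration, tissue
    classification, GM mask, distance transform of the mask complement); pair
    scoring then reuses the cache for both the chamfer matcher and the
    intensity baseline, which is how the two methods are compared on exactly
    the same alignments.
    """

    def __init__(
        self,
        cohort: list[tuple[str, str, Volume]],
        template: Volume,
        priors: TissuePriorSet,
        reg_cfg: RegistrationConfig | None = None,
        seg_cfg: SegmentationConfig | None = None,
        match_cfg: MatchingConfig | None = None,
        imposter_visits: str = "first",
    ) -> None:
        if len({sid for sid, _, _ in cohort}) < 2:
            raise MatchingError("no imposter pairs: need at least 2 subjects")
        self.labels = [(sid, vid) for sid, vid, _ in cohort]
        self.volumes = [v for _, _, v in cohort]
        self.template = template
        self.priors = priors
        self.reg_cfg = reg_cfg
        self.seg_cfg = seg_cfg
        self.match_cfg = match_cfg or MatchingConfig()
        self.genuine_pairs, self.imposter_pairs = enumerate_pairs(
            self.labels, imposter_visits
        )
        if not self.genuine_pairs:
            raise MatchingError("no genuine pairs: need a subject with >= 2 visits")
        self._prepared: list[dict] | None = None

    def _prepare(self) -> list[dict]:
        if self._prepared is None:
            prepared = []
            for vol in self.volumes:
                reg = estimate_rigid(vol, self.template, self.reg_cfg)
                seg = em_segment(
                    vol, self.priors, np.linalg.inv(reg.matrix), self.seg_cfg
                )
                mask = binarize_gray_matter(seg)
                prepared.append({"volume": vol, "reg": reg, "mask": mask})
            self._prepared = prepared
        return self._prepared

    def _forward(self, prep_a: dict, prep_b: dict) -> np.ndarray:
        """World transform from volume a's space into volume b's space."""
        return compose_inter_image_transform(
            np.linalg.inv(prep_b["reg"].matrix), np.linalg.inv(prep_a["reg"].matrix)
        )

    def distances(self, method: str = "chamfer") -> tuple[list[float], list[float]]:
        """Raw pair distances (genuine list, imposter list) for a method."""
        prepared = self._prepare()

        def dist(a: int, b: int) -> float:
            m12 = self._forward(prepared[a], prepared[b])
            if method == "chamfer":
                return _pair_distance(
                    prepared[a]["mask"], prepared[b]["mask"], m12, self.match_cfg
                )
            if method == "intensity":
                return intensity_distance(
                    prepared[a]["volume"], prepared[b]["volume"], m12
                )
            raise ValueError(f"unknown method {method!r}")

        return (
            [dist(a, b) for a, b in self.genuine_pairs],
            [dist(a, b) for a, b in self.imposter_pairs],
        )

    def score(
        self, method: str = "chamfer", normalizer: ScoreNormalizer | None = None
    ) -> ScoreSet:
        gen_d, imp_d = self.distances(method)
        if normalizer is None:
            pool = gen_d + imp_d
            if self.match_cfg.normalizer_training == "genuine":
                pool = gen_d
            normalizer = fit_normalizer(pool)

        def records(pairs, dists, kind):
            out = []
            for (a, b), d in zip(pairs, dists):
                sa, va = self.labels[a]
                sb, vb = self.labels[b]
                out.append(PairScore(sa, va, sb, vb, kind, d, normalize_score(d, normalizer)))
            return out

        return ScoreSet(
            genuine=records(self.genuine_pairs, gen_d, "genuine"),
            imposter=records(self.imposter_pairs, imp_d, "imposter"),
            normalizer=normalizer,
        )


def score_cohort(
    cohort: list[tuple[str, str, Volume]],
    template: Volume,
    priors: TissuePriorSet,
    reg_cfg: RegistrationConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    match_cfg: MatchingConfig | None = None,
    method: str = "chamfer",
    normalizer: ScoreNormalizer | None = None,
) -> ScoreSet:
    """Score every genuine and imposter pair of a cohort once."""
    scorer = CohortScorer(cohort, template, priors, reg_cfg, seg_cfg, match_cfg)
    return scorer.score(method=method, normalizer=normalizer)


def intensity_distance(i1: Volume, i2: Volume, m12: np.ndarray) -> float:
    """Mean squared intensity difference after alignment (pixel-based
    baseline); evaluated over the voxels where the moved image stays inside
    the field of view."""
    moved = resample(i1, m12, i2, mode="linear")
    support = resample(
        Volume(np.ones(i1.shape, dtype=np.float64), i1.affine), m12, i2, mode="nearest"
    )
    overlap = support.data > 0.5
    if not overlap.any():
        raise MatchingError("no overlap between aligned volumes")
    diff = moved.astype_float()[overlap] - i2.astype_float()[overlap]
    return float(np.mean(diff**2))


def intensity_baseline_score(
    i1: Volume, i2: Volume, m12: np.ndarray, norm: ScoreNormalizer
) -> float:
    """Pixel-based similarity: the aligned mean squared intensity difference
    mapped through the same linear score normalization as the chamfer
    distance (normalizer trained on MSE distances)."""
    return normalize_score(intensity_distance(i1, i2, m12), norm)


def rate_table(scores: ScoreSet, thresholds: list[float]) -> list[RatePoint]:
    """FAR/FRR/TAR at each threshold, accept-on-tie.

    frr(t) = #(genuine < t)/#genuine, far(t) = #(imposter >= t)/#imposter,
    tar(t) = 1 - far(t)."""
    g = scores.genuine_scores()
    i = scores.imposter_scores()
    if g.size == 0 or i.size == 0:
        raise MatchingError("empty genuine or imposter score list")
    out = []
    for t in thresholds:
        far = float(np.mean(i >= t))
        frr = float(np.mean(g < t))
        out.append(RatePoint(threshold=float(t), far=far, frr=frr, tar=1.0 - far))
    return out


def equal_error_rate(scores: ScoreSet) -> float:
    """Rate where FAR = FRR, linearly interpolated between the straddling
    thresholds of the empirical step curves."""
    g = scores.genuine_scores()
    i = scores.imposter_scores()
    if g.size == 0 or i.size == 0:
        raise MatchingError("empty genuine or imposter score list")
    if i.max() < g.min():
        return 0.0
    thr = np.unique(np.concatenate([g, i]))
    thr = np.concatenate([[thr[0] - 1.0], thr, [thr[-1] + 1.0]])
    far = np.array([np.mean(i >= t) for t in thr])
    frr = np.array([np.mean(g < t) for t in thr])
    diff = frr - far
    k = int(np.argmax(diff >= 0))
    if diff[k] == 0 or k == 0:
        return float(far[k])
    t = (0.0 - diff[k - 1]) / (diff[k] - diff[k - 1])
    return float(far[k - 1] + t * (far[k] - far[k - 1]))


def report(
    scores: ScoreSet,
    rates: list[RatePoint],
    eer: float,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write score CSV, rate-table CSV, histogram and FAR-vs-FRR plots, and a
    summary JSON. Returns the paths written."""
    if not scores.genuine or not scores.imposter:
        raise MatchingError("cannot report an empty score set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    paths["scores"] = out / "scores.csv"
    scores.to_frame().to_csv(paths["scores"], index=False)

    paths["rates"] = out / "rates.csv"
    pd.DataFrame([vars(r) for r in rates]).to_csv(paths["rates"], index=False)

    paths["summary"] = out / "summary.json"
    summary = {
        "eer": eer,
        "n_genuine": len(scores.genuine),
        "n_imposter": len(scores.imposter),
        "genuine_mean": float(scores.genuine_scores().mean()),
        "imposter_mean": float(scores.imposter_scores().mean()),
    }
    if scores.normalizer is not None:
        summary["dmin"] = scores.normalizer.dmin
        summary["dmax"] = scores.normalizer.dmax
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    fig, ax = plt.subplots()
    bins = np.linspace(0, 100, 41)
    ax.hist(scores.imposter_scores(), bins=bins, alpha=0.6, label="imposter")
    ax.hist(scores.genuine_scores(), bins=bins, alpha=0.6, label="genuine")
    ax.set_xlabel("matching score")
    ax.set_ylabel("pairs")
    ax.legend()
    paths["histogram"] = out / "score_histogram.png"
    fig.savefig(paths["histogram"], dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot([r.far for r in rates], [r.frr for r in rates], marker=".")
    ax.set_xlabel("FAR")
    ax.set_ylabel("FRR")
    paths["roc"] = out / "far_frr.png"
    fig.savefig(paths["roc"], dpi=100)
    plt.close(fig)
    return paths
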