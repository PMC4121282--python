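"""Seeded synthetic brain phantoms: template, priors, subjects, visits, cohorts.

The anatomy model is a nested set of perturbed ellipsoids: a white-matter
core, a gray-matter shell, a CSF shell, and an "other" background absorbing
scalp and air. Each shell boundary is a continuous angular function — a fixed
asymmetric base shape shared by every subject plus a subject-specific
band-limited harmonic perturbation — so a volume can be rendered *exactly* at
any pose by evaluating the boundary functions at each voxel's anatomy
coordinate (no label-grid resampling, hence no pose-dependent aliasing).
Visits of one subject share the anatomy exactly and differ by a rigid-body
motion, a global intensity gain, and additive Gaussian noise. Every output is
a pure function of (config, seed), and every generated volume carries its
ground-truth labels and motion, so registration-recovery and
segmentation-overlap assertions need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .registration import RigidParams, build_rigid_matrix, decompose_rigid
from .volume_io import (
    TissuePriorSet,
    Volume,
    gaussian_smooth,
    write_priors,
    write_volume,
)

#: integer label codes used by the renderer, in intensity order
LABEL_OTHER, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3

#: renderer label -> class axis position in the canonical (GM, WM, CSF, other) order
LABEL_TO_CLASS = {LABEL_GM: 0, LABEL_WM: 1, LABEL_CSF: 2, LABEL_OTHER: 3}

#: full intensity scale; noise_sd is a fraction of this
INTENSITY_SCALE = 100.0

#: shell boundaries as fractions of the head semi-axes: WM core, GM outer, CSF outer
SHELL_FRACTIONS = (0.61, 0.70, 0.90)

#: head semi-axes as fractions of the half field of view per axis; distinct
#: values keep all three rotations identifiable (no axis of symmetry)
HEAD_FRACTIONS = (0.66, 0.84, 0.76)

#: fixed low-order "egg" asymmetry shared by every subject, breaking the
#: residual front/back symmetry of a pure ellipsoid
BASE_ASYMMETRY = 0.12


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the acquisition geometry (1 mm in-plane, 1.25 mm slices)
    at a desk-scale 64x64x48 grid, a 2% noise level (the bottom of the 1.5 T
    SNR band), inter-visit motion up to 5 mm / 5 deg, and a 0.9-1.1 global
    intensity gain per visit.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.25)
    class_intensities: tuple[float, float, float, float] = (5.0, 25.0, 55.0, 85.0)
    noise_sd: float = 0.02
    deform_amplitude: float = 0.06
    n_harmonics: int = 4
    motion_t_max: float = 5.0
    motion_r_max_deg: float = 5.0
    gain_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("grid shape must be >= 32 per axis")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0 or self.deform_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not np.all(np.diff(self.class_intensities) > 0):
            raise ValueError("class intensities must be ordered other < CSF < GM < WM")
        if self.n_harmonics < 3:
            raise ValueError("need at least 3 harmonics")

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.spacing) + [1.0])

    @property
    def intensity_lut(self) -> np.ndarray:
        """Class intensity by renderer label code."""
        other, csf, gm, wm = self.class_intensities
        return np.array([other, csf, gm, wm], dtype=np.float64)


@dataclass(frozen=True)
class HarmonicField:
    """Band-limited angular function sum_j amp_j cos(m_j theta + alpha_j)
    sin(l_j phi + beta_j), normalized to unit peak on a reference sphere grid.
    Coefficient-based, so it can be evaluated exactly at any coordinate."""

    m: np.ndarray
    ell: np.ndarray
    amp: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        f = np.zeros_like(theta)
        for j in range(self.m.size):
            f += self.amp[j] * np.cos(self.m[j] * theta + self.alpha[j]) * np.sin(
                self.ell[j] * phi + self.beta[j]
            )
        return f


def _reference_peak(field: HarmonicField) -> float:
    th, ph = np.meshgrid(
        np.linspace(-np.pi, np.pi, 73), np.linspace(0.0, np.pi, 37), indexing="ij"
    )
    return float(np.max(np.abs(field.evaluate(th, ph))))


def _normalized(field: HarmonicField) -> HarmonicField:
    peak = _reference_peak(field)
    if peak <= 0:
        return field
    return replace(field, amp=field.amp / peak)


def _random_field(rng: np.random.Generator, n_harmonics: int) -> HarmonicField:
    return _normalized(
        HarmonicField(
            m=rng.integers(1, 4, size=n_harmonics),
            ell=rng.integers(1, 4, size=n_harmonics),
            amp=rng.normal(size=n_harmonics),
            alpha=rng.uniform(0, 2 * np.pi, size=n_harmonics),
            beta=rng.uniform(0, 2 * np.pi, size=n_harmonics),
        )
    )


def _mix_fields(base: HarmonicField, own: HarmonicField, frac: float) -> HarmonicField:
    mixed = HarmonicField(
        m=np.concatenate([base.m, own.m]),
        ell=np.concatenate([base.ell, own.ell]),
        amp=np.concatenate([frac * base.amp, (1 - frac) * own.amp]),
        alpha=np.concatenate([base.alpha, own.alpha]),
        beta=np.concatenate([base.beta, own.beta]),
    )
    return _normalized(mixed)


@dataclass
class SubjectTruth:
    """Ground-truth anatomy of one subject: identity-pose label volume plus
    the per-boundary perturbation fields defining the continuous anatomy."""

    labels: np.ndarray
    affine: np.ndarray
    subject_seed: int
    wm_field: HarmonicField  # WM/GM boundary perturbation, unit peak
    gm_field: HarmonicField  # GM/CSF boundary perturbation, unit peak
    csf_field: HarmonicField  # CSF/other boundary perturbation, unit peak


@dataclass
class Visit:
    """One acquisition of a subject, with its ground truth attached.

    ``matrix`` maps visit-image world coordinates onto anatomy (template)
    world coordinates, i.e. the transform a perfect registration to this
    subject's anatomy would recover.
    """

    volume: Volume
    matrix: np.ndarray
    params: RigidParams
    gain: float
    labels: np.ndarray


@dataclass
class Cohort:
    template: Volume
    priors: TissuePriorSet
    subjects: dict[str, SubjectTruth]
    visits: list[tuple[str, str, Visit]]  # (subject_id, visit_id, visit)

    def volumes(self) -> list[tuple[str, str, Volume]]:
        return [(s, v, visit.volume) for s, v, visit in self.visits]


def _grid_world(cfg: PhantomConfig) -> np.ndarray:
    idx = np.indices(cfg.shape, dtype=np.float64).reshape(3, -1)
    return np.asarray(cfg.spacing)[:, None] * idx


def _labels_at(
    cfg: PhantomConfig,
    world: np.ndarray,
    wm_field: HarmonicField,
    gm_field: HarmonicField,
    csf_field: HarmonicField,
) -> np.ndarray:
    """Exact anatomy labels at arbitrary world (mm) points, shape (3, N)."""
    extent = np.array(cfg.shape) * np.asarray(cfg.spacing)
    center = extent / 2.0
    semi = np.asarray(HEAD_FRACTIONS) * extent / 2.0
    v = (world - center[:, None]) / semi[:, None]
    rho = np.sqrt((v**2).sum(axis=0))
    theta = np.arctan2(v[1], v[0])
    phi = np.arccos(np.clip(v[2] / np.maximum(rho, 1e-12), -1.0, 1.0))
    a = cfg.deform_amplitude
    # Shared base anatomy: an egg-shaped low-order term plus fixed
    # mid-frequency bumps. The bumps are of higher angular order than the
    # subject fields (<= 3), so no subject deformation can mimic a rotation
    # of the base shape: orientation stays identifiable to the registration.
    base = (
        BASE_ASYMMETRY * np.cos(theta) * np.sin(phi)
        + 0.05 * np.cos(4 * theta + 1.0) * np.sin(3 * phi + 0.5)
        + 0.04 * np.cos(2 * theta - 0.7) * np.sin(5 * phi + 1.3)
        + 0.04 * np.cos(5 * theta + 2.1) * np.sin(4 * phi - 0.9)
    )
    wm_r, gm_r, csf_r = SHELL_FRACTIONS
    # Each boundary carries its own independent subject field: the gray-matter
    # shell varies on both faces, which is what separates subjects.
    labels = np.full(rho.shape, LABEL_OTHER, dtype=np.uint8)
    labels[rho < csf_r * (1.0 + base + a * csf_field.evaluate(theta, phi))] = LABEL_CSF
    labels[rho < gm_r * (1.0 + base + a * gm_field.evaluate(theta, phi))] = LABEL_GM
    labels[rho < wm_r * (1.0 + base + a * wm_field.evaluate(theta, phi))] = LABEL_WM
    return labels


def generate_subject(
    cfg: PhantomConfig,
    subject_seed: int,
    share_with: SubjectTruth | None = None,
    share_frac: float = 0.5,
) -> SubjectTruth:
    """Generate one subject's ground-truth anatomy.

    ``share_with`` mixes a fraction of another subject's perturbation fields
    into this one (correlated anatomy, used for hard-imposter cohorts).
    """
    rng = np.random.default_rng([cfg.seed, 101, subject_seed])
    wm = _random_field(rng, cfg.n_harmonics)
    gm = _random_field(rng, cfg.n_harmonics)
    csf = _random_field(rng, cfg.n_harmonics)
    if share_with is not None:
        wm = _mix_fields(share_with.wm_field, wm, share_frac)
        gm = _mix_fields(share_with.gm_field, gm, share_frac)
        csf = _mix_fields(share_with.csf_field, csf, share_frac)
    labels = _labels_at(cfg, _grid_world(cfg), wm, gm, csf).reshape(cfg.shape)
    return SubjectTruth(
        labels=labels,
        affine=cfg.affine,
        subject_seed=subject_seed,
        wm_field=wm,
        gm_field=gm,
        csf_field=csf,
    )


def generate_template(cfg: PhantomConfig) -> tuple[Volume, TissuePriorSet]:
    """Population-average template and tissue priors.

    Averages the one-hot labels of 8 seeded virtual subjects, smooths each
    class with a 3 mm FWHM kernel, renormalizes per voxel, and renders the
    template intensity volume as the prior-weighted mix of class intensities.
    """
    n_virtual = 8
    world = _grid_world(cfg)
    acc = np.zeros(cfg.shape + (4,), dtype=np.float64)
    for i in range(n_virtual):
        rng = np.random.default_rng([cfg.seed, 909, i])
        wm = _random_field(rng, cfg.n_harmonics)
        gm = _random_field(rng, cfg.n_harmonics)
        csf = _random_field(rng, cfg.n_harmonics)
        labels = _labels_at(cfg, world, wm, gm, csf).reshape(cfg.shape)
        for lab, k in LABEL_TO_CLASS.items():
            acc[..., k] += labels == lab
    acc /= n_virtual
    for k in range(4):
        acc[..., k] = gaussian_smooth(Volume(acc[..., k], cfg.affine), 3.0).data
    priors = TissuePriorSet(acc, cfg.affine)
    intens = cfg.intensity_lut[[2, 3, 1, 0]]  # reorder to (GM, WM, CSF, other)
    template = Volume(np.einsum("...k,k->...", priors.priors, intens), cfg.affine)
    return template, priors


def generate_visit(truth: SubjectTruth, visit_seed: int, cfg: PhantomConfig) -> Visit:
    """Render one acquisition: rigid motion, intensity gain, additive noise.

    The motion is a rotation about the field-of-view centre composed with a
    bounded translation, expressed in the corner-origin parameter convention.
    The visit volume at world coordinate x holds the continuous anatomy
    evaluated exactly at ``matrix @ x`` (crisp class boundaries, no
    partial-volume mixing), scaled by the visit gain, plus Gaussian noise
    with sd = ``noise_sd * 100``.
    """
    rng = np.random.default_rng([cfg.seed, 505, truth.subject_seed, visit_seed])
    t = rng.uniform(-cfg.motion_t_max, cfg.motion_t_max, size=3)
    r = np.deg2rad(rng.uniform(-cfg.motion_r_max_deg, cfg.motion_r_max_deg, size=3))
    center = np.array(cfg.shape) * np.array(cfg.spacing) / 2.0
    rot = build_rigid_matrix(RigidParams(0, 0, 0, r[0], r[1], r[2]))
    matrix = rot.copy()
    matrix[:3, 3] = center - rot[:3, :3] @ center + t
    params = decompose_rigid(matrix)
    gain = float(rng.uniform(*cfg.gain_range))

    world = _grid_world(cfg)
    anat = matrix[:3, :3] @ world + matrix[:3, 3:4]
    moved = _labels_at(
        cfg, anat, truth.wm_field, truth.gm_field, truth.csf_field
    ).reshape(cfg.shape)
    data = cfg.intensity_lut[moved] * gain
    data = data + rng.normal(0.0, cfg.noise_sd * INTENSITY_SCALE, size=cfg.shape)
    return Visit(
        volume=Volume(data.astype(np.float32), truth.affine.copy()),
        matrix=matrix,
        params=params,
        gain=gain,
        labels=moved,
    )


def generate_cohort(
    n_subjects: int,
    n_visits: int,
    cfg: PhantomConfig | None = None,
    out_dir: str | Path | None = None,
    shared_pair: bool = False,
    share_frac: float = 0.5,
) -> Cohort:
    """Generate a multi-subject, multi-visit cohort with ground truth.

    With ``shared_pair`` the first two subjects share ``share_frac`` of their
    deformation fields (a correlated, harder imposter pair). If ``out_dir`` is
    given, writes all volumes, the template, the priors, and a manifest CSV
    with the true transforms; regeneration from the same (config, seed) is
    reproducible.
    """
    if n_subjects < 2 or n_visits < 2:
        raise ValueError("need at least 2 subjects and 2 visits")
    cfg = cfg or PhantomConfig()
    template, priors = generate_template(cfg)
    subjects: dict[str, SubjectTruth] = {}
    visits: list[tuple[str, str, Visit]] = []
    first: SubjectTruth | None = None
    for si in range(n_subjects):
        sid = f"sub{si:02d}"
        share = first if (shared_pair and si == 1) else None
        truth = generate_subject(cfg, si, share_with=share, share_frac=share_frac)
        if si == 0:
            first = truth
        subjects[sid] = truth
        for vi in range(n_visits):
            vid = f"visit{vi:02d}"
            visits.append((sid, vid, generate_visit(truth, vi, cfg)))

    cohort = Cohort(template=template, priors=priors, subjects=subjects, visits=visits)
    if out_dir is not None:
        _write_cohort(cohort, cfg, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, cfg: PhantomConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(cohort.template, out_dir / "template.nii")
    write_priors(cohort.priors, out_dir / "priors.nii")
    rows = []
    for sid, vid, visit in cohort.visits:
        name = f"{sid}_{vid}.nii"
        write_volume(visit.volume, out_dir / name)
        p = visit.params
        rows.append(
            {
                "subject_id": sid,
                "visit_id": vid,
                "path": name,
                "tx": p.tx, "ty": p.ty, "tz": p.tz,
                "rx": p.rx, "ry": p.ry, "rz": p.rz,
                "gain": visit.gain,
                "seed": cfg.seed,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)


def registration_phantom(
    cfg: PhantomConfig, trial_seed: int, t_max: float, r_max_deg: float
) -> tuple[Volume, TissuePriorSet, Visit]:
    """Template-anatomy phantom moved by a known rigid motion: the standard
    fixture for registration parameter-recovery studies (deformation is
    disabled so the rigid ground truth is identifiable)."""
    base = replace(cfg, deform_amplitude=0.0, motion_t_max=t_max,
                   motion_r_max_deg=r_max_deg, gain_range=(1.0, 1.0))
    template, priors = generate_template(base)
    truth = generate_subject(base, 0)
    visit = generate_visit(truth, trial_seed, base)
    return template, priors, visit
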