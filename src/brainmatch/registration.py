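"""Six-parameter rigid-body registration by Gauss-Newton on intensity SSD.

The rigid transform is parameterized by three translations (mm) and three
rotations (radians), assembled as

    M = Trans(tx, ty, tz) @ Rx(rx) @ Ry(ry) @ Rz(rz)

acting on homogeneous world-coordinate column vectors. Each factor is a
proper right-handed rotation; all matrices map world millimetre coordinates.

``estimate_rigid(image, template)`` returns the matrix that carries *image*
world coordinates onto *template* world coordinates. The segmentation entry
points (see :mod:`brainmatch.segmentation`) expect the opposite direction
(template -> image); the pipeline inverts explicitly when crossing over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import RegistrationError
from .volume_io import Volume, gaussian_smooth


@dataclass(frozen=True)
class RigidParams:
    """Translations (mm) and rotations (radians) of the 6-parameter transform."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("rigid parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @staticmethod
    def from_array(p: np.ndarray) -> "RigidParams":
        p = np.asarray(p, dtype=float)
        # rotations reported wrapped to (-pi, pi]
        rot = -(np.mod(-p[3:6] + np.pi, 2 * np.pi) - np.pi)
        return RigidParams(p[0], p[1], p[2], rot[0], rot[1], rot[2])


@dataclass
class RegistrationConfig:
    """Settings for :func:`estimate_rigid`.

    fwhm_mm:        pre-smoothing kernel width (mm FWHM) applied to both volumes.
    tol:            relative SSD decrease below which iteration stops.
    max_iter:       Gauss-Newton iteration cap.
    sample_step:    voxel stride used when evaluating the SSD (1 = every voxel).
    estimate_scale: solve a closed-form global intensity scale each iteration,
                    absorbing acquisition gain differences.
    mask:           optional boolean array on the image grid restricting the SSD.
    """

    fwhm_mm: float = 5.0
    tol: float = 1e-6
    max_iter: int = 32
    sample_step: int = 2
    estimate_scale: bool = True
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.sample_step < 1:
            raise ValueError("sample_step must be >= 1")


@dataclass
class RegistrationResult:
    params: RigidParams
    matrix: np.ndarray
    ssd_trace: list[float]
    converged: bool
    n_iter: int


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _drot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[0, 0, 0], [0, -s, -c], [0, c, -s]], dtype=float)


def _drot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0, c], [0, 0, 0], [-c, 0, -s]], dtype=float)


def _drot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, -c, 0], [c, -s, 0], [0, 0, 0]], dtype=float)


def build_rigid_matrix(p: RigidParams) -> np.ndarray:
    """Assemble the 4x4 homogeneous matrix Trans @ Rx @ Ry @ Rz."""
    if not np.all(np.isfinite(p.as_array())):
        raise ValueError("rigid parameters must be finite")
    m = np.eye(4)
    m[:3, :3] = _rot_x(p.rx) @ _rot_y(p.ry) @ _rot_z(p.rz)
    m[:3, 3] = (p.tx, p.ty, p.tz)
    return m


def is_rigid(m: np.ndarray, tol: float = 1e-8) -> bool:
    """True if the 3x3 block is orthonormal with determinant +1 and the
    last row is [0, 0, 0, 1]."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4) or not np.allclose(m[3], [0, 0, 0, 1], atol=tol):
        return False
    r = m[:3, :3]
    return bool(
        np.allclose(r.T @ r, np.eye(3), atol=tol) and abs(np.linalg.det(r) - 1) < tol
    )


def decompose_rigid(m: np.ndarray, tol: float = 1e-8) -> RigidParams:
    """Recover the six parameters from a rigid matrix (Rx Ry Rz factor order).

    Raises on non-rigid input and on gimbal lock (|cos ry| < 1e-8), where the
    rx/rz split is not unique.
    """
    m = np.asarray(m, dtype=float)
    # looser orthonormality gate than the round-trip tolerance: reject scale/shear
    if not is_rigid(m, tol=max(tol, 1e-6)):
        raise ValueError("not rigid: rotation block is not orthonormal with det +1")
    r = m[:3, :3]
    sy = np.clip(r[0, 2], -1.0, 1.0)
    ry = float(np.arcsin(sy))
    if abs(np.cos(ry)) < 1e-8:
        raise ValueError("gimbal lock: |cos(ry)| < 1e-8, rx/rz are degenerate")
    rx = float(np.arctan2(-r[1, 2], r[2, 2]))
    rz = float(np.arctan2(-r[0, 1], r[0, 0]))
    return RigidParams(float(m[0, 3]), float(m[1, 3]), float(m[2, 3]), rx, ry, rz)


def compose_inter_image_transform(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Bridge two template registrations into an inter-image transform, M1 @ M2^-1.

    With template-to-image matrices passed as ``(m1, m2)`` the product maps
    image-2 world coordinates into image-1 world coordinates (the pull-back
    used to resample the first image onto the second image's grid).
    """
    m2 = np.asarray(m2, dtype=float)
    if abs(np.linalg.det(m2)) < 1e-12:
        raise RegistrationError("second transform is singular")
    return np.asarray(m1, dtype=float) @ np.linalg.inv(m2)


def _param_derivatives(p: RigidParams) -> list[np.ndarray]:
    """4x4 derivative of build_rigid_matrix w.r.t. each of the six parameters."""
    rx, ry, rz = _rot_x(p.rx), _rot_y(p.ry), _rot_z(p.rz)
    derivs = []
    for i in range(3):
        d = np.zeros((4, 4))
        d[i, 3] = 1.0
        derivs.append(d)
    for block in (
        _drot_x(p.rx) @ ry @ rz,
        rx @ _drot_y(p.ry) @ rz,
        rx @ ry @ _drot_z(p.rz),
    ):
        d = np.zeros((4, 4))
        d[:3, :3] = block
        derivs.append(d)
    return derivs


def resample(
    v: Volume, m: np.ndarray, reference: Volume, mode: str = "linear"
) -> Volume:
    """Resample ``v`` onto the grid of ``reference`` under world transform ``m``.

    ``m`` maps *v*'s world space onto the reference world space; the value at
    reference voxel x is ``v`` sampled at ``m^-1 x`` (pull-back). Voxels
    mapping outside the field of view are set to 0. ``mode`` is ``linear``
    (trilinear) or ``nearest`` (preserves the value set of binary inputs).
    """
    m = np.asarray(m, dtype=float)
    if abs(np.linalg.det(m)) < 1e-12:
        raise RegistrationError("singular transform")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    order = 1 if mode == "linear" else 0
    # reference voxel index -> reference world -> v world -> v voxel index
    total = np.linalg.inv(v.affine) @ np.linalg.inv(m) @ reference.affine
    idx = np.indices(reference.shape, dtype=np.float64).reshape(3, -1)
    src = total[:3, :3] @ idx + total[:3, 3:4]
    out = ndimage.map_coordinates(
        v.astype_float(), src, order=order, mode="constant", cval=0.0
    )
    return Volume(out.reshape(reference.shape), reference.affine.copy())


def _world_gradient(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Template intensities plus gradient volumes expressed in world mm units."""
    data = vol.astype_float()
    gi = np.stack(np.gradient(data), axis=0)  # index-space gradient
    a3inv_t = np.linalg.inv(vol.affine[:3, :3]).T
    gw = np.einsum("ij,j...->i...", a3inv_t, gi)
    return data, gw


def estimate_rigid(
    image: Volume, template: Volume, cfg: RegistrationConfig | None = None
) -> RegistrationResult:
    """Estimate the rigid transform mapping image coordinates onto template
    coordinates by minimizing the sum of squared intensity differences.

    Both volumes are pre-smoothed with ``cfg.fwhm_mm`` (default 5 mm FWHM) to
    enlarge the capture range, then Gauss-Newton steps on the first-order
    (Taylor) linearization of the SSD are iterated, with step halving whenever
    a trial step would increase the SSD, until the relative SSD decrease
    drops below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    """
    cfg = cfg or RegistrationConfig()
    img_s = gaussian_smooth(image, cfg.fwhm_mm)
    tpl_s = gaussian_smooth(template, cfg.fwhm_mm)
    tpl_data, tpl_grad = _world_gradient(tpl_s)
    tpl_inv = np.linalg.inv(tpl_s.affine)

    step = cfg.sample_step
    sel = tuple(slice(None, None, step) for _ in range(3))
    idx = np.indices(img_s.shape, dtype=np.float64)[(slice(None),) + sel].reshape(3, -1)
    if cfg.mask is not None:
        keep = np.asarray(cfg.mask, dtype=bool)[sel].reshape(-1)
        idx = idx[:, keep]
    world = img_s.affine[:3, :3] @ idx + img_s.affine[:3, 3:4]
    intens = img_s.astype_float()[sel].reshape(-1)
    if cfg.mask is not None:
        intens = intens[keep]
    n_pts = intens.size
    shape_arr = np.array(tpl_data.shape, dtype=float)
    # Out-of-field template samples are filled with the background value so
    # that sliding the head out of the field never cheapens the objective.
    background = float(tpl_data[0, 0, 0])

    def sample_template(m: np.ndarray):
        y = m[:3, :3] @ world + m[:3, 3:4]
        vox = tpl_inv[:3, :3] @ y + tpl_inv[:3, 3:4]
        inside = np.all((vox >= 0) & (vox <= shape_arr[:, None] - 1), axis=0)
        t = ndimage.map_coordinates(tpl_data, vox, order=1, mode="constant", cval=0.0)
        t[~inside] = background
        return vox, t, inside

    def _fit_scale(t: np.ndarray) -> float:
        if not cfg.estimate_scale:
            return 1.0
        denom = float(np.dot(t, t))
        if denom <= 0:
            return 1.0
        return float(np.dot(intens, t)) / denom

    def ssd_of(m: np.ndarray) -> float:
        _, t, _ = sample_template(m)
        r = intens - _fit_scale(t) * t
        return float(np.dot(r, r))

    p = np.zeros(6)
    matrix = build_rigid_matrix(RigidParams.from_array(p))
    vox, t, inside = sample_template(matrix)
    if inside.sum() < 0.05 * n_pts:
        raise RegistrationError("no overlap between image and template fields of view")

    scale = _fit_scale(t)
    resid = intens - scale * t
    ssd = float(np.dot(resid, resid))
    trace = [ssd]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        params = RigidParams.from_array(p)
        derivs = _param_derivatives(params)
        # template gradient at the mapped points, world units
        g = np.stack(
            [
                ndimage.map_coordinates(
                    tpl_grad[a], vox, order=1, mode="constant", cval=0.0
                )
                for a in range(3)
            ]
        )
        g[:, ~inside] = 0.0
        jac = np.empty((n_pts, 6))
        for j, dm in enumerate(derivs):
            dy = dm[:3, :3] @ world + dm[:3, 3:4]
            jac[:, j] = -scale * np.einsum("ij,ij->j", g, dy)
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        try:
            delta = np.linalg.solve(jtj + 1e-12 * np.eye(6) * np.trace(jtj), -jtr)
        except np.linalg.LinAlgError as exc:
            raise RegistrationError(f"normal equations singular: {exc}") from exc

        predicted = -(jtr @ delta)  # linear-model SSD decrease
        accepted = False
        for _ in range(8):
            trial_p = p + delta
            trial_m = build_rigid_matrix(RigidParams.from_array(trial_p))
            trial_ssd = ssd_of(trial_m)
            if trial_ssd < ssd:
                accepted = True
                break
            delta = delta / 2.0
        if not accepted:
            if it == 1 and ssd > 0 and predicted > cfg.tol * ssd:
                raise RegistrationError(
                    f"failed to converge: SSD increased on every trial step; trace={trace}"
                )
            converged = True
            break
        rel = (ssd - trial_ssd) / ssd if ssd > 0 else 0.0
        p, matrix, ssd = trial_p, trial_m, trial_ssd
        trace.append(ssd)
        vox, t, inside = sample_template(matrix)
        scale = _fit_scale(t)
        resid = intens - scale * t
        if rel < cfg.tol:
            converged = True
            break

    params = RigidParams.from_array(p)
    return RegistrationResult(
        params=params,
        matrix=build_rigid_matrix(params),
        ssd_trace=trace,
        converged=converged,
        n_iter=it,
    )
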