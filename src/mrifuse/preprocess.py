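"""Lightweight T1 preprocessing: brain extraction, bias-field correction,
rigid + global-scale affine registration to a template, and an optional
small-deformation nonlinear warp.

Geometry conventions
--------------------
A :class:`Volume` couples a 3-D scalar grid with a 4x4 voxel-to-world
affine (mm).  Spatial transforms live in world space: a
:class:`RigidScaleTransform` is the homogeneous matrix ``T @ R @ S``
(translation, rotation, isotropic scale — 7 free parameters) mapping
*moving-world* coordinates to *template-world* coordinates.  Resampling
always pulls: for each target voxel we map its world position through the
inverse transform (plus the displacement field, when present) and
trilinearly interpolate the source grid; samples outside the source
grid are zero.

The affine registration maximizes normalized cross-correlation inside
the template brain mask over a 3-level coarse-to-fine pyramid, using a
derivative-free Powell search initialized at the center-of-mass
alignment with unit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize
from scipy.cluster.vq import kmeans2
from skimage.filters import threshold_otsu

from .catalog import (
    CatalogHandle,
    PreprocessFileRecord,
)

__all__ = [
    "Volume",
    "RigidScaleTransform",
    "RegistrationConfig",
    "NonlinearConfig",
    "PreprocessResult",
    "extract_brain",
    "correct_bias",
    "register_affine",
    "register_nonlinear",
    "apply_transform",
    "warp_volume",
    "jacobian_determinant",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Volume


@dataclass
class Volume:
    """3-D scalar grid plus a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if min(self.data.shape) < 8:
            raise ValueError(f"grid dimensions must be >= 8, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), str(path))

    def world_coords(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (3, Nvox)."""
        idx = np.indices(self.shape).reshape(3, -1)
        return self.affine[:3, :3] @ idx + self.affine[:3, 3:4]

    def like(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.affine.copy())


def default_affine(shape: Sequence[int], voxel_size: float = 2.5) -> np.ndarray:
    """Axis-aligned affine with the world origin at the grid center."""
    A = np.eye(4)
    A[:3, :3] *= voxel_size
    A[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return A


# ---------------------------------------------------------------------------
# Rigid + isotropic-scale transform (7 DOF)


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_angles(R: np.ndarray) -> tuple[float, float, float]:
    # inverse of Rz @ Ry @ Rx, |ry| < pi/2 branch
    ry = math.asin(max(-1.0, min(1.0, -R[2, 0])))
    rx = math.atan2(R[2, 1], R[2, 2])
    rz = math.atan2(R[1, 0], R[0, 0])
    return rx, ry, rz


@dataclass
class RigidScaleTransform:
    """World-space rigid transform with one global isotropic scale.

    ``matrix`` composes as T(translations) @ R(rotations) @ S(scale):
    3 Euler angles (radians, applied x then y then z), 3 translations (mm)
    and one positive scale factor.
    """

    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = _euler_matrix(*self.rotations) * self.scale
        M[:3, 3] = self.translations
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidScaleTransform":
        M = np.asarray(M, dtype=float)
        A = M[:3, :3]
        scale = float(np.linalg.det(A)) ** (1.0 / 3.0)
        if not np.isfinite(scale) or scale <= 0:
            raise ValueError("matrix is not a rigid+scale transform (det <= 0)")
        R = A / scale
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("matrix rotation block is not orthogonal")
        return cls(np.array(_euler_angles(R)), M[:3, 3].copy(), scale)

    def inverse(self) -> "RigidScaleTransform":
        return RigidScaleTransform.from_matrix(np.linalg.inv(self.matrix))

    def to_params(self) -> np.ndarray:
        return np.concatenate([self.rotations, self.translations, [math.log(self.scale)]])

    @classmethod
    def from_params(cls, p: np.ndarray) -> "RigidScaleTransform":
        p = np.asarray(p, dtype=float)
        return cls(p[:3].copy(), p[3:6].copy(), float(math.exp(p[6])))

    def save_txt(self, path: str | Path) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.10f")

    @classmethod
    def load_txt(cls, path: str | Path) -> "RigidScaleTransform":
        return cls.from_matrix(np.loadtxt(str(path)))


# ---------------------------------------------------------------------------
# Resampling


def _pull_coords(
    vol: Volume,
    target_shape: Sequence[int],
    target_affine: np.ndarray,
    matrix: np.ndarray | None,
    displacement: np.ndarray | None,
) -> np.ndarray:
    """Voxel coordinates into ``vol`` for every target voxel (pull map)."""
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    world = target_affine[:3, :3] @ idx + target_affine[:3, 3:4]
    if displacement is not None:
        world = world + displacement.reshape(-1, 3).T
    if matrix is not None:
        inv = np.linalg.inv(matrix)
        world = inv[:3, :3] @ world + inv[:3, 3:4]
    Ainv = np.linalg.inv(vol.affine)
    return Ainv[:3, :3] @ world + Ainv[:3, 3:4]


def apply_transform(
    vol: Volume,
    t: RigidScaleTransform | None,
    field_mm: np.ndarray | None = None,
    target: Volume | None = None,
    order: int = 1,
) -> Volume:
    """Resample ``vol`` onto ``target``'s grid through ``t`` (and a field).

    ``t`` maps vol-world to target-world; ``field_mm`` is a per-target-voxel
    displacement (shape ``target.shape + (3,)``, mm) added to the target
    world position before the affine pull.  Outside-volume samples are 0.
    """
    if target is None:
        target = vol
    disp = None
    if field_mm is not None:
        field_mm = np.asarray(field_mm, dtype=float)
        if field_mm.shape != tuple(target.shape) + (3,):
            raise ValueError("displacement field shape does not match target grid")
        disp = field_mm
    coords = _pull_coords(vol, target.shape, target.affine,
                          t.matrix if t is not None else None, disp)
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=order, mode="constant", cval=0.0
    ).reshape(target.shape)
    return Volume(out, target.affine.copy())


def _downsample(vol: Volume, f: int) -> Volume:
    """Integer-factor downsample with matching anti-alias smoothing."""
    if f == 1:
        return vol
    data = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma=f / 2.0)
    new_shape = tuple(max(8, s // f) for s in vol.shape)
    idx = np.indices(new_shape, dtype=float).reshape(3, -1)
    fine_idx = idx * f + (f - 1) / 2.0
    out = ndimage.map_coordinates(data, fine_idx, order=1).reshape(new_shape)
    A = vol.affine.copy()
    shift = A[:3, :3] @ (np.full(3, (f - 1) / 2.0))
    A[:3, 3] += shift
    A[:3, :3] *= f
    return Volume(out, A)


# ---------------------------------------------------------------------------
# Brain extraction


def extract_brain(vol: Volume) -> Volume:
    """Binary brain mask by Otsu thresholding + morphology.

    Threshold maximizing between-class variance, largest connected
    component, morphological closing, hole filling; the result is a
    single connected foreground component on ``vol``'s grid.
    """
    data = np.asarray(vol.data, dtype=float)
    if float(data.var()) == 0.0:
        raise ValueError("cannot extract brain from a constant image")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("thresholding produced an empty foreground")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_closing(fg, structure=ndimage.generate_binary_structure(3, 2),
                                iterations=2)
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return vol.like(fg.astype(np.uint8))


# ---------------------------------------------------------------------------
# Bias-field correction


def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix (total degree <= order) on (N, 3) coords."""
    cols = []
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((x ** i) * (y ** j) * (z ** k))
    return np.stack(cols, axis=1)


def correct_bias(
    vol: Volume,
    mask: Volume,
    order: int = 3,
    on_nonpositive: str = "shift",
    n_classes: int = 3,
    n_iter: int = 4,
    smooth_mm: float = 10.0,
    trim_sd: float = 2.5,
) -> tuple[Volume, Volume]:
    """Estimate and remove a smooth multiplicative intensity bias field.

    The log-domain model is ``log I = log(tissue class mean) + log bias``,
    with the bias a 3-D polynomial of the given total degree on world
    coordinates normalized to [-1, 1] over the mask bounding box.  Because
    anatomy contrast dwarfs the bias, the fit is interleaved with a
    k-means tissue classification of the (current) corrected
    log-intensities: each iteration re-classifies, forms the per-voxel
    residual of log-intensity minus its class mean, suppresses
    fine-grained anatomy by trimming outliers and smoothing the residual
    map (normalized Gaussian convolution inside the 1-voxel-eroded mask),
    and refits the polynomial.  The fitted field is exponentiated, its
    log clamped to the in-mask range so it cannot blow up when
    extrapolated outside the brain, normalized to mean 1 over the mask,
    and divided out.  Returns ``(corrected, bias_field)``.
    """
    if not 1 <= order <= 4:
        raise ValueError("polynomial order must be in [1, 4]")
    m = np.asarray(mask.data) > 0
    if not m.any():
        raise ValueError("mask is empty")
    data = np.asarray(vol.data, dtype=float)
    vals = data[m]
    shift = 0.0
    if vals.min() <= 0:
        if on_nonpositive == "error":
            raise ValueError("nonpositive intensities inside mask")
        # shifted-log: raise everything so the in-mask minimum is positive
        shift = -vals.min() + 1e-3 * (vals.max() - vals.min() + 1e-12)

    mfit = ndimage.binary_erosion(m, iterations=1)
    if not mfit.any():
        mfit = m
    world = vol.world_coords().T  # (N, 3)
    in_world = world[m.reshape(-1)]
    lo, hi = in_world.min(axis=0), in_world.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def norm(w):
        return 2.0 * (w - lo) / span - 1.0

    Xf = _poly_design(norm(world[mfit.reshape(-1)]), order)
    Xall = _poly_design(norm(world), order)
    log_i = np.log(np.clip(data[mfit] + shift, 1e-12, None))
    sigma = [smooth_mm / v for v in vol.voxel_sizes]

    log_b = np.zeros_like(log_i)
    coef = np.zeros(Xf.shape[1])
    for _ in range(n_iter):
        corrected_log = log_i - log_b
        init = np.percentile(corrected_log, np.linspace(5, 95, n_classes))
        if np.unique(init).size < n_classes:  # (near-)constant image
            break
        centers, labels = kmeans2(corrected_log, init, minit="matrix", seed=0)
        resid = log_i - centers[labels]
        inlier = np.abs(resid - resid.mean()) < trim_sd * (resid.std() + 1e-12)
        r3 = np.zeros(vol.shape)
        w3 = np.zeros(vol.shape)
        r3[mfit] = resid * inlier
        w3[mfit] = inlier
        smr = ndimage.gaussian_filter(r3, sigma)
        smw = ndimage.gaussian_filter(w3, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(smw > 1e-3, smr / smw, 0.0)
        coef, *_ = np.linalg.lstsq(Xf, smoothed[mfit], rcond=None)
        log_b = Xf @ coef

    log_field = (Xall @ coef).reshape(vol.shape)
    if mfit.any():
        log_field = np.clip(log_field, log_field[mfit].min(), log_field[mfit].max())
    field = np.exp(log_field - log_field[m].mean())
    field /= field[m].mean()
    corrected = data / field
    return vol.like(corrected), vol.like(field)


# ---------------------------------------------------------------------------
# Affine registration (rigid + global scale)


@dataclass
class RegistrationConfig:
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    max_iter: tuple[int, ...] = (6, 4, 3)  # Powell outer iterations per level
    # search steps: radians, mm, log-scale — one Powell unit each
    step_rot: float = 0.02
    step_trans: float = 2.0
    step_logscale: float = 0.02
    xtol: float = 0.05
    ftol: float = 1e-6


@dataclass
class AffineResult:
    transform: RigidScaleTransform
    resampled: Volume
    similarity: float
    initial_similarity: float
    converged: bool


def _center_of_mass_world(vol: Volume) -> np.ndarray:
    data = np.clip(np.asarray(vol.data, dtype=float), 0, None)
    total = data.sum()
    if total <= 0:
        return vol.affine[:3, :3] @ ((np.asarray(vol.shape) - 1) / 2.0) + vol.affine[:3, 3]
    com_idx = np.array(ndimage.center_of_mass(data))
    return vol.affine[:3, :3] @ com_idx + vol.affine[:3, 3]


def _masked_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_affine(
    moving: Volume,
    template: Volume,
    template_mask: Volume,
    cfg: RegistrationConfig | None = None,
) -> AffineResult:
    """Recover the 7-DOF transform aligning ``moving`` to ``template``.

    Maximizes normalized cross-correlation inside ``template_mask`` over a
    coarse-to-fine pyramid with Powell's method; initialization aligns the
    intensity centers of mass at unit scale and zero rotation.  The final
    similarity never falls below the initialization's (best-so-far is
    kept), and a non-converged search returns its best point with
    ``converged=False``.
    """
    cfg = cfg or RegistrationConfig()
    if float(np.asarray(moving.data).var()) == 0 or float(np.asarray(template.data).var()) == 0:
        raise ValueError("cannot register constant images")

    com_m = _center_of_mass_world(moving)
    com_t = _center_of_mass_world(template)
    p0 = RigidScaleTransform(translations=com_t - com_m).to_params()

    steps = np.array([cfg.step_rot] * 3 + [cfg.step_trans] * 3 + [cfg.step_logscale])
    mov_data = np.asarray(moving.data, dtype=float)
    Ainv_m = np.linalg.inv(moving.affine)

    p = p0.copy()
    converged = True
    for factor, maxiter in zip(cfg.pyramid_factors, cfg.max_iter):
        tpl_l = _downsample(template, factor)
        msk_l = _downsample(
            Volume(np.asarray(template_mask.data, dtype=float), template_mask.affine), factor
        )
        mov_l = _downsample(moving, factor) if factor > 1 else moving
        mov_l_data = np.asarray(mov_l.data, dtype=float)
        Ainv_l = np.linalg.inv(mov_l.affine)
        sel = np.asarray(msk_l.data) > 0.5
        if sel.sum() < 32:
            continue
        idx = np.argwhere(sel).T.astype(float)
        world = tpl_l.affine[:3, :3] @ idx + tpl_l.affine[:3, 3:4]
        world_h = np.vstack([world, np.ones(world.shape[1])])
        tpl_vals = np.asarray(tpl_l.data, dtype=float)[sel]

        def neg_ncc(q, _world_h=world_h, _tpl=tpl_vals, _mov=mov_l_data, _Ainv=Ainv_l):
            t = RigidScaleTransform.from_params(p0 + q * steps)
            C = _Ainv @ np.linalg.inv(t.matrix)
            coords = (C @ _world_h)[:3]
            samp = ndimage.map_coordinates(_mov, coords, order=1, mode="constant", cval=0.0)
            return -_masked_ncc(samp, _tpl)

        q0 = (p - p0) / steps
        res = optimize.minimize(
            neg_ncc,
            q0,
            method="Powell",
            options={"maxiter": maxiter, "xtol": cfg.xtol, "ftol": cfg.ftol},
        )
        if -res.fun >= -neg_ncc(q0):
            p = p0 + res.x * steps
        converged = converged and bool(res.success)
        _ = Ainv_m  # full-resolution inverse kept for clarity

    transform = RigidScaleTransform.from_params(p)
    resampled = apply_transform(moving, transform, target=template)
    sel = np.asarray(template_mask.data) > 0
    final_sim = _masked_ncc(np.asarray(resampled.data)[sel], np.asarray(template.data, dtype=float)[sel])
    init_t = RigidScaleTransform.from_params(p0)
    init_res = apply_transform(moving, init_t, target=template)
    init_sim = _masked_ncc(np.asarray(init_res.data)[sel], np.asarray(template.data, dtype=float)[sel])
    if final_sim < init_sim:
        transform, resampled, final_sim = init_t, init_res, init_sim
    return AffineResult(transform, resampled, final_sim, init_sim, converged)


# ---------------------------------------------------------------------------
# Nonlinear (demons-style) registration


@dataclass
class NonlinearConfig:
    pyramid_factors: tuple[int, ...] = (2, 1)
    iterations: tuple[int, ...] = (60, 30)
    smooth_sigma_mm: float = 3.0   # Gaussian regularization of the field
    max_step_mm: float = 1.0       # per-iteration update clamp
    max_displacement_mm: float = 12.0


def register_nonlinear(
    affine_registered: Volume,
    template: Volume,
    cfg: NonlinearConfig | None = None,
) -> np.ndarray:
    """Small-deformation demons-style warp of an affinely aligned image.

    Iterates a gradient-driven intensity-matching update with Gaussian
    smoothing of the displacement field after every iteration and a hard
    clamp on the maximum displacement; coarse-to-fine over the pyramid.
    Returns the displacement field on the template grid, shape
    ``template.shape + (3,)``, in mm (pull convention: the registered image
    samples the input at ``x + u(x)``).
    """
    cfg = cfg or NonlinearConfig()
    if tuple(affine_registered.shape) != tuple(template.shape):
        raise ValueError("input must already be resampled onto the template grid")

    u = None  # (3,) + shape, mm, on current level grid
    for factor, n_iter in zip(cfg.pyramid_factors, cfg.iterations):
        tpl_l = _downsample(template, factor)
        mov_l = _downsample(affine_registered, factor)
        vox = tpl_l.voxel_sizes
        fixed = np.asarray(tpl_l.data, dtype=float)
        movd = np.asarray(mov_l.data, dtype=float)
        scale_i = float(np.abs(fixed).max()) or 1.0
        fixed = fixed / scale_i
        movd = movd / scale_i
        shape = fixed.shape
        base = np.indices(shape, dtype=float)

        if u is None:
            u = np.zeros((3,) + shape)
        else:
            zoom = [s2 / s1 for s1, s2 in zip(u.shape[1:], shape)]
            u = np.stack([ndimage.zoom(u[c], zoom, order=1) for c in range(3)])

        sigma_vox = [cfg.smooth_sigma_mm / v for v in vox]
        for _ in range(n_iter):
            coords = base + u / vox[:, None, None, None]
            warped = ndimage.map_coordinates(movd, coords.reshape(3, -1), order=1,
                                             mode="constant", cval=0.0).reshape(shape)
            diff = fixed - warped
            grad = np.stack(np.gradient(warped, *vox))
            gnorm2 = (grad ** 2).sum(axis=0)
            denom = gnorm2 + diff ** 2 / float(vox.mean()) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                step = np.where(denom > 1e-9, diff / denom, 0.0)
            upd = grad * step
            mag = np.sqrt((upd ** 2).sum(axis=0))
            over = mag > cfg.max_step_mm
            if over.any():
                upd[:, over] *= cfg.max_step_mm / mag[over]
            u = u + upd
            u = np.stack([ndimage.gaussian_filter(u[c], sigma_vox) for c in range(3)])
            mag = np.sqrt((u ** 2).sum(axis=0))
            over = mag > cfg.max_displacement_mm
            if over.any():
                u[:, over] *= cfg.max_displacement_mm / mag[over]

    if u.shape[1:] != tuple(template.shape):
        zoom = [s2 / s1 for s1, s2 in zip(u.shape[1:], template.shape)]
        u = np.stack([ndimage.zoom(u[c], zoom, order=1) for c in range(3)])
    # (3, X, Y, Z) voxel-frame axes displacement -> (X, Y, Z, 3) world mm.
    # Grids here are axis-aligned, so voxel axes coincide with world axes.
    return np.moveaxis(u, 0, -1)


def warp_volume(vol: Volume, field_mm: np.ndarray) -> Volume:
    """Apply a same-grid displacement field (pull convention)."""
    return apply_transform(vol, None, field_mm=field_mm, target=vol)


def jacobian_determinant(field_mm: np.ndarray, voxel_sizes: Sequence[float]) -> np.ndarray:
    """Finite-difference Jacobian determinant of ``x -> x + u(x)``."""
    field_mm = np.asarray(field_mm, dtype=float)
    J = np.empty(field_mm.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(field_mm[..., comp], *voxel_sizes)
        for ax in range(3):
            J[..., comp, ax] = grads[ax]
    J += np.eye(3)
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Catalog-integrated pipeline


@dataclass
class PreprocessResult:
    image_id: int
    mode: str
    paths: dict[str, str]
    similarity: float
    qc_ready: bool = True


def run_pipeline(
    catalog: CatalogHandle,
    image_id: int,
    template: Volume,
    template_mask: Volume,
    mode: str = "affine",
    store_root: str | Path = ".",
    bias_order: int = 3,
    cfg: RegistrationConfig | None = None,
    nl_cfg: NonlinearConfig | None = None,
    save_bias_field: bool = False,
) -> PreprocessResult:
    """Run extraction -> bias correction -> registration for one image.

    Artifacts (brain mask, registered image, 4x4 affine text matrix, bias
    field, and the warp for nonlinear mode) are written under
    ``store_root/<image_id>/<mode>/`` and registered in the catalog, one
    :class:`~mrifuse.catalog.PreprocessFileRecord` per file; the image's
    ``preprocessing_status`` is updated.  Rerunning the same mode replaces
    the prior artifacts.  Catalog writes are atomic.
    """
    if mode not in ("affine", "nonlinear"):
        raise ValueError("mode must be 'affine' or 'nonlinear'")
    row = catalog.fetch("image", image_id)
    if row is None:
        raise ValueError(f"no image with id {image_id}")
    src = Path(row["file_path"])
    if not src.exists():
        raise FileNotFoundError(f"image file not readable: {src}")
    vol = Volume.from_nifti(src)

    mask = extract_brain(vol)
    corrected, bias = correct_bias(vol, mask, order=bias_order)
    aff = register_affine(corrected, template, template_mask, cfg)
    registered = aff.resampled
    similarity = aff.similarity

    out_dir = Path(store_root) / str(image_id) / mode
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    field = None
    if mode == "nonlinear":
        field = register_nonlinear(registered, template, nl_cfg)
        registered = apply_transform(corrected, aff.transform, field_mm=field, target=template)
        sel = np.asarray(template_mask.data) > 0
        similarity = _masked_ncc(
            np.asarray(registered.data)[sel], np.asarray(template.data, dtype=float)[sel]
        )

    mask.to_nifti(out_dir / "brain_mask.nii.gz")
    paths["brain_mask"] = str(out_dir / "brain_mask.nii.gz")
    registered.to_nifti(out_dir / "registered_image.nii.gz")
    paths["registered_image"] = str(out_dir / "registered_image.nii.gz")
    aff.transform.save_txt(out_dir / "affine_matrix.txt")
    paths["affine_matrix"] = str(out_dir / "affine_matrix.txt")
    if save_bias_field:
        bias.to_nifti(out_dir / "bias_field.nii.gz")
        paths["bias_field"] = str(out_dir / "bias_field.nii.gz")
    if field is not None:
        nib.save(
            nib.Nifti1Image(np.asarray(field, dtype=np.float32), template.affine),
            str(out_dir / "nonlinear_warp.nii.gz"),
        )
        paths["nonlinear_warp"] = str(out_dir / "nonlinear_warp.nii.gz")

    task_id = catalog.lookup_id("preprocess_task", description=mode)
    conn = catalog.connection
    try:
        conn.execute(
            "DELETE FROM preprocess_file WHERE image_id=? AND task_id=?",
            (image_id, task_id),
        )
        for ftype, p in paths.items():
            ft_id = catalog.lookup_id("file_type", name=ftype)
            conn.execute(
                "INSERT INTO preprocess_file (image_id, task_id, file_type_id, path) "
                "VALUES (?,?,?,?)",
                (image_id, task_id, ft_id, p),
            )
        conn.execute(
            "UPDATE image SET preprocessing_status=? WHERE id=?", (mode, image_id)
        )
        conn.commit()
    except Exception:
        conn.rollback()
        raise
    return PreprocessResult(image_id, mode, paths, similarity)
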