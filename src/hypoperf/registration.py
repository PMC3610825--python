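"""Rigid-body registration, motion correction and affine resampling.

Transforms are expressed in world (mm) coordinates: a rotation about a
center point followed by a translation.  Applying a transform to an image
*moves its content* by the transform — ``resample(vol, T)`` samples the
input at ``T^{-1}(x)`` so that a feature at ``x0`` ends up at ``T(x0)``.

Registration minimizes the in-mask mean squared intensity difference with a
deterministic coordinate-wise golden-section search over the 6 rigid
parameters, run coarse-to-fine on a 2-level Gaussian pyramid.  Intramodal
(same contrast) alignment is the intended use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "resample",
    "rigid_register",
    "motion_correct",
]


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid mapping: rotation (Euler x-y-z, degrees, extrinsic
    fixed axes) about ``center_mm``, then translation (mm).

    ``center_mm`` of ``None`` means "the volume center", resolved against a
    concrete grid at application time; composition and inversion require an
    explicit center (or a pure translation, for which the center is moot).
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_deg", tuple(float(v) for v in self.rotation_deg))
        object.__setattr__(self, "translation_mm", tuple(float(v) for v in self.translation_mm))
        if self.center_mm is not None:
            object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))

    # -- basic predicates -------------------------------------------------
    @property
    def is_pure_translation(self) -> bool:
        return all(abs(a) < 1e-12 for a in self.rotation_deg)

    def resolved(self, grid_shape: Sequence[int], voxel_size_mm: Sequence[float]) -> "RigidTransform":
        """Return a copy whose center is pinned to the given volume center."""
        if self.center_mm is not None:
            return self
        center = (np.asarray(grid_shape, float) - 1.0) / 2.0 * np.asarray(voxel_size_mm, float)
        return RigidTransform(self.rotation_deg, self.translation_mm, tuple(center))

    def _center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, float)
        if self.is_pure_translation:
            return np.zeros(3)
        raise ValueError(
            "transform with rotation needs an explicit center for matrix "
            "algebra; use .resolved(grid_shape, voxel_size_mm) first"
        )

    # -- matrix algebra ---------------------------------------------------
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix in mm space: x -> R (x - c) + c + t."""
        c = self._center()
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()
        t = np.asarray(self.translation_mm, float)
        out = np.eye(4)
        out[:3, :3] = rot
        out[:3, 3] = c + t - rot @ c
        return out

    @classmethod
    def from_matrix(cls, mat: np.ndarray, center_mm: Sequence[float]) -> "RigidTransform":
        mat = np.asarray(mat, float)
        c = np.asarray(center_mm, float)
        rot = mat[:3, :3]
        angles = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        # b = c + t - R c  =>  t = b - c + R c
        t = mat[:3, 3] - c + rot @ c
        return cls(tuple(angles), tuple(t), tuple(c))

    def inverse(self) -> "RigidTransform":
        c = self._center()
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), c)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        c = self._center()
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(), c)

    def as_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": None if self.center_mm is None else list(self.center_mm),
            "convention": "euler-xyz-extrinsic-deg, rotate-about-center-then-translate",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        center = d.get("center_mm")
        return cls(
            tuple(d["rotation_deg"]),
            tuple(d["translation_mm"]),
            None if center is None else tuple(center),
        )


def resample(
    volume: np.ndarray,
    transform: "RigidTransform | np.ndarray",
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
    order: int = 1,
    out_shape: Sequence[int] | None = None,
) -> np.ndarray:
    """Resample a 3D volume under a rigid transform or a 4x4 mm-space affine.

    ``order=1`` is trilinear (intensity images), ``order=0`` nearest
    neighbour (label volumes), ``order=3`` cubic B-spline (when preserving
    fine contrast through repeated resampling matters).  Integer-typed
    inputs must use ``order=0``.  Out-of-field voxels are zero-filled.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("resample expects a 3D volume")
    if np.issubdtype(volume.dtype, np.integer) and order != 0:
        raise ValueError(
            "integer label volumes must be resampled with nearest-neighbour "
            "(order=0); trilinear would invent fractional labels"
        )
    if order not in (0, 1, 3):
        raise ValueError("order must be 0 (nearest), 1 (trilinear) or 3 (cubic)")
    if out_shape is None:
        out_shape = volume.shape
    vs = np.asarray(voxel_size_mm, float)
    if isinstance(transform, RigidTransform):
        mat = transform.resolved(out_shape, vs).matrix()
    else:
        mat = np.asarray(transform, float)
        if mat.shape != (4, 4):
            raise ValueError("affine transform must be a 4x4 matrix")
    sampling = np.linalg.inv(mat)  # maps output world coords -> input world coords
    scale = np.diag(vs)
    scale_inv = np.diag(1.0 / vs)
    m_vox = scale_inv @ sampling[:3, :3] @ scale
    off_vox = scale_inv @ sampling[:3, 3]
    return ndimage.affine_transform(
        volume,
        m_vox,
        offset=off_vox,
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


# Coarse-to-fine schedule: (smoothing sigma in mm, translation half-span in
# mm, rotation half-span in degrees or None to freeze rotations, sweeps).
# Sigmas are isotropic in world units — an anisotropic (per-voxel) kernel
# would not commute with rotation and would bias angles toward zero.  The
# coarse level captures large translations but its rotation landscape is
# dominated by residual interpolation artifacts, so rotations are searched
# only at the fine level; repeated sweeps let the cumulative angle exceed
# the per-sweep span.
_PYRAMID = (
    (6.0, 12.0, None, 2),
    (3.0, 4.0, 3.0, 3),
)
_XATOL = 0.02  # mm / degrees resolution of the line searches


def rigid_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> RigidTransform:
    """Find the rigid transform aligning ``moving`` onto ``fixed``.

    Minimizes the (optionally masked) mean squared intensity difference of
    ``resample(moving, T)`` against ``fixed`` by cyclic bounded
    golden-section line searches over the 6 parameters, from an identity
    start, on a smoothed-then-full-resolution schedule.  Deterministic.

    If no parameter set improves on the identity transform, the identity is
    returned and a warning is emitted.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a grid")
    vs = np.asarray(voxel_size_mm, float)
    center = tuple((np.asarray(moving.shape, float) - 1.0) / 2.0 * vs)
    flat_mask = None if mask is None else np.asarray(mask, bool)
    scale = np.diag(vs)
    scale_inv = np.diag(1.0 / vs)

    def sample(coeffs: np.ndarray, params: np.ndarray) -> np.ndarray:
        # Cubic-spline sampling of precomputed coefficients: trilinear
        # interpolation on a coarse anisotropic grid loses enough signal to
        # swamp the alignment cost of small rotations.
        t = RigidTransform(tuple(params[3:]), tuple(params[:3]), center)
        sampling = np.linalg.inv(t.matrix())
        return ndimage.affine_transform(
            coeffs,
            scale_inv @ sampling[:3, :3] @ scale,
            offset=scale_inv @ sampling[:3, 3],
            order=3,
            prefilter=False,
            mode="constant",
            cval=0.0,
        )

    def cost_on(mov_c: np.ndarray, fix_c: np.ndarray, params: np.ndarray) -> float:
        # Symmetric metric: each side is resampled by half the candidate
        # transform, so both carry one interpolation pass.  An asymmetric
        # metric (resample moving only) pays an interpolation-blur penalty
        # that grows with the transform and biases the optimum toward
        # identity.
        half = params / 2.0
        diff = sample(mov_c, half) - sample(fix_c, -half)
        if flat_mask is not None:
            diff = diff[flat_mask]
        return float(np.mean(diff * diff))

    params = np.zeros(6)
    mov_c = fix_c = moving  # overwritten below; keeps the final-level pair in scope
    for sigma_mm, t_span, r_span, sweeps in _PYRAMID:
        sigma_vox = sigma_mm / vs
        mov_c = ndimage.spline_filter(ndimage.gaussian_filter(moving, sigma_vox), order=3)
        fix_c = ndimage.spline_filter(ndimage.gaussian_filter(fixed, sigma_vox), order=3)
        active = range(3) if r_span is None else range(6)
        for _ in range(sweeps):
            for i in active:
                span = t_span if i < 3 else r_span
                current = cost_on(mov_c, fix_c, params)

                def line(v: float, i: int = i) -> float:
                    trial = params.copy()
                    trial[i] = v
                    return cost_on(mov_c, fix_c, trial)

                res = minimize_scalar(
                    line,
                    bounds=(params[i] - span, params[i] + span),
                    method="bounded",
                    options={"xatol": _XATOL},
                )
                if res.fun < current:
                    params[i] = res.x

    # Judge improvement on the finest pyramid level: raw sharp-edged volumes
    # carry interpolation artifacts that can mask a correct alignment.
    identity_cost = cost_on(mov_c, fix_c, np.zeros(6))
    final_cost = cost_on(mov_c, fix_c, params)
    if not final_cost < identity_cost - 1e-15:
        if np.any(np.abs(params) > _XATOL):
            warnings.warn(
                "rigid_register failed to improve on the identity transform; "
                "returning identity",
                RuntimeWarning,
                stacklevel=2,
            )
        return RigidTransform(center_mm=center)
    # The symmetric metric parametrizes the alignment as half-transforms on
    # each side; the full moving->fixed transform is the half composed twice.
    half = RigidTransform(tuple(params[3:] / 2.0), tuple(params[:3] / 2.0), center)
    return half.compose(half)


def motion_correct(
    series,
    reference: str = "mean",
):
    """Register every frame of an ASL series to a common reference.

    ``reference`` is either ``"mean"`` (the temporal mean image, robust for
    a series with ~half tag and ~half control frames whose contrast differs
    by well under 1%) or ``"first_frame"``.

    Returns ``(corrected_series, motions)`` where ``motions[k]`` is the
    estimated head motion of frame ``k`` (the inverse of the correcting
    transform), directly comparable to any injected motion.
    """
    from .asl_quant import AslSeries  # local import to avoid a cycle

    if series.n_frames < 2:
        raise ValueError("motion correction needs at least 2 frames")
    if reference not in ("mean", "first_frame"):
        raise ValueError(f"unknown reference {reference!r}")
    vs = series.voxel_size_mm
    corrected = np.array(series.data)
    motions: list[RigidTransform] = []
    # With a "mean" reference the first-pass target is smeared by the very
    # motion being estimated, so the mean is rebuilt from the corrected
    # frames and the original frames are registered to it once more.
    n_passes = 2 if reference == "mean" else 1
    for _ in range(n_passes):
        ref = corrected.mean(axis=-1) if reference == "mean" else series.frame(0)
        motions = []
        for k in range(series.n_frames):
            t = rigid_register(series.frame(k), ref, voxel_size_mm=vs)
            corrected[..., k] = resample(series.frame(k), t, vs)
            motions.append(t.inverse())
    out = AslSeries(
        data=corrected,
        frame_labels=series.frame_labels,
        acq=series.acq,
        affine=np.array(series.affine),
    )
    return out, motions
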