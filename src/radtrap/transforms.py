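"""Spatial transforms in the resampling (pull-back) convention.

A transform maps points of the *fixed* (CT) space into the *moving* (MRI)
space; resampling a moving image onto the fixed grid evaluates it at the
mapped points. The two-stage MRI-to-CT alignment composes a rigid transform
``T_r`` with a deformation ``d`` supported near the prostate as

    psi(x) = T_r(x + d(x)),

i.e. the deformation acts in the fixed space before the rigid map, which is
exactly how a deformable stage run on the rigidly pre-aligned moving image
composes with the rigid stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import VolumeGrid, read_volume, write_volume


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation matrix from extrinsic x-y-z Euler angles in degrees."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about ``center`` followed by a translation, in mm."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: Tuple[float, float, float]
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6) or np.linalg.det(rot) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tuple(float(t) for t in self.translation))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), (0.0, 0.0, 0.0))

    @classmethod
    def from_params(cls, angles_deg, translation, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(rotation_matrix(angles_deg), tuple(translation), tuple(center))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of physical points."""
        pts = np.asarray(points, dtype=float)
        ctr = np.asarray(self.center)
        return (pts - ctr) @ self.rotation.T + ctr + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        # x' = R(x-c)+c+t  =>  x = R^T(x'-(c+t)) + (c+t) - t
        ctr = np.asarray(self.center)
        t = np.asarray(self.translation)
        return RigidTransform(self.rotation.T, tuple(-t), tuple(ctr + t))

    def euler_angles_deg(self) -> Tuple[float, float, float]:
        """Extrinsic x-y-z Euler angles of the rotation, degrees."""
        r = self.rotation
        ay = np.arcsin(np.clip(-r[2, 0], -1, 1))
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
        return tuple(np.rad2deg((ax, ay, az)))


@dataclass
class DisplacementTransform:
    """Dense displacement field (mm) on a stated grid geometry.

    ``field`` has shape ``grid.shape + (3,)``. Points are displaced by the
    linearly interpolated field; the field is zero outside its grid.
    """

    field: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    support: Optional[np.ndarray] = None

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float)
        if self.field.ndim != 4 or self.field.shape[3] != 3:
            raise ValueError("field must have shape (nx, ny, nz, 3)")

    @classmethod
    def zero(cls, like: VolumeGrid) -> "DisplacementTransform":
        return cls(np.zeros(like.shape + (3,)), like.spacing, like.origin)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        out = np.empty_like(pts)
        for a in range(3):
            out[:, a] = ndimage.map_coordinates(
                self.field[..., a], coords.T, order=1, mode="constant", cval=0.0
            )
        return out.reshape(np.shape(points))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement_at(points)

    def max_displacement(self, mask: Optional[np.ndarray] = None) -> float:
        mag = np.linalg.norm(self.field, axis=-1)
        if mask is not None:
            mag = mag[mask]
        return float(mag.max()) if mag.size else 0.0


@dataclass
class CompositeTransform:
    """Rigid-then-deformable mapping ``psi(x) = T_r(x + d(x))``."""

    rigid: RigidTransform
    deformation: Optional[DisplacementTransform] = None

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.deformation is not None:
            pts = self.deformation.apply(pts)
        return self.rigid.apply(pts)


def jacobian_determinant(field: np.ndarray, spacing) -> np.ndarray:
    """Determinant of the Jacobian of ``x -> x + field(x)`` per voxel.

    Positive everywhere means the deformation does not fold.
    """
    field = np.asarray(field, dtype=float)
    jac = np.empty(field.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(field[..., comp], *spacing)
        for axis in range(3):
            jac[..., comp, axis] = grads[axis]
    jac += np.eye(3)
    return np.linalg.det(jac)


def resample_through_transform(
    moving: VolumeGrid,
    transform,
    reference: VolumeGrid,
    interpolation: str = "linear",
    cval: float = 0.0,
) -> VolumeGrid:
    """Resample ``moving`` onto ``reference`` through a point transform.

    ``transform`` must expose ``apply(points)`` mapping reference-space
    physical points to moving-space physical points.
    """
    xs, ys, zs = reference.physical_grid()
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    mapped = transform.apply(pts)
    coords = (mapped - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    order = 1 if interpolation == "linear" else 0
    vals = ndimage.map_coordinates(
        moving.values.astype(float), coords.T, order=order, mode="constant", cval=cval
    )
    return VolumeGrid(vals.reshape(reference.shape), reference.spacing, reference.origin, moving.modality)


# ---------------------------------------------------------------------------
# Serialization (text rigid parameters + NIfTI displacement field)


def write_rigid(transform: RigidTransform, path) -> None:
    ax, ay, az = transform.euler_angles_deg()
    lines = [
        f"angles_deg = {ax:.10g} {ay:.10g} {az:.10g}",
        "translation_mm = " + " ".join(f"{t:.10g}" for t in transform.translation),
        "center_mm = " + " ".join(f"{c:.10g}" for c in transform.center),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rigid(path) -> RigidTransform:
    vals = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, rhs = line.split("=", 1)
            vals[key.strip()] = [float(x) for x in rhs.split()]
    return RigidTransform.from_params(vals["angles_deg"], vals["translation_mm"], vals["center_mm"])


def write_displacement(transform: DisplacementTransform, path) -> None:
    """Write the displacement field as a 4D NIfTI (last axis = component)."""
    import nibabel as nib

    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = transform.spacing
    aff[:3, 3] = transform.origin
    nib.save(nib.Nifti1Image(transform.field, aff), str(path))


def read_displacement(path) -> DisplacementTransform:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    return DisplacementTransform(data, tuple(np.diag(aff[:3, :3])), tuple(aff[:3, 3]))
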