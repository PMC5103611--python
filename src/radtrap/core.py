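"""Volume and structure-set data model shared by all pipeline stages.

Conventions
-----------
Arrays are indexed ``values[i, j, k]`` with axis 0 = x (fastest varying on
disk), axis 1 = y, axis 2 = z (slice axis). Voxel indices are 0-based and
physical coordinates are ``origin + index * spacing`` in millimetres; only
axis-aligned geometries are supported and oblique orientation matrices are
rejected on read rather than silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

MODALITIES = ("T2w_small_FOV", "T2w_large_FOV", "ADC", "CT", "DOSE", "PROB", "MASK")


class GeometryError(ValueError):
    """Raised when grids are degenerate or mismatched."""


class DimensionalityError(ValueError):
    """Raised for non-3D images."""


class FormatError(ValueError):
    """Raised for unreadable or unsupported files."""


class EmptyStructureError(ValueError):
    """Raised when a required structure mask is empty."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar image with axis-aligned physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    spacing : tuple of float
        Per-axis voxel size in mm; all components > 0.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    modality : str
        One of :data:`MODALITIES`.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "T2w_small_FOV"

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {values.ndim}D with shape {values.shape}"
            )
        if any(s < 2 for s in values.shape):
            raise GeometryError(f"grid must have >= 2 voxels per axis, got {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be 3 positive components, got {spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.modality == "PROB":
            v = values[np.isfinite(values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("PROB volumes must have values in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, modality: Optional[str] = None) -> "VolumeGrid":
        """Return a copy carrying new values on the same grid."""
        return VolumeGrid(values, self.spacing, self.origin, modality or self.modality)

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def voxel_to_physical(self, index) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_voxel(self, point) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical`; exact for axis-aligned grids."""
        pt = np.asarray(point, dtype=float)
        return (pt - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def physical_grid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of every voxel, one array per axis."""
        idx = np.indices(self.shape, dtype=float)
        sp = np.asarray(self.spacing)
        og = np.asarray(self.origin)
        return tuple(og[a] + idx[a] * sp[a] for a in range(3))


@dataclass
class VoxelIndex:
    """Integer voxel coordinates within a grid."""

    i: int
    j: int
    k: int

    def as_tuple(self) -> Tuple[int, int, int]:
        return (self.i, self.j, self.k)


@dataclass
class StructureSet:
    """Named binary masks sharing one reference geometry.

    Masks are stored as boolean arrays aligned to ``reference`` (a
    :class:`VolumeGrid` providing shape/spacing/origin). When both a lesion
    and a prostate mask are present the lesion must lie inside the prostate.
    """

    reference: VolumeGrid
    structures: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name in list(self.structures):
            self.structures[name] = self._validate(name, self.structures[name])
        self._check_containment()

    def _validate(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.reference.shape:
            raise GeometryError(
                f"structure {name!r} shape {mask.shape} != reference {self.reference.shape}"
            )
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"structure {name!r} is not strictly binary (values {uniq[:5]}...)")
        return mask.astype(bool)

    def _check_containment(self):
        if "lesion" in self.structures and "prostate" in self.structures:
            if np.any(self.structures["lesion"] & ~self.structures["prostate"]):
                raise ValueError("lesion mask must be contained in the prostate mask")

    def add(self, name: str, mask: np.ndarray) -> None:
        self.structures[name] = self._validate(name, mask)
        self._check_containment()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def names(self) -> Iterable[str]:
        return self.structures.keys()

    def mask_volume(self, name: str, modality: str = "MASK") -> VolumeGrid:
        return self.reference.with_values(self.structures[name].astype(np.uint8), modality)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume as NIfTI-1 with an axis-aligned affine."""
    img = nib.Nifti1Image(np.asarray(volume.values), _affine_from_geometry(volume.spacing, volume.origin))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path, modality: str = "T2w_small_FOV") -> VolumeGrid:
    """Read a 3D NIfTI image without rescaling intensities.

    Raises
    ------
    FormatError
        If the file is missing or not a readable NIfTI image.
    DimensionalityError
        If the image is not 3D.
    GeometryError
        If the orientation matrix is not axis-aligned with positive spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got {data.ndim}D")
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise GeometryError(f"{path}: oblique orientation matrices are not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: expected positive diagonal spacing, got {spacing}")
    return VolumeGrid(data, tuple(spacing), tuple(aff[:3, 3]), modality)


def write_structure_set(structures: StructureSet, directory, prefix: str = "") -> Path:
    """Write one uint8 NIfTI per structure plus a plain-text manifest.

    Returns the manifest path. The manifest holds ``structure<TAB>filename``
    lines so a run is auditable from the filesystem alone.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / f"{prefix}structures.txt"
    lines = []
    for name in structures.names():
        fname = f"{prefix}{name}.nii.gz"
        write_volume(structures.mask_volume(name), directory / fname)
        lines.append(f"{name}\t{fname}")
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_structure_set(manifest_path) -> StructureSet:
    """Read a structure set written by :func:`write_structure_set`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"no such manifest: {manifest_path}")
    reference = None
    masks = {}
    for line in manifest_path.read_text().splitlines():
        if not line.strip():
            continue
        name, fname = line.split("\t")
        vol = read_volume(manifest_path.parent / fname, "MASK")
        if reference is None:
            reference = vol
        masks[name] = vol.values > 0.5
    if reference is None:
        raise FormatError(f"empty manifest: {manifest_path}")
    return StructureSet(reference=reference, structures=masks)


# ---------------------------------------------------------------------------
# Geometry operations


def resample_to_grid(moving: VolumeGrid, reference: VolumeGrid, interpolation: str = "linear") -> VolumeGrid:
    """Resample ``moving`` onto the geometry of ``reference``.

    ``interpolation`` is ``"linear"`` or ``"nearest"``; nearest preserves the
    value set of label volumes. Points outside the moving grid take the
    nearest-edge value (border replication).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    if any(s < 2 for s in reference.shape):
        raise GeometryError("degenerate reference grid")
    if moving.same_geometry(reference):
        return reference.with_values(moving.values.copy(), moving.modality)
    xs, ys, zs = reference.physical_grid()
    coords = np.stack(
        [
            (xs - moving.origin[0]) / moving.spacing[0],
            (ys - moving.origin[1]) / moving.spacing[1],
            (zs - moving.origin[2]) / moving.spacing[2],
        ]
    )
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        moving.values.astype(float), coords, order=order, mode="nearest"
    )
    return VolumeGrid(out, reference.spacing, reference.origin, moving.modality)


def mask_bounding_box(mask: np.ndarray) -> Tuple[Tuple[int, int], ...]:
    """Inclusive per-axis (lo, hi) bounds of the True voxels."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyStructureError("mask is empty")
    bounds = []
    for axis in range(mask.ndim):
        proj = mask.any(axis=tuple(a for a in range(mask.ndim) if a != axis))
        nz = np.nonzero(proj)[0]
        bounds.append((int(nz[0]), int(nz[-1])))
    return tuple(bounds)


def crop_to_structure(volume: VolumeGrid, mask: np.ndarray, margin_mm: float = 0.0) -> VolumeGrid:
    """Crop ``volume`` to the mask bounding box dilated by ``margin_mm``.

    The margin is converted per axis to ``ceil(margin / spacing)`` voxels and
    the box is clipped to the volume extent; no mask voxel is ever discarded.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise GeometryError("mask is not aligned with the volume")
    bounds = mask_bounding_box(mask)
    lo, hi = [], []
    for axis, (b0, b1) in enumerate(bounds):
        pad = int(np.ceil(margin_mm / volume.spacing[axis])) if margin_mm else 0
        lo.append(max(0, b0 - pad))
        hi.append(min(volume.shape[axis] - 1, b1 + pad))
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    new_origin = tuple(volume.origin[a] + lo[a] * volume.spacing[a] for a in range(3))
    vals = volume.values[sl]
    if any(s < 2 for s in vals.shape):  # keep VolumeGrid invariant on tiny boxes
        return _CroppedBox(vals, volume.spacing, new_origin, volume.modality)
    return VolumeGrid(vals, volume.spacing, new_origin, volume.modality)


@dataclass(frozen=True)
class _CroppedBox:
    """Degenerate (sub-2-voxel) crop result; carries the same fields as VolumeGrid."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    modality: str

    @property
    def shape(self):
        return self.values.shape
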