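"""Binary segmentation mask I/O with explicit physical geometry.

All masks are reoriented on load into a single internal patient-axis
convention: world axes are **LAS** (+x toward the patient's left,
+y anterior, +z superior) and voxel axes are permuted/flipped so that
voxel axis 0 also increases toward the patient's left.  Downstream code
relies on a deterministic "patient left" direction: the pancreatic tail
lies toward the patient's left, which fixes the orientation of the
centerline.

Voxel indices are 0-based and world coordinates refer to voxel centers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGeometry",
    "VoxelMask",
    "read_mask",
    "write_mask",
    "voxel_to_world",
    "world_to_voxel",
]

_LAS_FLIP = np.diag([-1.0, 1.0, 1.0, 1.0])  # RAS world <-> LAS world


@dataclasses.dataclass(frozen=True)
class VolumeGeometry:
    """Physical geometry of a voxel grid.

    Parameters
    ----------
    spacing : (3,) array
        Per-axis voxel edge length in mm; all components positive.
    origin : (3,) array
        World position (mm, LAS) of the center of voxel (0, 0, 0).
    direction : (3, 3) array
        Orthonormal matrix whose columns map voxel axes to world axes.
    """

    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.all(spacing > 0):
            raise ValueError(f"spacing must be positive, got {spacing}")
        gram = direction.T @ direction
        if not np.allclose(gram, np.eye(3), atol=1e-6):
            raise ValueError("direction columns must be orthonormal")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> LAS world affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def close_to(self, other: "VolumeGeometry", tol: float = 1e-6) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclasses.dataclass
class VoxelMask:
    """3D binary label volume with physical geometry."""

    values: np.ndarray
    geometry: VolumeGeometry
    label_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError(f"mask must be 3D with positive dims, got shape {values.shape}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        self.values = values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def sum(self) -> int:
        return int(self.values.sum())


def check_pair(pancreas: VoxelMask, duct: VoxelMask) -> None:
    """Validate that a pancreas/duct pair belongs to one case."""
    if pancreas.shape != duct.shape:
        raise ValueError(
            f"mask shapes differ: pancreas {pancreas.shape} vs duct {duct.shape}"
        )
    if not pancreas.geometry.close_to(duct.geometry):
        raise ValueError("mask geometries differ between pancreas and duct")


def voxel_to_world(index: np.ndarray, geometry: VolumeGeometry) -> np.ndarray:
    """Map voxel indices to world points (mm).

    ``world = origin + direction @ (spacing * index)``.  Indices may be
    fractional or outside the array (extrapolated).  Accepts a single
    triple or an (N, 3) array.
    """
    idx = np.asarray(index, dtype=float)
    return geometry.origin + (idx * geometry.spacing) @ geometry.direction.T


def world_to_voxel(point: np.ndarray, geometry: VolumeGeometry) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; returns fractional voxel indices."""
    pts = np.asarray(point, dtype=float)
    return ((pts - geometry.origin) @ geometry.direction) / geometry.spacing


def _geometry_from_las_affine(affine: np.ndarray) -> VolumeGeometry:
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(f"degenerate voxel spacing in header: {spacing}")
    direction = rot / spacing[np.newaxis, :]
    return VolumeGeometry(spacing=spacing, origin=affine[:3, 3].copy(), direction=direction)


def _reorient_to_las(values: np.ndarray, ras_affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute/flip voxel axes to ('L','A','S') and return the LAS-world affine."""
    current = nib.orientations.io_orientation(ras_affine)
    target = nib.orientations.axcodes2ornt(("L", "A", "S"))
    transform = nib.orientations.ornt_transform(current, target)
    ras_affine = ras_affine @ nib.orientations.inv_ornt_aff(transform, values.shape)
    values = nib.orientations.apply_orientation(values, transform)
    return values, _LAS_FLIP @ ras_affine


def read_mask(path: str | Path, expected_label: str = "") -> VoxelMask:
    """Read a binary mask from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Any nonzero voxel is binarized to 1; the volume is reoriented into the
    internal LAS patient-axis convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    name = path.name.lower()
    if name.endswith((".mha", ".mhd")):
        values, ras_affine = _load_metaimage(path)
    else:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        if values.ndim == 4 and values.shape[3] == 1:
            values = values[..., 0]
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {values.shape} in {path}")
        ras_affine = img.affine
    values, las_affine = _reorient_to_las(np.asarray(values), np.asarray(ras_affine, dtype=float))
    geometry = _geometry_from_las_affine(las_affine)
    return VoxelMask(values=(values != 0).astype(np.uint8), geometry=geometry,
                     label_name=expected_label)


def _load_metaimage(path: Path) -> tuple[np.ndarray, np.ndarray]:
    import SimpleITK as sitk  # optional format; imported only when needed

    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D volume, got {img.GetDimension()}D in {path}")
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    lps_affine = np.eye(4)
    lps_affine[:3, :3] = direction * spacing[np.newaxis, :]
    lps_affine[:3, 3] = origin
    # LPS world -> RAS world so both readers share one internal path.
    ras_affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps_affine
    return values, ras_affine


def write_mask(mask: VoxelMask, path: str | Path) -> Path:
    """Write a mask as NIfTI; round-trips through :func:`read_mask`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    ras_affine = _LAS_FLIP @ mask.geometry.affine
    img = nib.Nifti1Image(mask.values.astype(np.uint8), ras_affine)
    nib.save(img, str(path))
    return path
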