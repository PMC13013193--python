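"""Volume data model, NIfTI I/O and affine resampling.

The package represents a scan as an :class:`ImageVolume`: a 3D scalar grid
plus a 4x4 voxel-to-physical (mm) affine, the same convention nibabel uses.
Binary annotations (substantia nigra, midbrain) are :class:`BinaryMask`
objects on the same grid. Physical-space mappings between volumes are
:class:`AffineTransform` matrices; by convention a transform returned by
registration maps *fixed*-space physical points into *moving*-space physical
points, which is exactly what resampling needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel-to-physical-space metadata.

    Parameters
    ----------
    data:
        ``(H, W, D)`` array of finite intensities (arbitrary units).
    affine:
        4x4 homogeneous matrix mapping voxel indices to physical mm
        coordinates (nibabel convention).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have at least one voxel")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """(sx, sy, sz) voxel size in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def center_physical(self) -> np.ndarray:
        """Physical coordinates of the grid centre."""
        c = (np.asarray(self.shape) - 1) / 2.0
        return (self.affine @ np.append(c, 1.0))[:3]


@dataclass
class BinaryMask(ImageVolume):
    """A {0,1} label volume on the grid of a paired :class:`ImageVolume`."""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.isin(data, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = data.astype(np.uint8)
        super().__post_init__()

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def physical_volume(self) -> float:
        """Foreground volume in mm^3 (count x voxel volume)."""
        return self.count() * self.voxel_volume


@dataclass
class AffineTransform:
    """4x4 homogeneous physical-space transform (mm coordinates).

    ``matrix`` maps fixed-space points to moving-space points. ``success``
    is False when a registration fell back to identity.
    """

    matrix: np.ndarray
    success: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1)):
            raise ValueError("last row of an affine transform must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("linear part of transform is singular")

    @classmethod
    def identity(cls, success: bool = True) -> "AffineTransform":
        return cls(np.eye(4), success=success)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), success=self.success)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix,
                               success=self.success and other.success)

    def save(self, path) -> None:
        """Write the 4x4 matrix as a plain-text file."""
        np.savetxt(str(path), self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


def read_volume(path, mask: bool = False):
    """Read a 3D NIfTI volume (.nii or .nii.gz).

    Set ``mask=True`` to get a :class:`BinaryMask` (values validated).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    cls = BinaryMask if mask else ImageVolume
    return cls(data=data, affine=np.asarray(img.affine))


def write_volume(v: ImageVolume, path) -> None:
    """Write a volume or mask as NIfTI; readable back by :func:`read_volume`."""
    data = v.data
    if isinstance(v, BinaryMask):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, v.affine), str(path))


def _reference_grid(reference) -> tuple[tuple[int, int, int], np.ndarray]:
    if isinstance(reference, ImageVolume):
        return reference.shape, reference.affine
    shape, affine = reference
    return tuple(shape), np.asarray(affine, dtype=float)


def resample_affine(v, T: AffineTransform, reference, interp: str = "linear"):
    """Resample ``v`` onto a reference grid through a physical-space transform.

    ``T`` maps reference(physical) -> v(physical). Output voxels falling
    outside ``v``'s field of view are filled with 0. Masks must use nearest
    interpolation so the output stays binary.
    """
    is_mask = isinstance(v, BinaryMask)
    if is_mask and interp != "nearest":
        raise ValueError("masks must be resampled with nearest interpolation")
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interp!r}")
    out_shape, out_affine = _reference_grid(reference)
    # voxel_out -> phys_ref -> phys_v -> voxel_v
    M = np.linalg.inv(v.affine) @ T.matrix @ out_affine
    order = 0 if interp == "nearest" else 1
    out = ndimage.affine_transform(
        v.data.astype(np.float32),
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=out_shape,
        order=order,
        mode="constant",
        cval=0.0,
    )
    if is_mask:
        return BinaryMask(data=(out > 0.5).astype(np.uint8), affine=out_affine)
    return ImageVolume(data=out, affine=out_affine)
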