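"""Reading, writing and validating segmentation volumes.

Every volume handled by this package is a *soft mask*: a 3D scalar field
whose voxel values give the fraction of the voxel occupied by a structure
(lesion, spinal cord, or a white-matter tract probability). Values live in
[0, 1].

On read, volumes are reoriented to a fixed anatomical convention:

* axis 0 runs right -> left      (sagittal slice index),
* axis 1 runs posterior -> anterior,
* axis 2 runs inferior -> superior.

All downstream geometry (projection maps, left/right splits, tissue-bridge
measurements) assumes this convention, so no other module needs to reason
about orientation. Inputs are assumed to be co-registered to a common
template grid; this module checks grid compatibility but never resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "CANONICAL_AXIS_ROLES",
    "VoxelGrid",
    "SoftMask",
    "read_mask",
    "write_mask",
    "assert_cogrid",
    "VolumeError",
    "DimensionalityError",
    "MaskValueError",
    "ObliqueAffineError",
    "CoRegistrationError",
]

#: Anatomical direction each array axis increases toward, in order.
CANONICAL_AXIS_ROLES: tuple[str, str, str] = (
    "right-left",
    "posterior-anterior",
    "inferior-superior",
)

#: nibabel orientation codes matching CANONICAL_AXIS_ROLES (axis *end* labels).
_CANONICAL_AXCODES = ("L", "A", "S")

#: Soft values may stray this far outside [0, 1] before being an error.
VALUE_TOL = 1e-6

#: Spacings closer than this (mm) are considered identical.
SPACING_TOL = 1e-4

#: Off-axis direction cosines above this mark an oblique acquisition.
OBLIQUITY_TOL = 1e-3


class VolumeError(ValueError):
    """Base class for volume validation failures."""


class DimensionalityError(VolumeError):
    """Input volume is not three-dimensional."""


class MaskValueError(VolumeError):
    """Voxel values fall outside [0, 1] beyond tolerance."""


class ObliqueAffineError(VolumeError):
    """Affine has oblique direction cosines; resample before use."""


class CoRegistrationError(VolumeError):
    """Volumes expected to share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D volume: shape, spacing (mm) and axis roles.

    A voxel is treated as a cell of volume ``prod(spacing)`` centred on its
    (0-based) index, which makes volume sums exact.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    axis_roles: tuple[str, str, str] = CANONICAL_AXIS_ROLES

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise VolumeError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be a positive real triple (mm), got {self.spacing}")
        if sorted(self.axis_roles) != sorted(CANONICAL_AXIS_ROLES):
            raise VolumeError(
                f"axis_roles must be a bijection onto {set(CANONICAL_AXIS_ROLES)}, got {self.axis_roles}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_of(self, role: str) -> int:
        """Array axis carrying the given anatomical role."""
        return self.axis_roles.index(role)

    def matches(self, other: "VoxelGrid", spacing_tol: float = SPACING_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= spacing_tol for a, b in zip(self.spacing, other.spacing))
            and self.axis_roles == other.axis_roles
        )


class SoftMask:
    """A 3D scalar volume on a :class:`VoxelGrid` with values in [0, 1].

    Values within ``VALUE_TOL`` outside [0, 1] are clamped silently (float
    noise from interpolation); larger excursions raise :class:`MaskValueError`.
    """

    __slots__ = ("grid", "values")

    def __init__(self, grid: VoxelGrid, values: np.ndarray, *, copy: bool = True):
        arr = np.array(values, dtype=np.float64, copy=copy)
        if arr.ndim != 3:
            raise DimensionalityError(f"mask values must be 3D, got {arr.ndim}D")
        if tuple(arr.shape) != grid.shape:
            raise VolumeError(f"values shape {arr.shape} does not match grid shape {grid.shape}")
        vmin = float(arr.min())
        vmax = float(arr.max())
        if vmin < -VALUE_TOL or vmax > 1.0 + VALUE_TOL:
            raise MaskValueError(
                f"soft-mask values must lie in [0, 1]; found min={vmin:.6g}, max={vmax:.6g}"
            )
        np.clip(arr, 0.0, 1.0, out=arr)
        self.grid = grid
        self.values = arr

    @property
    def mass(self) -> float:
        """Sum of soft values (voxels' worth of structure)."""
        return float(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        """Soft volume: sum of values times the voxel volume."""
        return self.mass * self.grid.voxel_volume_mm3

    def binarize(self, threshold: float = 0.5) -> "SoftMask":
        """Hard mask: 1 where value >= threshold, else 0."""
        return SoftMask(self.grid, (self.values >= threshold).astype(np.float64), copy=False)

    def is_empty(self, threshold: float = 0.0) -> bool:
        return not bool((self.values > threshold).any())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SoftMask(shape={self.grid.shape}, spacing={self.grid.spacing}, mass={self.mass:.3g})"


def _check_not_oblique(affine: np.ndarray) -> None:
    rot = np.asarray(affine, dtype=float)[:3, :3]
    norms = np.linalg.norm(rot, axis=0)
    if np.any(norms <= 0):
        raise VolumeError("affine has a zero-length direction vector")
    cosines = rot / norms
    # Each column must be axis-aligned: one |cosine| ~ 1, off terms ~ 0.
    off = np.abs(cosines) * (np.abs(np.abs(cosines) - 1.0) > OBLIQUITY_TOL)
    if np.any(off > OBLIQUITY_TOL):
        raise ObliqueAffineError(
            "volume has an oblique affine (off-axis direction cosines exceed "
            f"{OBLIQUITY_TOL}); resample to an axis-aligned grid first"
        )


def read_mask(path: str | Path) -> SoftMask:
    """Read a 3D NIfTI soft mask, reorienting to the canonical convention.

    Parameters
    ----------
    path
        A readable ``.nii`` / ``.nii.gz`` file holding a 3D volume with an
        axis-aligned affine. Values must lie in [0, 1] up to float tolerance.

    Returns
    -------
    SoftMask
        Values reordered so axis 0 runs right->left, axis 1
        posterior->anterior, axis 2 inferior->superior.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D volume, got {data.ndim}D shape {data.shape}")
    affine = img.affine
    _check_not_oblique(affine)

    ornt = nib.orientations.io_orientation(affine)
    target = nib.orientations.axcodes2ornt(_CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(data, transform)

    zooms = np.abs(np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0))
    # transform row i: (source axis feeding canonical axis i, flip)
    spacing = tuple(float(zooms[int(src)]) for src, _flip in transform)

    grid = VoxelGrid(shape=tuple(data.shape), spacing=spacing)
    try:
        return SoftMask(grid, np.asarray(data, dtype=np.float64), copy=False)
    except MaskValueError as exc:
        raise MaskValueError(f"{path}: {exc}") from None


def write_mask(mask: SoftMask, path: str | Path) -> None:
    """Write a soft mask as float32 NIfTI in the canonical orientation.

    The affine encodes spacing and the canonical axis directions (axis 0
    pointing left, axis 1 anterior, axis 2 superior), so a round trip through
    :func:`read_mask` reproduces values (float32 precision) and grid exactly.
    """
    sx, sy, sz = mask.grid.spacing
    affine = np.diag([-sx, sy, sz, 1.0])
    img = nib.Nifti1Image(mask.values.astype(np.float32), affine)
    nib.save(img, str(path))


def assert_cogrid(masks: Sequence[SoftMask] | Iterable[SoftMask]) -> None:
    """Check that all masks share one grid (shape, spacing, axis roles).

    Raises :class:`CoRegistrationError` naming the first differing field.
    Spacing is compared with a tolerance of ``SPACING_TOL`` mm.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise VolumeError("assert_cogrid needs at least two masks")
    ref = masks[0].grid
    for i, m in enumerate(masks[1:], start=1):
        g = m.grid
        if g.shape != ref.shape:
            raise CoRegistrationError(f"mask {i}: shape {g.shape} differs from reference {ref.shape}")
        if any(abs(a - b) > SPACING_TOL for a, b in zip(g.spacing, ref.spacing)):
            raise CoRegistrationError(
                f"mask {i}: spacing {g.spacing} differs from reference {ref.spacing} (tol {SPACING_TOL} mm)"
            )
        if g.axis_roles != ref.axis_roles:
            raise CoRegistrationError(
                f"mask {i}: axis_roles {g.axis_roles} differ from reference {ref.axis_roles}"
            )
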