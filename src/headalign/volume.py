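"""Volumes with physical geometry, LPS orientation, resampling, normalization.

All modules share one coordinate convention: LPS physical coordinates
(+x = patient Left, +y = Posterior, +z = Superior), 0-based voxel
indices, and voxel *centers* mapping to physical points via

    physical(i, j, k) = origin + direction @ (spacing * (i, j, k))

This mapping is the single source of truth; every landmark coordinate
in the package is an LPS point in millimetres.

SimpleITK (which works natively in LPS) backs file I/O and resampling;
the array held in :class:`VolumeGrid` is indexed ``[i, j, k]`` =
``[x, y, z]``, i.e. transposed relative to SimpleITK's ``[z, y, x]``
array view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import ConfigurationError, VolumeIOError

__all__ = [
    "VolumeGrid",
    "LabelMap",
    "read_volume",
    "write_volume",
    "reorient_to_lps",
    "resample",
    "normalize_intensity",
]

_ORTHO_TOL = 1e-6
DEFAULT_IMAGE_FILL = -1024.0  # HU of air
DEFAULT_LABEL_FILL = 0


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    voxels
        3D array indexed ``[i, j, k]`` along (x, y, z).
    spacing
        Per-axis voxel size in mm, all > 0.
    origin
        Physical LPS position (mm) of the center of voxel (0, 0, 0).
    direction
        3x3 direction-cosine matrix (columns are the physical directions
        of the i, j, k index axes); orthonormal within 1e-6.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigurationError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ConfigurationError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ConfigurationError(f"origin must be a 3-vector, got {self.origin}")
        if self.direction.shape != (3, 3):
            raise ConfigurationError("direction must be 3x3")
        err = np.abs(self.direction.T @ self.direction - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ConfigurationError(
                f"direction matrix not orthonormal (|D^T D - I| max = {err:.2e})"
            )

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_physical(self, ijk) -> np.ndarray:
        """Physical LPS point (mm) of a (possibly fractional) voxel index."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (self.spacing * ijk) @ self.direction.T

    def physical_to_index(self, xyz) -> np.ndarray:
        """Fractional voxel index of a physical LPS point."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.origin) @ self.direction / self.spacing

    def physical_corners(self) -> np.ndarray:
        """The 8 corners of the physical extent (voxel-edge bounding box)."""
        lo = -0.5 * np.ones(3)
        hi = np.asarray(self.shape) - 0.5
        corners = np.array(
            [[a, b, c] for a in (lo[0], hi[0]) for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]
        )
        return self.index_to_physical(corners)

    def contains_point(self, xyz) -> bool:
        idx = self.physical_to_index(xyz)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    # -- SimpleITK bridge ---------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeGrid":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            voxels=arr,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeGrid":
        """Same geometry, new voxel data."""
        return type(self)(
            voxels=voxels,
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            direction=self.direction.copy(),
        )


class LabelMap(VolumeGrid):
    """A binary landmark mask sharing :class:`VolumeGrid` geometry.

    Voxel values are restricted to {0, 1}; label maps are only ever
    resampled with nearest-neighbour interpolation so this invariant
    survives every pipeline stage.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ConfigurationError(f"label map values must be in {{0,1}}, got {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)


# -- file I/O ---------------------------------------------------------


def read_volume(path: str | os.PathLike, label: bool = False) -> VolumeGrid:
    """Read a NIfTI file or a DICOM series directory into LPS geometry.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file, or a directory holding one DICOM
        series with uniform spacing.
    label
        Return a :class:`LabelMap` (binary) instead of a
        :class:`VolumeGrid`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file or directory: {path}")
    try:
        if os.path.isdir(path):
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(path)
            if not files:
                raise VolumeIOError(f"no DICOM series found in directory: {path}")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(path)
    except VolumeIOError:
        raise
    except Exception as exc:  # sitk raises RuntimeError on unreadable input
        raise VolumeIOError(f"failed to read {path}: {exc}") from exc
    cls = LabelMap if label else VolumeGrid
    return cls.from_sitk(img)


def write_volume(volume: VolumeGrid, path: str | os.PathLike) -> None:
    """Write to NIfTI (``.nii`` or ``.nii.gz``)."""
    path = os.fspath(path)
    try:
        sitk.WriteImage(volume.to_sitk(), path)
    except Exception as exc:
        raise VolumeIOError(f"failed to write {path}: {exc}") from exc


# -- orientation ------------------------------------------------------


def reorient_to_lps(volume: VolumeGrid, oblique_tol_deg: float = 1.0) -> VolumeGrid:
    """Permute/flip voxel axes so the direction matrix becomes identity in LPS.

    A pure index operation: no interpolation, every voxel keeps its
    physical location. Volumes whose direction matrix deviates from the
    nearest axis alignment by more than ``oblique_tol_deg`` degrees are
    rejected -- resample such data onto an axis-aligned grid first.
    """
    d = volume.direction
    # nearest signed permutation matrix
    nearest = np.zeros((3, 3))
    for col in range(3):
        row = int(np.argmax(np.abs(d[:, col])))
        nearest[row, col] = np.sign(d[row, col])
    if np.abs(np.abs(nearest).sum(axis=0) - 1).max() > 0 or np.abs(
        np.abs(nearest).sum(axis=1) - 1
    ).max() > 0:
        raise ConfigurationError("direction matrix is too oblique to classify axes")
    # worst-case angle between an index axis and its nearest anatomical axis
    cosines = np.abs((d * nearest).sum(axis=0))
    tilt_deg = float(np.degrees(np.arccos(np.clip(cosines.min(), -1, 1))))
    if tilt_deg > oblique_tol_deg:
        raise ConfigurationError(
            f"volume is oblique ({tilt_deg:.2f} deg from axis-aligned); "
            "resample onto an axis-aligned grid before reorienting"
        )
    if np.allclose(d, np.eye(3), atol=1e-12):
        return volume
    img = sitk.DICOMOrient(volume.to_sitk(), "LPS")
    return type(volume).from_sitk(img)


# -- resampling -------------------------------------------------------


def resample(
    volume: VolumeGrid,
    target_spacing_mm,
    interpolation: str | None = None,
    fill_value: float | None = None,
) -> VolumeGrid:
    """Resample onto a grid with the requested spacing, covering the
    input physical extent.

    Images get linear interpolation, label maps nearest-neighbour
    (the only interpolation ever applied to labels); pass
    ``interpolation`` explicitly to override. Voxels outside the input
    extent take ``fill_value`` (air for images, background for labels).
    """
    target = np.asarray(target_spacing_mm, dtype=float)
    if target.shape == ():
        target = np.repeat(target, 3)
    if target.shape != (3,) or np.any(target <= 0):
        raise ConfigurationError(f"target spacing must be 3 positive values, got {target}")

    is_label = isinstance(volume, LabelMap)
    if interpolation is None:
        interpolation = "nearest" if is_label else "linear"
    if interpolation not in ("linear", "nearest"):
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")
    if is_label and interpolation == "linear":
        raise ConfigurationError("label maps must use nearest-neighbour interpolation")
    if fill_value is None:
        fill_value = DEFAULT_LABEL_FILL if is_label else DEFAULT_IMAGE_FILL

    size_out = np.maximum(
        1, np.ceil(np.asarray(volume.shape) * volume.spacing / target).astype(int)
    )
    img = volume.to_sitk()
    interp = sitk.sitkNearestNeighbor if interpolation == "nearest" else sitk.sitkLinear
    out = sitk.Resample(
        img,
        [int(s) for s in size_out],
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        tuple(target),
        img.GetDirection(),
        float(fill_value),
        img.GetPixelID(),
    )
    return type(volume).from_sitk(out)


# -- intensity --------------------------------------------------------


def normalize_intensity(volume: VolumeGrid) -> VolumeGrid:
    """Min-max rescale intensities to [0, 1].

    The preprocessing applied before landmark prediction; undefined
    (and rejected) for constant volumes.
    """
    v = volume.voxels.astype(float)
    lo, hi = float(np.min(v)), float(np.max(v))
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ConfigurationError("volume contains non-finite intensities")
    if hi <= lo:
        raise ConfigurationError("cannot normalize a constant volume")
    return volume.with_voxels((v - lo) / (hi - lo))
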