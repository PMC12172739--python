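"""Landmark points and their extraction from label maps.

Three bony landmarks drive the alignment: the right and left cochleas
and the nasal bridge. They are easy to find on CT, roughly coplanar
with the historical orbito-meatal scanning line, and — being bone —
stable across contrast phases and most pathology.

A landmark *point* is the center of mass of a binary label (a manual
sphere, an oracle threshold component on a phantom, or a network
prediction); all COM math happens in physical LPS millimetres so label
resolution never enters coordinate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateGeometryError, LandmarkNotFoundError
from .volume import LabelMap, VolumeGrid

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomSpec

__all__ = [
    "LandmarkSet",
    "LANDMARK_NAMES",
    "sphere_label",
    "label_center_of_mass",
    "detect_landmarks_oracle",
]

LANDMARK_NAMES = ("right_cochlea", "left_cochlea", "nasal_bridge")

#: default label diameter: a 1 cm sphere around each landmark center
DEFAULT_LABEL_DIAMETER_MM = 10.0

_26_CONN = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LandmarkSet:
    """The three named landmark points, LPS mm.

    Anatomical sanity is enforced on construction: the points are
    pairwise distinct and non-collinear, the left cochlea lies at
    larger x than the right (LPS: +x = Left), and the nasal bridge is
    anterior to (smaller y than) the inter-cochlear midpoint.
    """

    right_cochlea: np.ndarray
    left_cochlea: np.ndarray
    nasal_bridge: np.ndarray
    source: str = "manual"  # manual | oracle | network

    def __post_init__(self) -> None:
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ConfigurationError(f"{name} must be a 3-vector, got {p}")
            object.__setattr__(self, name, p)
        rc, lc, nb = self.right_cochlea, self.left_cochlea, self.nasal_bridge
        for a, b, na, nb_ in ((rc, lc, "right_cochlea", "left_cochlea"),
                              (rc, nb, "right_cochlea", "nasal_bridge"),
                              (lc, nb, "left_cochlea", "nasal_bridge")):
            if np.linalg.norm(a - b) <= 1.0:
                raise DegenerateGeometryError(f"{na} and {nb_} are less than 1 mm apart")
        axis = lc - rc
        perp = (nb - rc) - (np.dot(nb - rc, axis) / np.dot(axis, axis)) * axis
        if np.linalg.norm(perp) <= 1.0:
            raise DegenerateGeometryError(
                "nasal bridge is within 1 mm of the inter-cochlear line (collinear landmarks)"
            )
        if lc[0] <= rc[0]:
            raise ConfigurationError(
                f"left cochlea (x={lc[0]:.2f}) must lie at larger x than right "
                f"cochlea (x={rc[0]:.2f}) in LPS"
            )
        if nb[1] >= self.cochlear_midpoint[1]:
            raise ConfigurationError(
                "nasal bridge must be anterior to (smaller y than) the cochlear midpoint"
            )

    @property
    def cochlear_midpoint(self) -> np.ndarray:
        return 0.5 * (self.right_cochlea + self.left_cochlea)

    def as_array(self) -> np.ndarray:
        """Points stacked as rows in canonical order."""
        return np.stack([self.right_cochlea, self.left_cochlea, self.nasal_bridge])

    @classmethod
    def from_array(cls, pts: np.ndarray, source: str = "manual") -> "LandmarkSet":
        pts = np.asarray(pts, dtype=float)
        return cls(pts[0], pts[1], pts[2], source=source)

    def to_dict(self) -> dict:
        return {
            "landmarks": {name: list(map(float, getattr(self, name))) for name in LANDMARK_NAMES},
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        lm = d["landmarks"]
        return cls(
            right_cochlea=np.asarray(lm["right_cochlea"], float),
            left_cochlea=np.asarray(lm["left_cochlea"], float),
            nasal_bridge=np.asarray(lm["nasal_bridge"], float),
            source=d.get("source", "manual"),
        )


def sphere_label(
    center,
    diameter_mm: float = DEFAULT_LABEL_DIAMETER_MM,
    grid: VolumeGrid | None = None,
) -> LabelMap:
    """Voxelize a sphere around ``center`` on ``grid``'s geometry.

    A voxel is foreground iff its *center* lies within ``diameter_mm/2``
    of ``center``. This is how training labels are made: a 1 cm sphere
    at the cochlear modiolus (or nasal-bridge apex).
    """
    if grid is None:
        raise ConfigurationError("sphere_label requires a reference grid")
    if diameter_mm <= 0:
        raise ConfigurationError(f"diameter must be positive, got {diameter_mm}")
    center = np.asarray(center, dtype=float)
    if not grid.contains_point(center):
        raise ConfigurationError(f"sphere center {center} lies outside the grid extent")
    radius = diameter_mm / 2.0
    # squared physical distance from every voxel center, separably per axis
    # (valid because direction is orthonormal: |D s (ijk) - c'| with c' in index frame)
    cidx = grid.physical_to_index(center)
    nx, ny, nz = grid.shape
    dx2 = ((np.arange(nx) - cidx[0]) * grid.spacing[0]) ** 2
    dy2 = ((np.arange(ny) - cidx[1]) * grid.spacing[1]) ** 2
    dz2 = ((np.arange(nz) - cidx[2]) * grid.spacing[2]) ** 2
    d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
    mask = (d2 <= radius**2).astype(np.uint8)
    return LabelMap(
        voxels=mask,
        spacing=grid.spacing.copy(),
        origin=grid.origin.copy(),
        direction=grid.direction.copy(),
    )


def label_center_of_mass(label: LabelMap) -> np.ndarray:
    """Center of mass of a binary label, in LPS mm.

    The unweighted mean of the physical centers of the foreground
    voxels of the *largest* 26-connected component; component selection
    guards against speckle in predicted labels. An empty label raises
    :class:`LandmarkNotFoundError` — the failure mode behind absent or
    destroyed anatomy.
    """
    comps, ncomp = ndimage.label(label.voxels, structure=_26_CONN)
    if ncomp == 0:
        raise LandmarkNotFoundError("landmark not found: label map is empty")
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, ncomp + 1))
        keep = int(np.argmax(sizes)) + 1
    else:
        keep = 1
    idx = np.argwhere(comps == keep).astype(float)
    # index->physical is affine, so the mean commutes with the mapping
    return label.index_to_physical(idx.mean(axis=0))


def detect_landmarks_oracle(volume: VolumeGrid, phantom_spec: "PhantomSpec") -> LandmarkSet:
    """Network-free landmark detection on a synthetic phantom.

    Thresholds midway between the skull and landmark intensities,
    splits 26-connected components, and assigns anatomy geometrically:
    the closest pair of components are the cochleas (separated by
    ~60 mm, versus ~80 mm to the nasal bridge), right/left by x order,
    the remaining component is the nasal bridge. Valid for phantoms
    rotated up to +/-45 degrees per plane, where x-order of the
    cochleas is preserved.
    """
    threshold = 0.5 * (phantom_spec.skull_intensity + phantom_spec.landmark_intensity)
    mask = volume.voxels > threshold
    comps, ncomp = ndimage.label(mask, structure=_26_CONN)
    if ncomp != 3:
        raise LandmarkNotFoundError(
            f"landmark not found: expected 3 high-intensity components, found {ncomp}"
        )
    coms = []
    for lab in range(1, 4):
        idx = np.argwhere(comps == lab).astype(float)
        coms.append(volume.index_to_physical(idx.mean(axis=0)))
    coms = np.asarray(coms)
    # closest pair = cochleas
    dists = {
        (a, b): np.linalg.norm(coms[a] - coms[b]) for a in range(3) for b in range(a + 1, 3)
    }
    (a, b), _ = min(dists.items(), key=lambda kv: kv[1])
    nb = ({0, 1, 2} - {a, b}).pop()
    if coms[a][0] > coms[b][0]:
        a, b = b, a  # a = right (smaller x), b = left
    return LandmarkSet(
        right_cochlea=coms[a], left_cochlea=coms[b], nasal_bridge=coms[nb], source="oracle"
    )
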