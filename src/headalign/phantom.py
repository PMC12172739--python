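"""Synthetic head-CT phantoms with exactly known landmarks.

The phantom is deliberately schematic — an ellipsoidal "head" of soft
tissue wrapped in a skull shell, three high-density spheres at the
landmark positions, and a small bony ridge marking the nasal bridge —
because only the *geometry* matters to the alignment algorithm under
test. Intensities are Hounsfield-like (air -1024, soft tissue ~40,
bone ~700), and the landmark spheres sit well above bone so a simple
threshold detector can stand in for the segmentation network.

The canonical pose is already aligned: the cochleas differ only in x
(separation ~60 mm) and the nasal bridge lies on their axial plane,
~80 mm anterior. Known rigid misalignments (up to 45 degrees per
plane, the augmentation envelope of the reference training recipe) are
then applied with a single resampling pass; the landmark points are
propagated *analytically* through every transform so that algorithm
error and discretization error can be separated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .align import (
    RigidTransform,
    apply_transform,
    rotation_x,
    rotation_y,
    rotation_z,
    transform_points,
)
from .errors import ConfigurationError
from .landmarks import LANDMARK_NAMES, LandmarkSet, sphere_label
from .volume import LabelMap, VolumeGrid

__all__ = [
    "PhantomSpec",
    "MisalignmentSpec",
    "MAX_MISALIGNMENT_DEG",
    "generate_phantom",
    "apply_misalignment",
    "sample_misalignments",
    "write_landmark_sidecar",
    "read_landmark_sidecar",
]

#: hardest rotation the pipeline is specified to handle, per plane
MAX_MISALIGNMENT_DEG = 45.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic head phantom.

    Defaults reproduce the working resolution of the reference
    pipeline (1.5 mm isotropic, 128x128 in-plane) and anatomically
    plausible landmark geometry: cochleas 60 mm apart left-right, the
    nasal bridge 80 mm anterior on the cochlear axial plane.
    ``jitter_mm`` adds seed-driven uniform shifts — a joint shift of
    the cochlear pair (so their separation stays exact) and an
    independent shift of the nasal bridge — giving per-subject variety.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    cochlea_separation_mm: float = 60.0
    nasal_bridge_offset_mm: tuple[float, float] = (80.0, 0.0)  # (anterior, superior)
    skull_intensity: float = 700.0
    tissue_intensity: float = 40.0
    air_intensity: float = -1024.0
    landmark_intensity: float = 2000.0
    landmark_radius_mm: float = 5.0
    jitter_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("all spacings must be positive")
        if any(n < 8 for n in self.grid_shape):
            raise ConfigurationError("grid must be at least 8 voxels per axis")
        if self.landmark_radius_mm <= 0:
            raise ConfigurationError("landmark radius must be positive")
        if self.cochlea_separation_mm <= 2 * self.landmark_radius_mm:
            raise ConfigurationError(
                "cochlea separation must exceed the landmark sphere diameter"
            )
        if self.jitter_mm < 0:
            raise ConfigurationError("jitter must be non-negative")

    @property
    def grid_center_mm(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    def landmark_points(self) -> LandmarkSet:
        """Exact landmark positions for this spec (deterministic by seed)."""
        rng = np.random.default_rng(self.seed)
        mid_shift = rng.uniform(-self.jitter_mm, self.jitter_mm, size=3)
        nb_shift = rng.uniform(-self.jitter_mm, self.jitter_mm, size=3)
        c0 = self.grid_center_mm + mid_shift
        half = 0.5 * self.cochlea_separation_mm
        anterior, superior = self.nasal_bridge_offset_mm
        return LandmarkSet(
            right_cochlea=c0 + np.array([-half, 0.0, 0.0]),
            left_cochlea=c0 + np.array([+half, 0.0, 0.0]),
            nasal_bridge=c0 + np.array([0.0, -anterior, superior]) + nb_shift,
            source="manual",
        )


@dataclass(frozen=True)
class MisalignmentSpec:
    """A known rigid misalignment: signed degrees per plane.

    yaw is about z (axial plane), pitch about x (sagittal), roll about
    y (coronal); applied in that order about ``center`` (defaulting to
    the phantom's cochlear midpoint).
    """

    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    center: tuple[float, float, float] | None = None
    seed: int = 0
    max_deg: float = MAX_MISALIGNMENT_DEG

    def __post_init__(self) -> None:
        for name in ("yaw_deg", "pitch_deg", "roll_deg"):
            if abs(getattr(self, name)) > self.max_deg:
                raise ConfigurationError(
                    f"|{name}| = {abs(getattr(self, name)):.1f} exceeds the "
                    f"configured maximum of {self.max_deg:.1f} degrees"
                )

    def rotation_matrix(self) -> np.ndarray:
        return (
            rotation_y(self.roll_deg)
            @ rotation_x(self.pitch_deg)
            @ rotation_z(self.yaw_deg)
        )

    def to_transform(self, default_center) -> RigidTransform:
        center = default_center if self.center is None else np.asarray(self.center, float)
        return RigidTransform(rotation=self.rotation_matrix(), center=center)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, LandmarkSet, dict[str, LabelMap]]:
    """Build the phantom volume, its exact landmarks, and per-landmark labels.

    Regenerating with the same spec (including seed) is bit-identical.
    """
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, float)
    landmarks = spec.landmark_points()

    grid = VolumeGrid(
        voxels=np.zeros(shape, dtype=np.float32),
        spacing=spacing,
        origin=np.zeros(3),
        direction=np.eye(3),
    )
    for name in LANDMARK_NAMES:
        pt = getattr(landmarks, name)
        if not grid.contains_point(pt):
            raise ConfigurationError(f"landmark {name} at {pt} lies outside the grid extent")

    # physical coordinates of voxel centers, one axis at a time
    xs = np.arange(shape[0]) * spacing[0]
    ys = np.arange(shape[1]) * spacing[1]
    zs = np.arange(shape[2]) * spacing[2]
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    c0 = spec.grid_center_mm

    vox = np.full(shape, spec.air_intensity, dtype=np.float32)

    # head: soft-tissue ellipsoid centered on the grid, skull shell on its rim
    semi = np.array([70.0, 88.0, 60.0])
    q = ((X - c0[0]) / semi[0]) ** 2 + ((Y - c0[1]) / semi[1]) ** 2 + ((Z - c0[2]) / semi[2]) ** 2
    vox[q <= 1.0] = spec.skull_intensity
    vox[q <= 0.92**2] = spec.tissue_intensity

    # nasal-bridge ridge: a small bony box just posterior of the landmark
    nb = landmarks.nasal_bridge
    ridge = (
        (np.abs(X - nb[0]) <= 6.0)
        & (Y - nb[1] >= 0.0)
        & (Y - nb[1] <= 12.0)
        & (np.abs(Z - nb[2]) <= 10.0)
    )
    vox[ridge] = spec.skull_intensity

    # landmark spheres, well above bone so thresholding finds them
    labels: dict[str, LabelMap] = {}
    for name in LANDMARK_NAMES:
        pt = getattr(landmarks, name)
        lab = sphere_label(pt, diameter_mm=2 * spec.landmark_radius_mm, grid=grid)
        vox[lab.voxels.astype(bool)] = spec.landmark_intensity
        labels[name] = lab

    volume = grid.with_voxels(vox)
    return volume, landmarks, labels


def apply_misalignment(
    volume: VolumeGrid,
    landmarks: LandmarkSet,
    mis: MisalignmentSpec,
) -> tuple[VolumeGrid, LandmarkSet, RigidTransform]:
    """Rotate a phantom by a known misalignment.

    The volume is resampled once on its own grid; the landmark points
    are transformed analytically (never read back from the resampled
    image), so the returned LandmarkSet is exact ground truth.
    """
    transform = mis.to_transform(landmarks.cochlear_midpoint)
    rotated = apply_transform(volume, transform, expand_z=False)
    moved = LandmarkSet.from_array(
        transform_points(landmarks.as_array(), transform), source=landmarks.source
    )
    return rotated, moved, transform


def sample_misalignments(n: int, max_deg: float = MAX_MISALIGNMENT_DEG, seed: int = 0):
    """Draw ``n`` misalignments with each angle uniform on [-max_deg, +max_deg]."""
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    if max_deg < 0:
        raise ConfigurationError("max_deg must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        yaw, pitch, roll = rng.uniform(-max_deg, max_deg, size=3)
        out.append(
            MisalignmentSpec(
                yaw_deg=float(yaw),
                pitch_deg=float(pitch),
                roll_deg=float(roll),
                seed=seed + i,
                max_deg=max(max_deg, MAX_MISALIGNMENT_DEG),
            )
        )
    return out


# -- sidecar JSON -----------------------------------------------------
#
# Schema: {"landmarks": {name: [x, y, z] LPS mm}, "source": str,
#          "angles_deg": {"yaw": .., "pitch": .., "roll": ..}}  (optional)


def write_landmark_sidecar(
    path: str | os.PathLike,
    landmarks: LandmarkSet,
    angles_deg: dict | None = None,
) -> None:
    payload = landmarks.to_dict()
    if angles_deg is not None:
        payload["angles_deg"] = {k: float(v) for k, v in angles_deg.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_landmark_sidecar(path: str | os.PathLike) -> tuple[LandmarkSet, dict | None]:
    with open(path) as fh:
        payload = json.load(fh)
    return LandmarkSet.from_dict(payload), payload.get("angles_deg")
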