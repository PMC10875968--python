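"""World/voxel geometry conventions and the image containers.

Conventions (used by every module):

* Internal world frame is LPS-flavoured and axis-aligned: world axis 0 is
  LR (+left), axis 1 is AP (+posterior), axis 2 is SI (+superior).
* Voxel indices are 0-based and positions refer to voxel *centres*;
  world = origin + index * spacing, axis by axis.
* Oblique / non-orthogonal lattices are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

AXIS_LABELS = ("LR", "AP", "SI")


class GeometryError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class VolumeImage:
    """3D scalar lattice with world geometry.

    values : (n0, n1, n2) array, lattice axes mapped to world axes by
             ``axis_labels`` (default identity: LR, AP, SI).
    valid  : optional bool mask of voxels carrying data (used by
             reconstructions whose support does not cover the FOV).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_labels: tuple[str, str, str] = AXIS_LABELS
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError("VolumeImage values must be 3D")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be positive")
        if sorted(self.axis_labels) != sorted(AXIS_LABELS):
            raise GeometryError("axis_labels must be a permutation of (LR, AP, SI)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_from_voxel(self, index) -> np.ndarray:
        """Affine voxel-centre -> world (mm). Bounds-checked."""
        index = np.asarray(index, dtype=np.float64)
        n = np.asarray(self.shape)
        if np.any(index < 0) or np.any(index > n - 1):
            raise IndexError(f"index {index} outside lattice {self.shape}")
        return self.origin + index * self.spacing

    def voxel_from_world(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=np.float64) - self.origin) / self.spacing

    def fov_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of voxel centres."""
        n = np.asarray(self.shape, dtype=np.float64)
        return self.origin.copy(), self.origin + (n - 1) * self.spacing

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one lattice axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def copy_with(self, values: np.ndarray, valid: np.ndarray | None = None) -> "VolumeImage":
        return replace(self, values=np.asarray(values, dtype=np.float64), valid=valid)


@dataclass
class SliceGeometry:
    """Geometry of one thick 2D slice.

    origin          : world mm of the centre of pixel (0, 0) on the centre plane
    in_plane_axes   : (2, 3) orthonormal world directions of the pixel axes
    normal          : (3,) unit world direction (through-plane)
    in_plane_spacing: (2,) mm
    shape           : (2,) pixels
    thickness       : slice-profile FWHM in mm
    """

    origin: np.ndarray
    in_plane_axes: np.ndarray
    normal: np.ndarray
    in_plane_spacing: np.ndarray
    shape: tuple[int, int]
    thickness: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        self.in_plane_spacing = np.asarray(self.in_plane_spacing, dtype=np.float64)
        self.shape = tuple(int(s) for s in self.shape)
        if self.thickness <= 0:
            raise GeometryError("thickness must be positive")
        m = np.vstack([self.in_plane_axes, self.normal[None]])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise GeometryError("in_plane_axes and normal must be orthonormal")

    def world_axis_map(self) -> tuple[np.ndarray, np.ndarray]:
        """For axis-aligned slices: (world axis index per slice axis, signs).

        Slice axes ordered (in-plane 0, in-plane 1, normal).
        """
        axes = np.vstack([self.in_plane_axes, self.normal[None]])
        world = np.zeros(3, dtype=np.int64)
        signs = np.zeros(3)
        for k in range(3):
            a = int(np.argmax(np.abs(axes[k])))
            if not np.isclose(abs(axes[k, a]), 1.0, atol=1e-9):
                raise GeometryError("slice is not axis-aligned")
            world[k] = a
            signs[k] = np.sign(axes[k, a])
        if len(set(world.tolist())) != 3:
            raise GeometryError("slice axes are degenerate")
        return world, signs

    def pixel_world(self) -> np.ndarray:
        """(p0, p1, 3) world coordinates of pixel centres on the centre plane."""
        i = np.arange(self.shape[0])[:, None, None]
        j = np.arange(self.shape[1])[None, :, None]
        return (
            self.origin[None, None]
            + i * self.in_plane_spacing[0] * self.in_plane_axes[0][None, None]
            + j * self.in_plane_spacing[1] * self.in_plane_axes[1][None, None]
        )


@dataclass
class DynamicSlice:
    """One acquired or simulated thick slice."""

    geometry: SliceGeometry
    values: np.ndarray
    t_index: int
    t_seconds: float
    role: str  # "surrogate" | "motion"
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.geometry.shape):
            raise GeometryError("slice values do not match geometry shape")
        if self.role not in ("surrogate", "motion"):
            raise GeometryError(f"unknown slice role {self.role!r}")
        if self.valid is None:
            self.valid = np.ones_like(self.values, dtype=bool)


@dataclass
class ROIMaskSet:
    """Named binary masks on a shared volume lattice."""

    masks: dict[str, np.ndarray]
    reference: VolumeImage

    def __post_init__(self):
        for name, m in self.masks.items():
            if m.shape != self.reference.shape:
                raise GeometryError(f"mask {name!r} shape mismatch")
            self.masks[name] = np.asarray(m, dtype=bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self):
        return list(self.masks)


def body_mask(vol: VolumeImage, threshold_fraction: float = 0.2) -> np.ndarray:
    """Threshold-based body outline.

    Threshold at ``threshold_fraction`` of the 99th intensity percentile,
    keep the largest connected component, fill internal holes (so air
    cavities such as the lungs belong to the body).
    """
    v = vol.values
    if np.ptp(v) == 0:
        raise DegenerateInputError("volume has constant intensity")
    thr = threshold_fraction * np.percentile(v, 99)
    raw = v > thr
    if not raw.any():
        raise DegenerateInputError("empty mask after thresholding")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(raw)
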