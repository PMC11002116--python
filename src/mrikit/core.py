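"""Core domain types.

The universal carrier is :class:`ImageVolume`: an N-dimensional intensity
array (2-5 dims, ordered x, y, slice, echo/time, repetition) together with
its acquisition geometry (in-plane voxel size, slice thickness, slice gap)
and optional echo/repetition time lists. Binary masks live on the spatial
grid of a parent volume and carry a role tag so that downstream volumetry
knows which mask is the brain, which are the hemispheres and which is a
region of interest.

Conventions
-----------
* voxel indices are 0-based; the slice axis is the 3rd array dimension;
* lengths are millimetres, times milliseconds, areas mm^2, volumes mm^3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConsistencyError,
    DimensionalityError,
    GeometryError,
    MetadataError,
    ParameterError,
)

__all__ = [
    "Geometry",
    "ImageVolume",
    "MaskRole",
    "BinaryMask",
    "Session",
]


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry of a slice-based MRI volume.

    Parameters
    ----------
    voxel_x, voxel_y : float
        In-plane voxel dimensions in mm.
    slice_thickness : float
        Thickness of each acquired slice in mm.
    slice_gap : float
        Distance between two adjacent slices not covered by either slice
        (mm, >= 0). The gap volume is *estimated*, not counted, during
        volumetry.
    units_label : str
        Unit of the three lengths; everything internal assumes "mm".
    """

    voxel_x: float
    voxel_y: float
    slice_thickness: float
    slice_gap: float = 0.0
    units_label: str = "mm"

    def __post_init__(self) -> None:
        if not (self.voxel_x > 0 and self.voxel_y > 0 and self.slice_thickness > 0):
            raise ParameterError(
                "voxel_x, voxel_y and slice_thickness must all be positive, got "
                f"({self.voxel_x}, {self.voxel_y}, {self.slice_thickness})"
            )
        if self.slice_gap < 0:
            raise ParameterError(f"slice_gap must be >= 0, got {self.slice_gap}")

    @property
    def voxel_area(self) -> float:
        """In-plane area of one voxel (mm^2)."""
        return self.voxel_x * self.voxel_y

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, slice gap excluded (mm^3)."""
        return self.voxel_x * self.voxel_y * self.slice_thickness

    def to_dict(self) -> dict:
        return {
            "voxel_x": self.voxel_x,
            "voxel_y": self.voxel_y,
            "slice_thickness": self.slice_thickness,
            "slice_gap": self.slice_gap,
            "units_label": self.units_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(**d)


def _default_affine(geometry: Geometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = geometry.voxel_x
    aff[1, 1] = geometry.voxel_y
    aff[2, 2] = geometry.slice_thickness + geometry.slice_gap
    return aff


@dataclass
class ImageVolume:
    """An MRI experiment: intensity data plus geometry and timing metadata.

    ``data`` is 2- to 5-dimensional, ordered (x, y, slice, echo/time,
    repetition). ``te_list``/``tr_list`` (ms) describe the 4th dimension
    when present; their length must match that dimension's extent.
    """

    data: np.ndarray
    geometry: Geometry
    te_list: tuple = ()
    tr_list: tuple = ()
    experiment_id: str = "volume"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if not 2 <= self.data.ndim <= 5:
            raise DimensionalityError(
                f"image data must have 2-5 dimensions, got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise MetadataError("image intensities must all be finite")
        self.te_list = tuple(float(t) for t in self.te_list)
        self.tr_list = tuple(float(t) for t in self.tr_list)
        for name, lst in (("te_list", self.te_list), ("tr_list", self.tr_list)):
            if lst and self.data.ndim >= 4 and len(lst) != self.data.shape[3]:
                raise MetadataError(
                    f"{name} has {len(lst)} entries but the 4th dimension "
                    f"extent is {self.data.shape[3]}"
                )
        if self.affine is None:
            self.affine = _default_affine(self.geometry)
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise GeometryError("affine must be a 4x4 matrix")

    @property
    def spatial_shape(self) -> tuple:
        """Shape of the (x, y[, slice]) spatial grid."""
        return self.data.shape[: min(self.data.ndim, 3)]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2] if self.data.ndim >= 3 else 1


class MaskRole(str, enum.Enum):
    BRAIN = "brain"
    HEMISPHERE_IPSI = "hemisphere_ipsi"
    HEMISPHERE_CONTRA = "hemisphere_contra"
    ROI = "roi"


@dataclass
class BinaryMask:
    """A boolean volume on the spatial grid of a parent :class:`ImageVolume`."""

    data: np.ndarray
    role: MaskRole = MaskRole.ROI
    parent_id: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if not 2 <= self.data.ndim <= 3:
            raise DimensionalityError(
                f"mask must be 2D or 3D, got {self.data.ndim} dims"
            )
        self.role = MaskRole(self.role)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, other: "BinaryMask | ImageVolume") -> None:
        """Raise GeometryError unless `other` lives on the same spatial grid."""
        shape = (
            other.spatial_shape if isinstance(other, ImageVolume) else other.data.shape
        )
        if tuple(self.data.shape) != tuple(shape):
            raise GeometryError(
                f"mask shape {self.data.shape} does not match {tuple(shape)}"
            )


@dataclass
class Session:
    """A working set of volumes, masks and parameter maps with provenance.

    Masks and maps must reference a volume already present in the session;
    the provenance log records operations in the order they were applied.
    """

    volumes: list = field(default_factory=list)
    masks: list = field(default_factory=list)
    maps: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def volume_ids(self) -> set:
        return {v.experiment_id for v in self.volumes}

    def add_volume(self, volume: ImageVolume) -> None:
        if volume.experiment_id in self.volume_ids():
            raise ConsistencyError(
                f"duplicate experiment_id {volume.experiment_id!r} in session"
            )
        self.volumes.append(volume)

    def add_mask(self, mask: BinaryMask) -> None:
        if mask.parent_id not in self.volume_ids():
            raise ConsistencyError(
                f"mask references unknown volume {mask.parent_id!r}"
            )
        self.masks.append(mask)

    def add_map(self, pmap) -> None:
        if getattr(pmap, "parent_id", None) not in self.volume_ids():
            raise ConsistencyError(
                f"parameter map references unknown volume "
                f"{getattr(pmap, 'parent_id', None)!r}"
            )
        self.maps.append(pmap)

    def log(self, operation: str, **params) -> None:
        self.provenance.append({"operation": operation, "params": params})
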