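"""Voxel-grid containers shared by every pipeline stage.

All volumes use ``(z, y, x)`` axis order — ``z`` is the TIFF stack order —
with a single isotropic voxel edge length in micrometres.  Geometry
compatibility (equal shape and voxel size) is the contract the
segmentation, morphometry and statistics stages rely on; every container
validates it at construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = ["VolumeImage", "BinaryVolume", "DistanceMap", "check_same_geometry"]


def _validate_grid(data: np.ndarray, voxel_size_um: float) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise GeometryError(
            f"expected a 3D (z, y, x) array, got {data.ndim} dimension(s)"
        )
    if min(data.shape) < 1:
        raise GeometryError(f"all three dimensions must be >= 1, got {data.shape}")
    if not (np.isfinite(voxel_size_um) and voxel_size_um > 0):
        raise ParameterError(
            f"voxel_size_um must be a positive finite scalar, got {voxel_size_um!r}"
        )
    return data


@dataclass(frozen=True)
class VolumeImage:
    """A 3D grayscale volume with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities.  Integer or floating dtype; all values finite.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres (e.g. 4.444 for the
        reference micro-CT scan geometry).
    name : str
        Free-text sample identifier, carried through reports.
    """

    data: np.ndarray
    voxel_size_um: float
    name: str = ""

    def __post_init__(self):
        data = _validate_grid(self.data, self.voxel_size_um)
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise ParameterError("volume contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_um", float(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def diagonal_um(self) -> float:
        """Physical length of the volume diagonal, an upper bound on any
        voxel-to-voxel distance."""
        return float(np.linalg.norm(self.data.shape)) * self.voxel_size_um

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(data, self.voxel_size_um, self.name)


@dataclass(frozen=True)
class BinaryVolume:
    """A boolean voxel grid sharing a :class:`VolumeImage`'s geometry.

    ``kind`` distinguishes the two masks the pipeline produces: the vessel
    segment and the organ (outer-shape) mask derived from it.
    """

    data: np.ndarray
    voxel_size_um: float
    kind: str = "vessel"
    name: str = ""

    KINDS = ("vessel", "organ")

    def __post_init__(self):
        data = _validate_grid(self.data, self.voxel_size_um)
        if data.dtype != bool:
            data = data.astype(bool)
        if self.kind not in self.KINDS:
            raise ParameterError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_um", float(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_fraction(self) -> float:
        return self.n_true / self.data.size


@dataclass(frozen=True)
class DistanceMap:
    """Per-voxel signed distance to the vessel-surface proxy, in micrometres.

    Positive on background (tissue) voxels, negative inside the vessel
    segment; the voxel-center metric never attains zero.
    """

    data: np.ndarray
    voxel_size_um: float
    name: str = ""

    def __post_init__(self):
        data = _validate_grid(self.data, self.voxel_size_um)
        data = np.asarray(data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_um", float(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def check_same_geometry(*volumes) -> None:
    """Raise :class:`GeometryError` unless all volumes share shape and voxel size."""
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise GeometryError(
                f"shape mismatch: {v.data.shape} vs {ref.data.shape}"
            )
        if not math.isclose(v.voxel_size_um, ref.voxel_size_um, rel_tol=1e-9):
            raise GeometryError(
                f"voxel size mismatch: {v.voxel_size_um} vs {ref.voxel_size_um} um"
            )
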