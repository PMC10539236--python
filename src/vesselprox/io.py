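"""TIFF-stack input/output for 3D volumes.

Volumes travel as stacks of 2D TIFF slices (one file per z-plane, zero-padded
numeric names so lexicographic order equals z order) or as a single multi-page
TIFF.  The voxel size is supplied by the caller — TIFF resolution-tag dialects
vary too much to trust — but if a resolution tag is present and disagrees with
the supplied voxel size by more than 1 %, a warning is emitted.

Boolean masks are stored as 8-bit 0/255 TIFFs for viewer compatibility; any
nonzero value reads back as true.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import GeometryError, InputError, VolumeIOError
from .volume import BinaryVolume, DistanceMap, VolumeImage

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_tiff_volume",
    "as_binary",
    "write_distance_map",
]

_ACCEPTED_DTYPES = ("uint8", "uint16", "float32")


def _check_resolution_tag(page, voxel_size_um: float, path) -> None:
    """Warn (never fail) if an embedded XResolution tag contradicts the
    caller-supplied voxel size."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
        unit = getattr(unit, "value", unit)
        per_unit = float(Fraction(*xres)) if isinstance(xres, tuple) else float(xres)
        if per_unit <= 0:
            return
        unit_um = {2: 25400.0, 3: 10000.0}.get(int(getattr(unit, "value", unit) or 0))
        if unit_um is None:
            return
        tag_voxel_um = unit_um / per_unit
        if abs(tag_voxel_um - voxel_size_um) > 0.01 * voxel_size_um:
            warnings.warn(
                f"{path}: TIFF resolution tag implies {tag_voxel_um:.4g} um/voxel "
                f"but {voxel_size_um:.4g} um was supplied; using the supplied value",
                stacklevel=3,
            )
    except (KeyError, TypeError, ValueError, ZeroDivisionError):
        pass


def read_tiff_stack(
    paths: Sequence, voxel_size_um: float, name: str = ""
) -> VolumeImage:
    """Read an ordered list of 2D TIFF slices into a :class:`VolumeImage`.

    Slices are stacked along z in the given order.  All slices must share
    height, width and dtype; integer data is preserved bit-exactly.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise InputError("no TIFF slices given")
    slices = []
    for p in paths:
        try:
            with tifffile.TiffFile(p) as tf:
                arr = tf.asarray()
                _check_resolution_tag(tf.pages[0], voxel_size_um, p)
        except (OSError, ValueError, tifffile.TiffFileError) as exc:
            raise VolumeIOError(f"cannot read TIFF slice {p}: {exc}") from exc
        if arr.ndim == 3:  # a multipage file inside a stack listing
            slices.extend(arr)
        elif arr.ndim == 2:
            slices.append(arr)
        else:
            raise GeometryError(f"{p}: expected a 2D slice, got shape {arr.shape}")
    first = slices[0]
    for i, s in enumerate(slices):
        if s.shape != first.shape:
            raise GeometryError(
                f"slice {i} has shape {s.shape}, expected {first.shape}"
            )
        if s.dtype != first.dtype:
            raise GeometryError(
                f"slice {i} has dtype {s.dtype}, expected {first.dtype}"
            )
    return VolumeImage(np.stack(slices, axis=0), voxel_size_um, name=name)


def read_tiff_volume(path, voxel_size_um: float, name: str = "") -> VolumeImage:
    """Read a single multi-page TIFF (or a directory of slices) as a volume."""
    path = Path(path)
    if path.is_dir():
        slices = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        return read_tiff_stack(slices, voxel_size_um, name=name or path.name)
    return read_tiff_stack([path], voxel_size_um, name=name or path.stem)


def write_tiff_stack(volume, directory) -> list[Path]:
    """Write a volume as one TIFF per z-slice.

    File names are zero-padded so lexicographic order equals z order;
    ``read_tiff_stack(write_tiff_stack(v))`` reproduces integer and boolean
    data exactly.  Boolean masks are written as uint8 0/255.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise VolumeIOError(f"cannot create output directory {directory}: {exc}") from exc
    data = volume.data
    if data.dtype == bool:
        data = np.where(data, np.uint8(255), np.uint8(0))
    stem = getattr(volume, "name", "") or "slice"
    stem = "".join(c if (c.isalnum() or c in "-_") else "_" for c in stem)
    width = max(4, len(str(data.shape[0] - 1)))
    out = []
    for z in range(data.shape[0]):
        p = directory / f"{stem}_z{z:0{width}d}.tif"
        try:
            tifffile.imwrite(p, data[z])
        except OSError as exc:
            raise VolumeIOError(f"cannot write TIFF slice {p}: {exc}") from exc
        out.append(p)
    return out


def as_binary(volume: VolumeImage, kind: str = "vessel") -> BinaryVolume:
    """Interpret a grayscale volume as a mask: any nonzero voxel is true."""
    return BinaryVolume(volume.data != 0, volume.voxel_size_um, kind=kind,
                        name=volume.name)


def write_distance_map(dmap: DistanceMap, directory) -> list[Path]:
    """Export a signed distance map as a 32-bit float TIFF stack."""
    vol = VolumeImage(dmap.data.astype(np.float32), dmap.voxel_size_um,
                      name=(dmap.name or "distance"))
    return write_tiff_stack(vol, directory)
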