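"""Volume containers and I/O for isotropic 3D scan data.

Arrays are indexed ``[x, y, z]`` where ``z`` is the slice axis of a TIFF
stack.  Voxel spacing is isotropic and carried in micrometres; anisotropic
input is rejected rather than resampled.  Binary masks are serialized as
8-bit 0/255 volumes for interoperability with common viewers.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

#: hc in keV * nm (CODATA).  12.398 keV at lambda = 0.1 nm.
HC_KEV_NM = 1.239841984


class VolumeIOError(RuntimeError):
    """Raised for malformed volumes or missing metadata."""


@dataclass
class GrayVolume:
    """3D scalar field with isotropic voxel spacing in micrometres."""

    data: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected 3D data, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise VolumeIOError("all dimensions must be >= 1")
        if not self.spacing > 0:
            raise VolumeIOError("spacing must be positive")
        if np.issubdtype(self.data.dtype, np.signedinteger) and self.data.min() < 0:
            raise VolumeIOError("intensities must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """3D boolean mask on the same grid as its source :class:`GrayVolume`."""

    mask: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise VolumeIOError(f"expected 3D mask, got {self.mask.ndim}D")
        if any(s < 1 for s in self.mask.shape):
            raise VolumeIOError("all dimensions must be >= 1")
        if not self.spacing > 0:
            raise VolumeIOError("spacing must be positive")
        if self.mask.dtype != bool:
            self.mask = self.mask > 0

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_um3(self) -> float:
        return self.voxel_count() * self.spacing**3


def voxels_to_micrometres(n: float, spacing: float) -> float:
    """Convert a voxel count (or edge length) to micrometres.

    ``(92, 0.325) -> 29.9``; ``(2560, 0.325) -> 832``.
    """
    if n < 0:
        raise ValueError("voxel count must be non-negative")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    return n * spacing


def wavelength_to_energy(wavelength_nm: float) -> float:
    """Photon energy in keV for a wavelength in nm (``0.1 nm -> 12.398 keV``)."""
    if not wavelength_nm > 0:
        raise ValueError("wavelength must be positive")
    return HC_KEV_NM / wavelength_nm


def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".mhd", ".mha"):
        return "mhd-raw"
    return "tiff-stack"


def _to_xyz(zyx: np.ndarray) -> np.ndarray:
    # stacks arrive as (z, y, x); internal order is (x, y, z)
    return np.ascontiguousarray(zyx.transpose(2, 1, 0))


def _to_zyx(xyz: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(xyz.transpose(2, 1, 0))


def read_volume(path, format: str | None = None, spacing_um: float | None = None) -> GrayVolume:
    """Read a grayscale volume from a multi-page TIFF, a directory of
    numbered single-page TIFFs, or an MHD+RAW pair.

    Spacing is taken from the file metadata (ImageJ ``spacing`` for TIFF,
    ``ElementSpacing`` for MHD) unless overridden with ``spacing_um``.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"not found: {path}")
    fmt = format or _infer_format(path)

    if fmt == "mhd-raw":
        img = sitk.ReadImage(str(path))
        sx, sy, sz = img.GetSpacing()
        if not np.allclose([sx, sy], sz, rtol=1e-6):
            raise VolumeIOError("anisotropic spacing is not supported")
        spacing = spacing_um if spacing_um is not None else float(sx)
        data = _to_xyz(sitk.GetArrayFromImage(img))
        return GrayVolume(data, spacing)

    if fmt != "tiff-stack":
        raise VolumeIOError(f"unknown format: {fmt}")

    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in (".tif", ".tiff")),
            key=lambda f: [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", f.name)],
        )
        if not files:
            raise VolumeIOError(f"no TIFF slices in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeIOError(f"inconsistent slices: shapes {sorted(shapes)}")
        data = np.stack(slices, axis=0)
        meta_spacing = None
    else:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            shapes = {p.shape for p in pages}
            if len(shapes) != 1:
                raise VolumeIOError(f"inconsistent slices: shapes {sorted(shapes)}")
            data = np.stack(pages, axis=0) if len(pages) > 1 else pages[0][None]
            meta_spacing = None
            ij = tif.imagej_metadata
            if ij and "spacing" in ij:
                meta_spacing = float(ij["spacing"])

    if spacing_um is not None:
        spacing = spacing_um
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        raise VolumeIOError("spacing missing from metadata; pass spacing_um")
    if data.ndim != 3:
        data = data[None]
    return GrayVolume(_to_xyz(data), spacing)


def write_volume(volume: GrayVolume | BinaryVolume, path, format: str | None = None) -> None:
    """Write a volume; a round-trip read returns bit-identical data and spacing.

    Binary masks are written as 8-bit 0/255.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if isinstance(volume, BinaryVolume):
        data = volume.mask.astype(np.uint8) * 255
    else:
        data = volume.data
    spacing = volume.spacing

    if fmt == "mhd-raw":
        img = sitk.GetImageFromArray(_to_zyx(data))
        img.SetSpacing((spacing, spacing, spacing))
        sitk.WriteImage(img, str(path))
        return
    if fmt != "tiff-stack":
        raise VolumeIOError(f"unknown format: {fmt}")
    os.makedirs(path.parent, exist_ok=True)
    tifffile.imwrite(
        path,
        _to_zyx(data),
        imagej=True,
        metadata={"spacing": spacing, "unit": "um", "axes": "ZYX"},
    )


def read_mask(path, format: str | None = None, spacing_um: float | None = None) -> BinaryVolume:
    """Read a 0/255-serialized binary mask back as a boolean volume."""
    vol = read_volume(path, format=format, spacing_um=spacing_um)
    return BinaryVolume(vol.data > 0, vol.spacing)
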