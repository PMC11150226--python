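"""Volume/mask I/O, isotropic resampling and VOI-based grayscale normalization.

Conventions
-----------
Arrays are indexed ``[z, y, x]`` (the numpy view of a SimpleITK image);
``spacing_mm`` is stored in the same axis order, i.e. ``spacing_mm[0]`` is the
voxel pitch along the first array axis.  All voxel coordinates are 0-based.
World-space origin is kept in SimpleITK's ``(x, y, z)`` convention purely as
pass-through metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "Mask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "resample_isotropic",
    "normalize_grayscale",
]

#: relative tolerance used when comparing the grids of a volume and its mask
GRID_RTOL = 1e-4


@dataclass
class CTVolume:
    """A 3D scalar image with grid metadata.

    Attributes
    ----------
    data : (nz, ny, nx) float array
    spacing_mm : voxel pitch per array axis, strictly positive
    origin : world origin, SimpleITK ``(x, y, z)`` order (metadata only)
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Mask:
    """A binary region on the same grid as its paired :class:`CTVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _to_sitk(data: np.ndarray, spacing_mm, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data))
    img.SetSpacing(tuple(float(s) for s in spacing_mm[::-1]))  # sitk wants (x,y,z)
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _grids_match(a, b) -> bool:
    return a.shape == b.shape and np.allclose(a.spacing_mm, b.spacing_mm, rtol=GRID_RTOL)


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or NRRD scalar volume.

    Raises ``IOError`` for unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all reader failures in RuntimeError
        raise IOError(f"could not read image {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).astype(np.float64)
    return CTVolume(data=data, spacing_mm=img.GetSpacing()[::-1], origin=img.GetOrigin())


def read_mask(path: str | Path, reference: CTVolume) -> Mask:
    """Read a mask, binarize (any nonzero -> 1), and verify its grid against
    ``reference``; a mismatch beyond tolerance is a hard error naming both grids."""
    vol = read_volume(path)
    mask = Mask(data=vol.data, spacing_mm=vol.spacing_mm, origin=vol.origin)
    if not _grids_match(mask, reference):
        raise ValueError(
            "mask grid does not match reference volume: "
            f"mask shape={mask.shape} spacing={mask.spacing_mm} vs "
            f"volume shape={reference.shape} spacing={reference.spacing_mm}"
        )
    return mask


def write_volume(volume: CTVolume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(volume.data, volume.spacing_mm, volume.origin), str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    sitk.WriteImage(
        _to_sitk(mask.data.astype(np.uint8), mask.spacing_mm, mask.origin), str(path)
    )


def write_labels(labels: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write an integer label volume (e.g. a habitat map) as NIfTI/NRRD."""
    sitk.WriteImage(_to_sitk(labels.astype(np.int16), spacing_mm, (0.0, 0.0, 0.0)), str(path))


def resample_isotropic(
    volume: CTVolume,
    mask: Mask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[CTVolume, Mask]:
    """Resample a volume (trilinear) and its mask (nearest neighbour) to the
    requested spacing, 1 mm isotropic by default.

    The output size along each axis is ``round(n_in * s_in / s_out)`` (at least
    1).  Raises ``ValueError`` if the inputs are on different grids or the mask
    becomes empty after resampling.
    """
    if not _grids_match(mask, volume):
        raise ValueError(
            f"volume and mask are on different grids: {volume.shape}/{volume.spacing_mm}"
            f" vs {mask.shape}/{mask.spacing_mm}"
        )
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"requested spacing must be positive, got {spacing}")

    in_img = _to_sitk(volume.data, volume.spacing_mm, volume.origin)
    in_msk = _to_sitk(mask.data.astype(np.uint8), mask.spacing_mm, mask.origin)

    out_size_zyx = [
        max(1, int(round(n * s_in / s_out)))
        for n, s_in, s_out in zip(volume.shape, volume.spacing_mm, spacing)
    ]
    out_size_xyz = tuple(int(n) for n in out_size_zyx[::-1])
    out_spacing_xyz = tuple(spacing[::-1])

    def _resample(img: sitk.Image, interp) -> sitk.Image:
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing(out_spacing_xyz)
        rs.SetSize(out_size_xyz)
        rs.SetOutputOrigin(img.GetOrigin())
        rs.SetOutputDirection(img.GetDirection())
        rs.SetInterpolator(interp)
        rs.SetDefaultPixelValue(0)
        return rs.Execute(img)

    out_vol = sitk.GetArrayFromImage(_resample(in_img, sitk.sitkLinear)).astype(np.float64)
    out_msk = sitk.GetArrayFromImage(_resample(in_msk, sitk.sitkNearestNeighbor))

    new_vol = CTVolume(data=out_vol, spacing_mm=spacing, origin=volume.origin)
    new_msk = Mask(data=out_msk, spacing_mm=spacing, origin=mask.origin)
    if new_msk.n_voxels == 0:
        raise ValueError("mask is empty after resampling")
    return new_vol, new_msk


def normalize_grayscale(volume: CTVolume, mask: Mask) -> CTVolume:
    """Linearly map intensities to the 0-255 range using min/max statistics
    computed *inside the VOI only*; the whole volume is mapped and clipped.

    A constant in-mask region maps to all zeros (documented convention).  The
    map is invariant to affine intensity transforms ``a*x + b`` with ``a > 0``.
    """
    if mask.n_voxels == 0:
        raise ValueError("cannot normalize with an empty mask")
    inside = volume.data[mask.data > 0]
    lo, hi = float(inside.min()), float(inside.max())
    if hi <= lo:
        out = np.zeros_like(volume.data)
    else:
        out = np.clip((volume.data - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return CTVolume(data=out, spacing_mm=volume.spacing_mm, origin=volume.origin)
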