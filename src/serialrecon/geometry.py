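"""Core image containers shared by every pipeline stage.

Geometry convention
-------------------
World coordinates are millimetres with the origin at the corner of the first
voxel of the first slice: ``world = index * spacing``.  Axes are named
``(x, y, z)`` with ``z`` the slice (sectioning) axis; coronal sectioning of a
brain maps onto ``z`` without loss of generality.

Arrays are stored numpy-style: a 2D image is indexed ``pixels[y, x]`` and a
volume ``voxels[z, y, x]``.  Spacing tuples are always given in axis order
``(sx, sy[, sz])`` regardless of the memory layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "Image2D",
    "ImageVolume",
    "LabelVolume",
    "BinaryMask",
    "SectionStack",
]


def _check_spacing(spacing: Sequence[float], n: int) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != n:
        raise ValueError(f"expected {n} spacing components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class Image2D:
    """A single 2D section image (grayscale or 3-channel)."""

    pixels: np.ndarray  # (ny, nx) or (ny, nx, 3)
    spacing: tuple  # (sx, sy) mm / pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("Image2D expects a 2D or (ny, nx, 3) array")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("multi-channel images must have 3 channels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        self.spacing = _check_spacing(self.spacing, 2)

    @property
    def shape_xy(self) -> tuple:
        return (self.pixels.shape[1], self.pixels.shape[0])

    def gray(self) -> np.ndarray:
        """Luminance view for multi-channel images, identity for grayscale."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels @ np.array([0.2125, 0.7154, 0.0721])


@dataclass
class ImageVolume:
    """A 3D intensity volume; ``voxels[z, y, x]`` with spacing (sx, sy, sz)."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume expects a 3D array")
        self.spacing = _check_spacing(self.spacing, 3)

    @property
    def shape_xyz(self) -> tuple:
        nz, ny, nx = self.voxels.shape
        return (nx, ny, nz)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_image(self, z: int) -> Image2D:
        return Image2D(self.voxels[z], self.spacing[:2])


@dataclass
class LabelVolume:
    """Integer label volume; 0 is reserved for background."""

    labels: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume expects a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing, 3)

    @property
    def shape_xyz(self) -> tuple:
        nz, ny, nx = self.labels.shape
        return (nx, ny, nz)

    def values(self) -> np.ndarray:
        return np.unique(self.labels)

    def mask(self, label: Optional[int] = None) -> "BinaryMask":
        """Binary mask of one label, or of all foreground when label is None."""
        bits = self.labels > 0 if label is None else self.labels == label
        return BinaryMask(bits, self.spacing)


@dataclass
class BinaryMask:
    """Boolean mask, 2D or 3D, with the geometry of its source image."""

    bits: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.bits = np.asarray(self.bits).astype(bool)
        if self.bits.ndim not in (2, 3):
            raise ValueError("BinaryMask expects a 2D or 3D array")
        self.spacing = _check_spacing(self.spacing, self.bits.ndim)

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def cog_mm(self) -> np.ndarray:
        """Centre of gravity in world mm, axis order (x, y[, z])."""
        if self.count == 0:
            raise ValueError("cannot compute the centre of gravity of an empty mask")
        idx = np.argwhere(self.bits)  # rows are (y, x) or (z, y, x)
        centroid = idx.mean(axis=0)[::-1]  # -> (x, y[, z]) in index units
        return centroid * np.asarray(self.spacing)


@dataclass
class SectionStack:
    """Ordered 2D images of one modality plus slice-thickness metadata.

    ``meta`` carries one dict per slice (index, optional landmarks, anything a
    stage wants to attach); indices are strictly increasing.
    """

    slices: list  # list[Image2D]
    modality: str
    sz: float  # slice thickness, mm
    meta: list = field(default_factory=list)

    def __post_init__(self):
        if not self.slices:
            raise ValueError("a SectionStack needs at least one slice")
        shape0 = self.slices[0].pixels.shape
        spacing0 = self.slices[0].spacing
        for im in self.slices:
            if im.pixels.shape != shape0 or im.spacing != spacing0:
                raise ValueError("all slices must share shape and spacing")
        if self.sz <= 0:
            raise ValueError("slice thickness must be positive")
        if not self.meta:
            self.meta = [{"index": i} for i in range(len(self.slices))]
        indices = [m["index"] for m in self.meta]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("slice indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def spacing(self) -> tuple:
        return self.slices[0].spacing

    def as_volume(self) -> ImageVolume:
        """Naive stacking (no alignment): slices become the z axis."""
        vox = np.stack([im.gray() for im in self.slices], axis=0)
        return ImageVolume(vox, (*self.spacing, self.sz))


def geometry_equal(a: Any, b: Any, atol: float = 1e-9) -> bool:
    """True when two containers share array shape and spacing."""
    arr_a = getattr(a, "voxels", getattr(a, "labels", getattr(a, "bits", getattr(a, "pixels", None))))
    arr_b = getattr(b, "voxels", getattr(b, "labels", getattr(b, "bits", getattr(b, "pixels", None))))
    if arr_a is None or arr_b is None:
        raise TypeError("geometry_equal expects image containers")
    return arr_a.shape[: arr_a.ndim] == arr_b.shape[: arr_b.ndim] and np.allclose(
        a.spacing, b.spacing, atol=atol
    )
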