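"""Resampling of images, volumes and label maps through spatial transforms.

All resampling uses the inverse-mapping convention: the transform maps
coordinates of the *output* (fixed/reference) grid into the *input* (moving)
image, and the input is interpolated there.  Out-of-domain samples are 0.
Label maps are always resampled with nearest-neighbour interpolation so no
label values are invented at structure boundaries.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import BinaryMask, Image2D, ImageVolume, LabelVolume

__all__ = ["resample_volume", "resample_image2d", "resample_mask"]

_ORDERS = {"nearest": 0, "linear": 1, "cubic-bspline": 3}


def _order_for(interpolation: str, is_label: bool) -> int:
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}; expected one of {sorted(_ORDERS)}")
    if is_label and interpolation != "nearest":
        raise ValueError("label images must be resampled with nearest-neighbour interpolation")
    return _ORDERS[interpolation]


def _reference_geometry(reference, spacing, shape_xyz, ndim):
    if reference is not None:
        spacing = reference.spacing
        shape_xyz = reference.shape_xyz if ndim == 3 else reference.shape_xy
    if spacing is None or shape_xyz is None:
        raise ValueError("a reference geometry (object or spacing+shape) is required")
    return tuple(spacing), tuple(shape_xyz)


def _sample(data: np.ndarray, idx_cols: np.ndarray, order: int) -> np.ndarray:
    # idx_cols: (ndim, N) in array-axis order
    return map_coordinates(data, idx_cols, order=order, mode="constant", cval=0.0, prefilter=order > 1)


def resample_volume(
    volume: Union[ImageVolume, LabelVolume],
    transform,
    interpolation: str = "linear",
    reference=None,
    spacing: Optional[Sequence[float]] = None,
    shape_xyz: Optional[Tuple[int, int, int]] = None,
) -> Union[ImageVolume, LabelVolume]:
    """Resample a volume onto a reference grid through ``transform``.

    ``transform`` maps reference (fixed) world coordinates to the volume's
    (moving) world coordinates.  ``reference`` may be any volume-like object;
    otherwise pass ``spacing`` and ``shape_xyz`` explicitly.
    """
    is_label = isinstance(volume, LabelVolume)
    if is_label:
        interpolation = "nearest"
    order = _order_for(interpolation, is_label)
    ref_spacing, (nx, ny, nz) = _reference_geometry(reference, spacing, shape_xyz, 3)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.column_stack(
        [xx.ravel() * ref_spacing[0], yy.ravel() * ref_spacing[1], zz.ravel() * ref_spacing[2]]
    )
    moving = transform.apply(pts)
    src_spacing = np.asarray(volume.spacing)
    idx = (moving / src_spacing).T[::-1]  # world (x,y,z) -> array axes (z,y,x)

    data = volume.labels if is_label else volume.voxels
    if is_label:
        out = _sample(data.astype(float), idx, 0).round().astype(data.dtype)
        return LabelVolume(out.reshape(nz, ny, nx), ref_spacing)
    out = _sample(data.astype(float), idx, order)
    return ImageVolume(out.reshape(nz, ny, nx), ref_spacing)


def resample_image2d(
    image: Image2D,
    transform,
    interpolation: str = "linear",
    reference: Optional[Image2D] = None,
    spacing: Optional[Sequence[float]] = None,
    shape_xy: Optional[Tuple[int, int]] = None,
) -> Image2D:
    """2D analogue of :func:`resample_volume` (multi-channel images allowed)."""
    order = _order_for(interpolation, is_label=False)
    if reference is not None:
        spacing, shape_xy = reference.spacing, reference.shape_xy
    if spacing is None or shape_xy is None:
        spacing, shape_xy = image.spacing, image.shape_xy
    nx, ny = shape_xy
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.column_stack([xx.ravel() * spacing[0], yy.ravel() * spacing[1]])
    moving = transform.apply(pts)
    idx = (moving / np.asarray(image.spacing)).T[::-1]  # (y, x) array order

    if image.pixels.ndim == 2:
        out = _sample(image.pixels.astype(float), idx, order).reshape(ny, nx)
    else:
        out = np.stack(
            [_sample(image.pixels[..., c].astype(float), idx, order).reshape(ny, nx) for c in range(3)],
            axis=-1,
        )
    return Image2D(out, spacing)


def resample_mask(
    mask: BinaryMask,
    transform,
    reference=None,
    spacing: Optional[Sequence[float]] = None,
    shape=None,
) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask (2D or 3D)."""
    if mask.bits.ndim == 3:
        vol = LabelVolume(mask.bits.astype(np.uint8), mask.spacing)
        out = resample_volume(vol, transform, "nearest", reference=reference, spacing=spacing, shape_xyz=shape)
        return BinaryMask(out.labels > 0, out.spacing)
    img = Image2D(mask.bits.astype(float), mask.spacing)
    out = resample_image2d(img, transform, "nearest", reference=reference, spacing=spacing, shape_xy=shape)
    return BinaryMask(out.pixels > 0.5, out.spacing)
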