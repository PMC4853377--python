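"""Two-phase blockface reconstruction.

Phase one aligns the photographed blockface images on the circular chuck
markers by pure translations, which removes the camera/chuck repositioning
jitter but leaves the perspective error: tissue and markers sit at different
heights, so the tissue can be offset relative to the markers in a
slice-dependent way.  Phase two computes a running median volume along z —
the perspective offsets behave as outliers and are suppressed by the median —
and re-aligns each slice onto its median counterpart by an exhaustive-search
translation minimizing the sum of squared differences.  Finally the
reconstructed volume is separated from the surround with a 3D watershed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.segmentation import watershed

from .geometry import BinaryMask, Image2D, ImageVolume, SectionStack
from .resample import resample_image2d
from .transforms import Rigid2D

__all__ = [
    "MarkerSet",
    "detect_markers",
    "marker_align",
    "median_volume",
    "refine_to_median",
    "segment_brain",
    "reconstruct_blockface",
]


@dataclass
class MarkerSet:
    """Detected fiducials on one image: sub-pixel centers in mm, sorted by a
    stable row-major (y, then x) spatial key."""

    centers_mm: np.ndarray  # (n, 2) as (x, y)
    radii_mm: np.ndarray

    def __post_init__(self):
        self.centers_mm = np.atleast_2d(np.asarray(self.centers_mm, dtype=float))
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        if len(self.centers_mm) < 1:
            raise ValueError("a MarkerSet needs at least one center")

    def __len__(self) -> int:
        return len(self.centers_mm)

    @property
    def mean_center(self) -> np.ndarray:
        return self.centers_mm.mean(axis=0)


def detect_markers(
    image: Image2D,
    expected_n: int,
    threshold_frac: float = 0.75,
    min_area_px: int = 5,
    polarity: str = "bright",
) -> MarkerSet:
    """Detect ``expected_n`` circular fiducials by thresholding, connected
    components and intensity-weighted sub-pixel centroids.

    ``threshold_frac`` places the threshold at that fraction of the image's
    dynamic range (markers must be the brightest — or darkest, for
    ``polarity='dark'`` — objects in the frame).
    """
    gray = image.gray().astype(float)
    if polarity == "dark":
        gray = -gray
    elif polarity != "bright":
        raise ValueError("polarity must be 'bright' or 'dark'")
    lo, hi = float(gray.min()), float(gray.max())
    if hi - lo < 1e-12:
        raise ValueError("blank image: no markers detectable")
    thr = lo + threshold_frac * (hi - lo)
    binary = gray > thr
    lab, n = ndi.label(binary)
    comps = [i for i in range(1, n + 1) if (lab == i).sum() >= min_area_px]
    if len(comps) < expected_n:
        raise ValueError(f"found only {len(comps)} circular components, expected {expected_n}")
    # Keep the expected_n largest components (tissue never reaches the marker
    # intensity band under the configured polarity/threshold).
    comps.sort(key=lambda i: -(lab == i).sum())
    comps = comps[:expected_n]

    sx, sy = image.spacing
    centers, radii = [], []
    for i in comps:
        ys, xs = np.nonzero(lab == i)
        w = gray[ys, xs] - thr
        cx = float(np.average(xs, weights=w))
        cy = float(np.average(ys, weights=w))
        area = len(xs)
        centers.append((cx * sx, cy * sy))
        radii.append(np.sqrt(area / np.pi) * sx)
    centers = np.asarray(centers)
    # Row-major (y, then x) with the row key quantized to marker-sized bins,
    # so the order is stable under sub-marker jitter of nominally equal rows.
    row_bin = max(4.0 * float(np.median(radii)), 2.0 * sy)
    order = np.lexsort((centers[:, 0], np.round(centers[:, 1] / row_bin)))
    return MarkerSet(centers_mm=centers[order], radii_mm=np.asarray(radii)[order])


def marker_align(stack: SectionStack, expected_n: int = 4, **detect_kwargs) -> List[Rigid2D]:
    """Translation-only chain aligning every slice's mean marker centroid onto
    slice 0's.  Returned transforms are forward maps (slice -> slice-0 frame);
    rotations are zero by construction."""
    markers = []
    for i, im in enumerate(stack.slices):
        try:
            markers.append(detect_markers(im, expected_n, **detect_kwargs))
        except ValueError as err:
            raise ValueError(f"slice {i}: {err}") from err
    counts = {len(m) for m in markers}
    if len(counts) > 1:
        raise ValueError(f"marker count mismatch across slices: {sorted(counts)}")
    ref = markers[0].mean_center
    return [Rigid2D(theta=0.0, t=tuple(ref - m.mean_center)) for m in markers]


def apply_slice_transforms(stack: SectionStack, transforms: List[Rigid2D]) -> ImageVolume:
    """Resample every slice through the inverse of its forward transform and
    stack into a volume (grayscale)."""
    if len(transforms) != len(stack):
        raise ValueError("one transform per slice is required")
    out = [
        resample_image2d(Image2D(im.gray(), im.spacing), tr.inverse(), "linear").pixels
        for im, tr in zip(stack.slices, transforms)
    ]
    return ImageVolume(np.stack(out, axis=0), (*stack.spacing, stack.sz))


def median_volume(volume: ImageVolume, radius: int = 5) -> ImageVolume:
    """Voxelwise running median along z over a window of ``2*radius + 1``
    slices, clipped at the stack ends."""
    if radius < 1:
        raise ValueError("median radius must be at least 1")
    nz = volume.n_slices
    if nz < 2 * radius + 1:
        raise ValueError(f"volume has {nz} slices; needs at least {2 * radius + 1} for radius {radius}")
    vox = volume.voxels
    out = np.empty_like(vox, dtype=float)
    for z in range(nz):
        z0, z1 = max(0, z - radius), min(nz, z + radius + 1)
        out[z] = np.median(vox[z0:z1], axis=0)
    return ImageVolume(out, volume.spacing)


def _leave_one_out_median(volume: ImageVolume, radius: int) -> ImageVolume:
    """Median along z over the window excluding the slice itself.

    Used by the reconstruction pipeline as the phase-two reference: a slice
    carrying a perspective offset must not vote on its own reference, or the
    median reproduces the offset wherever the tissue geometry changes
    monotonically along z (ties break toward the centre slice).
    """
    if radius < 1:
        raise ValueError("median radius must be at least 1")
    nz = volume.n_slices
    vox = volume.voxels
    out = np.empty_like(vox, dtype=float)
    for z in range(nz):
        z0, z1 = max(0, z - radius), min(nz, z + radius + 1)
        window = np.concatenate([vox[z0:z], vox[z + 1 : z1]], axis=0)
        loo = np.median(window, axis=0)
        # A slice whose neighbours carry no tissue has no external reference;
        # fall back to the self-inclusive median (which then changes nothing).
        try:
            support = int((loo > threshold_otsu(loo)).sum()) if loo.std() > 1e-12 else 0
        except ValueError:
            support = 0
        out[z] = loo if support >= 100 else np.median(vox[z0:z1], axis=0)
    return ImageVolume(out, volume.spacing)


def _ssd_translation_map(
    fixed: np.ndarray, moving: np.ndarray, search_px: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """SSD at every integer shift in [-search, search]^2 of ``moving``,
    restricted to ``mask`` on the fixed frame, via FFT cross-correlations:
    SSD(s) = sum m f^2 - 2 * xcorr(m f, g)(s) + xcorr(m, g^2)(s)."""
    ny, nx = fixed.shape
    if mask is None:
        mask = np.ones_like(fixed)
    m = mask.astype(float)
    pad_y, pad_x = ny + 2 * search_px, nx + 2 * search_px
    shifts = np.arange(-search_px, search_px + 1)

    def _xcorr(a, b):
        # c[d] = sum_y a[y] * b[y - d], zero-padded (linear, no wrap for |d|<=search)
        A = np.fft.rfft2(a, s=(pad_y, pad_x))
        B = np.fft.rfft2(b, s=(pad_y, pad_x))
        c = np.fft.irfft2(A * np.conj(B), s=(pad_y, pad_x))
        return c[np.ix_(shifts % pad_y, shifts % pad_x)]

    return (m * fixed**2).sum() - 2.0 * _xcorr(m * fixed, moving) + _xcorr(m, moving**2)


def _subpixel_1d(vals: np.ndarray) -> float:
    """Parabola vertex through three samples at -1, 0, +1 (0 when flat)."""
    denom = vals[0] - 2 * vals[1] + vals[2]
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (vals[0] - vals[2]) / denom, -0.5, 0.5))


def refine_to_median(
    volume: ImageVolume, median_vol: ImageVolume, search_px: int = 15,
    min_support_px: int = 100,
) -> List[Rigid2D]:
    """Per-slice SSD-minimizing translation onto the corresponding median
    slice: exhaustive integer search over ±``search_px`` followed by a
    quadratic sub-pixel fit.  Forward maps, composable with the marker-phase
    output.

    Degenerate slices pass through as identity with a warning: constant
    slices, and slices whose median reference carries fewer than
    ``min_support_px`` foreground pixels (too little structure for a
    meaningful translation estimate)."""
    if volume.voxels.shape != median_vol.voxels.shape:
        raise ValueError("volume and median volume geometries must match")
    sx, sy = volume.spacing[:2]
    global_range = float(np.ptp(median_vol.voxels))
    out: List[Rigid2D] = []
    for z in range(volume.n_slices):
        mov = volume.voxels[z].astype(float)
        fix = median_vol.voxels[z].astype(float)
        if mov.std() < 1e-12:
            warnings.warn(f"slice {z} is constant; returning identity", stacklevel=2)
            out.append(Rigid2D())
            continue
        # Restrict the metric to the (dilated) foreground of the median slice:
        # tissue drives the alignment, frame-wide background noise does not.
        mask = None
        support, contrast = 0, 0.0
        if fix.std() > 1e-12:
            try:
                thr = threshold_otsu(fix)
                fg = fix > thr
                support = int(fg.sum())
                if fg.any() and (~fg).any():
                    contrast = float(fix[fg].mean() - fix[~fg].mean())
                if 20 <= support < fg.size:
                    mask = ndi.binary_dilation(fg, iterations=4).astype(float)
            except ValueError:
                pass
        if support < min_support_px or contrast < 0.05 * global_range:
            warnings.warn(
                f"slice {z}: median reference too weak (support {support} px, "
                f"contrast {contrast:.3g}); returning identity", stacklevel=2,
            )
            out.append(Rigid2D())
            continue
        ssd = _ssd_translation_map(fix, mov, search_px, mask)
        iy, ix = np.unravel_index(np.argmin(ssd), ssd.shape)
        dy, dx = iy - search_px, ix - search_px
        fx = _subpixel_1d(ssd[iy, max(ix - 1, 0) : ix + 2]) if 0 < ix < ssd.shape[1] - 1 else 0.0
        fy = _subpixel_1d(ssd[max(iy - 1, 0) : iy + 2, ix]) if 0 < iy < ssd.shape[0] - 1 else 0.0
        out.append(Rigid2D(theta=0.0, t=((dx + fx) * sx, (dy + fy) * sy)))
    return out


def segment_brain(
    volume: ImageVolume,
    bg_quantile: float = 0.50,
    fg_quantile: float = 0.92,
    closing_radius: int = 2,
) -> BinaryMask:
    """3D watershed on the gradient magnitude, seeded from background and
    foreground intensity quantiles; returns the largest connected foreground
    basin, morphologically closed and hole-filled."""
    vox = volume.voxels.astype(float)
    lo = np.quantile(vox, bg_quantile)
    hi = np.quantile(vox, fg_quantile)
    if hi - lo < 1e-9:
        raise ValueError("no tissue/background contrast: empty foreground")
    grad = ndi.gaussian_gradient_magnitude(vox, sigma=1.0)
    seeds = np.zeros(vox.shape, dtype=np.int32)
    seeds[vox <= lo] = 1
    seeds[vox >= hi] = 2
    ws = watershed(grad, markers=seeds)
    fg = ws == 2
    if not fg.any():
        raise ValueError("watershed produced an empty foreground")
    lab, n = ndi.label(fg)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    fg = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        fg = ndi.binary_closing(fg, structure=ball(closing_radius))
    fg = ndi.binary_fill_holes(fg)
    lab, n = ndi.label(fg)  # closing can merge nothing but re-check components
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask(fg, volume.spacing)


def _erase_markers(stack: SectionStack, expected_n: int, **detect_kwargs) -> SectionStack:
    """Blank the fiducial disks (replaced by the image minimum) so that the
    median/SSD refinement phase is driven by tissue alone — the markers are
    already exactly corrected by phase one and would otherwise pin the
    perspective offset in place."""
    out = []
    for im in stack.slices:
        ms = detect_markers(im, expected_n, **detect_kwargs)
        gray = im.gray().astype(float).copy()
        ny, nx = gray.shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        bg = float(np.median(gray[gray <= np.quantile(gray, 0.5)]))
        for (cx, cy), r in zip(ms.centers_mm / np.asarray(im.spacing), ms.radii_mm / im.spacing[0]):
            gray[np.hypot(xx - cx, yy - cy) <= 2.0 * r + 1.5] = bg
        out.append(Image2D(gray, im.spacing))
    return SectionStack(slices=out, modality=stack.modality, sz=stack.sz,
                        meta=[dict(m) for m in stack.meta])


def reconstruct_blockface(
    stack: SectionStack,
    expected_markers: int = 4,
    median_radius: int = 5,
    search_px: int = 15,
    **detect_kwargs,
) -> Tuple[ImageVolume, List[Rigid2D]]:
    """Full two-phase reconstruction; returns the refined marker-free volume
    and the composed per-slice forward transforms (phase 2 ∘ phase 1)."""
    phase1 = marker_align(stack, expected_markers, **detect_kwargs)
    tissue_stack = _erase_markers(stack, expected_markers, **detect_kwargs)
    vol1 = apply_slice_transforms(tissue_stack, phase1)
    med = _leave_one_out_median(vol1, radius=median_radius)
    phase2 = refine_to_median(vol1, med, search_px=search_px)
    composed = [b.compose(a) for a, b in zip(phase1, phase2)]
    vol2 = apply_slice_transforms(tissue_stack, composed)
    return vol2, composed
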