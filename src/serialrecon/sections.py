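"""Alignment of distorted section images to their reconstructed blockface
slices, with one strategy per modality.

* histology: full-contrast tissue — centre-of-gravity superposition followed by
  an exhaustive rotation search with the sum of squared differences.
* autoradiograph: images contain zero-signal "empty regions" where the probed
  receptor is not expressed, which breaks area-based overlap criteria.  The
  stack is first made internally coherent by chaining feature-based
  (scale-invariant keypoints) rigid matches between consecutive sections, then
  anchored to the blockface with landmark-derived rigid transforms on every
  K-th slice, interpolated in between.
* pli: orientation-coded images — COG initialization, rigid registration on
  mutual information, then a slice-wise cubic B-spline refinement with a fixed
  5×6 control grid on the sum of squared differences.

Direction conventions: every 2D estimator here returns the *forward* motion
(section -> blockface frame) except :func:`pli_refine`, whose non-invertible
B-spline stage makes it return resampling maps (blockface -> section).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage as ndi
from skimage.feature import SIFT, match_descriptors
from skimage.filters import threshold_otsu
from skimage.morphology import binary_closing, disk

from .geometry import BinaryMask, Image2D, ImageVolume, SectionStack
from .resample import resample_image2d
from .similarity import mutual_information, ssd as ssd_metric
from .transforms import BSplineField, ComposedTransform, Rigid2D

__all__ = [
    "tissue_mask_2d",
    "cog_align",
    "brute_force_rotation",
    "feature_match_rigid",
    "landmark_rigid",
    "interpolate_rigid",
    "pli_refine",
    "reconstruct_stack",
    "SectionReconConfig",
]


def tissue_mask_2d(image: Image2D, closing_radius: int = 2) -> BinaryMask:
    """Tissue/background separation: Otsu threshold, largest connected
    component, morphological closing."""
    gray = image.gray().astype(float)
    if gray.max() - gray.min() < 1e-12:
        raise ValueError("uniform image: no tissue mask extractable")
    thr = threshold_otsu(gray)
    binary = gray > thr
    if not binary.any():
        raise ValueError("empty tissue mask after thresholding")
    lab, n = ndi.label(binary)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        mask = binary_closing(mask, disk(closing_radius))
    return BinaryMask(mask, image.spacing)


def cog_align(section_mask: BinaryMask, blockface_mask: BinaryMask) -> Rigid2D:
    """Translation mapping the section's binary COG onto the blockface's."""
    t = blockface_mask.cog_mm() - section_mask.cog_mm()
    return Rigid2D(theta=0.0, t=tuple(t))


def brute_force_rotation(
    section: Image2D,
    blockface: Image2D,
    step_deg: float = 0.5,
    range_deg: float = 180.0,
    cog_translation: Optional[Rigid2D] = None,
    full_output: bool = False,
):
    """Exhaustive SSD rotation search about the blockface COG.

    Every angle in ``[-range, range)`` at ``step_deg`` is tested on top of the
    (already applied) COG translation; ties resolve to the smallest |angle|.
    Returns the winning rotation composed with the COG translation (forward
    section -> blockface map).
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if cog_translation is None:
        cog_translation = cog_align(tissue_mask_2d(section), tissue_mask_2d(blockface))
    center = tuple(tissue_mask_2d(blockface).cog_mm())
    angles = np.arange(-range_deg, range_deg, step_deg)
    ssds = np.empty(len(angles))
    bf = blockface.gray().astype(float)
    for i, ang in enumerate(angles):
        fwd = Rigid2D(theta=np.deg2rad(ang), center=center).compose(cog_translation)
        moved = resample_image2d(section, fwd.inverse(), "linear", reference=blockface)
        ssds[i] = ((moved.gray() - bf) ** 2).sum()
    order = np.lexsort((np.abs(angles), ssds))
    best = order[0]
    result = Rigid2D(theta=np.deg2rad(angles[best]), center=center).compose(cog_translation)
    if full_output:
        return result, angles, ssds
    return result


def landmark_rigid(pairs: np.ndarray) -> Rigid2D:
    """Closed-form least-squares rigid transform from paired points.

    ``pairs`` is (n, 4) of [xs, ys, xb, yb] mm (section, blockface); the fit
    is a 2D orthogonal Procrustes: demean, SVD of the cross-covariance,
    rotation (no reflection) then translation.  Returns the forward
    section -> blockface map.
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[0] < 2 or pairs.shape[1] != 4:
        raise ValueError("at least 2 landmark pairs of [xs, ys, xb, yb] are required")
    src, dst = pairs[:, :2], pairs[:, 2:]
    if np.ptp(src, axis=0).max() < 1e-12:
        raise ValueError("landmark points are coincident; rigid fit is degenerate")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, np.linalg.det(Vt.T @ U.T)])
    R = Vt.T @ D @ U.T
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    t = mu_d - R @ mu_s
    return Rigid2D(theta=theta, t=tuple(t))


def _consensus_rigid(pts_a: np.ndarray, pts_b: np.ndarray, inlier_mm: float) -> Rigid2D:
    """Robust rigid fit: every 2-point hypothesis is scored by its inlier
    count, the best consensus set is refit by least squares, then one round
    of distance-based rejection (> 3x median residual) and a final refit."""
    n = len(pts_a)
    best_inliers, best_count = None, -1
    for i in range(min(n, 40)):
        for j in range(i + 1, min(n, 40)):
            try:
                cand = landmark_rigid(np.column_stack([pts_a[[i, j]], pts_b[[i, j]]]))
            except ValueError:
                continue
            resid = np.linalg.norm(cand.apply(pts_a) - pts_b, axis=1)
            count = int((resid < inlier_mm).sum())
            if count > best_count:
                best_count, best_inliers = count, resid < inlier_mm
    if best_count < 2:
        raise ValueError("no rigid consensus among the keypoint matches")
    fit = landmark_rigid(np.column_stack([pts_a[best_inliers], pts_b[best_inliers]]))
    resid = np.linalg.norm(fit.apply(pts_a) - pts_b, axis=1)
    keep = resid <= 3.0 * max(np.median(resid), 1e-12)
    if keep.sum() >= 2:
        fit = landmark_rigid(np.column_stack([pts_a[keep], pts_b[keep]]))
    return fit


def feature_match_rigid(image_a: Image2D, image_b: Image2D, max_ratio: float = 0.75) -> Rigid2D:
    """Rigid fit between scale-invariant keypoint matches of two images.

    Keypoints and gradient-orientation descriptors are detected on both
    images and matched with a ratio test (plus cross-check); the surviving
    pairs feed a consensus-based rigid fit that tolerates gross mismatches
    (smooth tissue textures produce repetitive descriptors).  Raises when
    fewer than two stable matches survive; callers fall back to COG
    alignment.  Forward a -> b map.
    """
    def _extract(img: Image2D):
        g = img.gray().astype(float)
        rng_ = g.max() - g.min()
        if rng_ < 1e-12:
            raise ValueError("textureless image: no keypoints")
        sift = SIFT()
        sift.detect_and_extract((g - g.min()) / rng_)
        return sift.keypoints, sift.descriptors

    try:
        kp_a, des_a = _extract(image_a)
        kp_b, des_b = _extract(image_b)
    except RuntimeError as err:  # skimage raises when no keypoints survive
        raise ValueError(f"keypoint detection failed: {err}") from err
    matches = match_descriptors(des_a, des_b, max_ratio=max_ratio, cross_check=True)
    if len(matches) < 2:
        raise ValueError(f"only {len(matches)} keypoint matches survive the ratio test")
    sp = np.asarray(image_a.spacing)
    pts_a = kp_a[matches[:, 0]][:, ::-1] * sp  # (row, col) -> (x, y) mm
    pts_b = kp_b[matches[:, 1]][:, ::-1] * np.asarray(image_b.spacing)
    return _consensus_rigid(pts_a, pts_b, inlier_mm=1.5 * sp[0])


def _center0(tr: Rigid2D) -> Tuple[float, float, float]:
    """(theta, tx, ty) of the center-at-origin parameterization."""
    H = tr.matrix()
    return float(np.arctan2(H[1, 0], H[0, 0])), float(H[0, 2]), float(H[1, 2])


def interpolate_rigid(anchors: Dict[int, Rigid2D], k: int) -> Rigid2D:
    """Linear interpolation of (theta, tx, ty) between the bracketing anchor
    slices, with angle unwrapping across the anchor sequence; outside the
    anchor range the nearest anchor is held constant."""
    if not anchors:
        raise ValueError("no anchors to interpolate between")
    idx = np.array(sorted(anchors))
    params = np.array([_center0(anchors[i]) for i in idx])
    params[:, 0] = np.unwrap(params[:, 0])
    if k <= idx[0]:
        p = params[0]
    elif k >= idx[-1]:
        p = params[-1]
    else:
        j = int(np.searchsorted(idx, k, side="right"))
        i0, i1 = idx[j - 1], idx[j]
        w = (k - i0) / (i1 - i0)
        p = (1 - w) * params[j - 1] + w * params[j]
    return Rigid2D(theta=float(p[0]), t=(float(p[1]), float(p[2])))


# ---------------------------------------------------------------------------
# PLI refinement (rigid MI + 5x6 B-spline SSD), SimpleITK-backed
# ---------------------------------------------------------------------------

def _signal_2d(image: Image2D) -> Image2D:
    """Scalar signal of a section: for orientation-coded (hue = direction)
    3-channel images the value channel (channel max) carries the tissue
    signal; grayscale passes through.  Rescaled to [0, 1]."""
    px = image.pixels.max(axis=2) if image.pixels.ndim == 3 else image.pixels
    px = px.astype(float)
    rng_ = np.ptp(px)
    if rng_ > 1e-12:
        px = (px - px.min()) / rng_
    return Image2D(px, image.spacing)


def _to_sitk2d(image: Image2D) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(image.gray().astype(np.float64)))
    img.SetSpacing(tuple(image.spacing))
    return img


def _euler2d_to_rigid(tx: sitk.Euler2DTransform) -> Rigid2D:
    return Rigid2D(theta=float(tx.GetAngle()), t=tuple(tx.GetTranslation()), center=tuple(tx.GetCenter()))


def _bspline2d_to_field(tx: sitk.BSplineTransform) -> BSplineField:
    fp = np.asarray(tx.GetFixedParameters(), dtype=float)
    gsize = fp[0:2].astype(int)
    origin, spacing = fp[2:4], fp[4:6]
    coeff = np.asarray(tx.GetParameters(), dtype=float).reshape(2, gsize[1], gsize[0])
    coeff = np.transpose(coeff, (2, 1, 0))  # -> (gx, gy, 2)
    return BSplineField(grid_origin=origin, grid_spacing=spacing, coefficients=coeff)


def pli_refine(
    section: Image2D,
    blockface_slice: Image2D,
    section_mask: Optional[BinaryMask] = None,
    blockface_mask: Optional[BinaryMask] = None,
    grid_size: Tuple[int, int] = (5, 6),
    rigid_iterations: int = 150,
    bspline_iterations: int = 60,
) -> Tuple[Rigid2D, BSplineField, dict]:
    """COG init -> rigid (mutual information) -> cubic B-spline with a fixed
    control grid (default 5x6) on SSD, restricted to the mask union.

    Returns ``(rigid_map, bspline_field, info)`` where both transforms are
    resampling maps (blockface -> section); the final map is
    ``p -> rigid(p + d(p))``.  If a stage leaves the metric worse than its
    initialization the stage is dropped and ``info['flag']`` says so.
    """
    sec_sig = _signal_2d(section)
    bf_sig = _signal_2d(blockface_slice)
    if section_mask is None:
        section_mask = tissue_mask_2d(sec_sig)
    if blockface_mask is None:
        blockface_mask = tissue_mask_2d(bf_sig)
    fwd_cog = cog_align(section_mask, blockface_mask)
    init_map = fwd_cog.inverse()  # blockface -> section

    fixed = _to_sitk2d(bf_sig)
    moving = _to_sitk2d(sec_sig)

    # Metric mask: union of the blockface mask and the COG-mapped section mask.
    from .resample import resample_mask

    sec_in_bf = resample_mask(section_mask, init_map, spacing=blockface_slice.spacing,
                              shape=blockface_slice.shape_xy)
    union = ndi.binary_dilation(blockface_mask.bits | sec_in_bf.bits, iterations=3)
    mask_img = sitk.GetImageFromArray(union.astype(np.uint8))
    mask_img.CopyInformation(fixed)

    def _metrics(resample_map):
        moved = resample_image2d(sec_sig, resample_map, "linear", reference=bf_sig)
        bf = bf_sig.pixels
        return (
            mutual_information(moved.pixels, bf, mask=union),
            ssd_metric(moved.pixels, bf, mask=union),
        )

    mi_init, _ = _metrics(init_map)
    info = {"flag": "", "mi_init": mi_init}

    # --- rigid on mutual information ---
    # Seed the angle with a coarse SSD sweep on the signal images (near-circular
    # sections leave the MI gradient too flat to pull in several degrees).
    coarse = brute_force_rotation(
        sec_sig, bf_sig, step_deg=1.0, range_deg=15.0, cog_translation=fwd_cog
    )
    init_map = coarse.inverse()
    mi_coarse, _ = _metrics(init_map)
    if mi_coarse < mi_init:
        init_map = fwd_cog.inverse()
    else:
        mi_init = mi_coarse
    euler = sitk.Euler2DTransform()
    c = np.asarray(blockface_mask.cog_mm())
    H0 = init_map.matrix()
    euler.SetCenter(tuple(c))
    euler.SetAngle(float(np.arctan2(H0[1, 0], H0[0, 0])))
    euler.SetTranslation(tuple(H0[:2, :2] @ c + H0[:2, 2] - c))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescent(
        learningRate=1.0, numberOfIterations=rigid_iterations,
        estimateLearningRate=reg.Once,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(euler, inPlace=True)
    try:
        reg.Execute(fixed, moving)
        rigid_map = _euler2d_to_rigid(euler)
        mi_rigid, ssd_rigid = _metrics(rigid_map)
    except RuntimeError:  # optimizer left the overlap region entirely
        mi_rigid = -np.inf
    if mi_rigid < mi_init:
        warnings.warn("rigid stage degraded mutual information; keeping COG init", stacklevel=2)
        rigid_map = init_map
        mi_rigid, ssd_rigid = mi_init, _metrics(init_map)[1]
        info["flag"] = "rigid_degraded"
    info["mi_rigid"] = mi_rigid

    # --- B-spline (fixed control grid) on SSD ---
    mesh = [max(1, grid_size[0] - 3), max(1, grid_size[1] - 3)]
    bsp = sitk.BSplineTransformInitializer(fixed, mesh, 3)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=bspline_iterations)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    rigid_sitk = sitk.Euler2DTransform()
    rigid_sitk.SetCenter(tuple(rigid_map.center))
    rigid_sitk.SetAngle(rigid_map.theta)
    rigid_sitk.SetTranslation(tuple(rigid_map.t))
    reg.SetMovingInitialTransform(rigid_sitk)
    reg.SetInitialTransform(bsp, inPlace=True)
    try:
        reg.Execute(fixed, moving)
        field = _bspline2d_to_field(bsp)
        final_map = ComposedTransform([rigid_map, field])
        _, ssd_final = _metrics(final_map)
    except RuntimeError:
        field = _bspline2d_to_field(sitk.BSplineTransformInitializer(fixed, mesh, 3))
        ssd_final = np.inf
    if field.max_displacement() > 0.5 * float(field.grid_spacing.min()):
        ssd_final = np.inf  # fold-over territory: treat as divergence
    if ssd_final > ssd_rigid:
        warnings.warn("B-spline stage degraded SSD; keeping rigid result", stacklevel=2)
        field = BSplineField(
            grid_origin=field.grid_origin, grid_spacing=field.grid_spacing,
            coefficients=np.zeros_like(field.coefficients),
        )
        info["flag"] = (info["flag"] + "+" if info["flag"] else "") + "bspline_degraded"
        ssd_final = ssd_rigid
    info["ssd_final"] = ssd_final
    return rigid_map, field, info


# ---------------------------------------------------------------------------
# Stack reconstruction dispatch
# ---------------------------------------------------------------------------

@dataclass
class SectionReconConfig:
    rotation_step_deg: float = 0.5
    rotation_range_deg: float = 180.0
    sift_max_ratio: float = 0.75
    grid_size: Tuple[int, int] = (5, 6)
    min_tissue_px: int = 50


def _bf_slice_index(stack: SectionStack, i: int, ratio: float) -> int:
    meta = stack.meta[i]
    if "blockface_slice" in meta:
        return int(meta["blockface_slice"])
    return int(round(i * ratio))


def _histology_forward(section, bf_img, cfg) -> Rigid2D:
    sec_mask = tissue_mask_2d(section)
    bf_mask = tissue_mask_2d(bf_img)
    cog = cog_align(sec_mask, bf_mask)
    return brute_force_rotation(
        section, bf_img, cfg.rotation_step_deg, cfg.rotation_range_deg, cog_translation=cog
    )


def reconstruct_stack(
    stack: SectionStack,
    blockface_volume: ImageVolume,
    strategy: str,
    landmarks: Optional[Dict[int, np.ndarray]] = None,
    config: Optional[SectionReconConfig] = None,
) -> Tuple[ImageVolume, List[dict]]:
    """Align every section to its corresponding blockface slice.

    ``strategy`` is one of ``histology`` (COG + exhaustive rotation),
    ``autoradiograph`` (feature-based intra-stack chain to slice 0, landmark
    anchors, interpolation) or ``pli`` (rigid MI + 5x6 B-spline).  Sections
    with less tissue than ``config.min_tissue_px`` pass through unaligned.

    Returns the reconstructed volume (blockface in-plane geometry, one output
    slice per section) and per-section records with the estimated transforms.
    """
    cfg = config or SectionReconConfig()
    if strategy not in ("histology", "autoradiograph", "pli"):
        raise ValueError(f"unknown strategy {strategy!r}")
    ratio = stack.sz / blockface_volume.spacing[2]
    n = len(stack)
    bf_slices = [blockface_volume.slice_image(_bf_slice_index(stack, i, ratio)) for i in range(n)]

    def _tissue_ok(img: Image2D) -> bool:
        try:
            return tissue_mask_2d(img).count >= cfg.min_tissue_px
        except ValueError:
            return False

    usable = [_tissue_ok(im) for im in stack.slices]
    records: List[dict] = [
        {"index": i, "blockface_slice": _bf_slice_index(stack, i, ratio), "flag": "", "forward": None,
         "resample": None}
        for i in range(n)
    ]

    if strategy == "autoradiograph":
        if landmarks is None:
            landmarks = {
                m["index"]: m["landmarks"] for m in stack.meta if "landmarks" in m
            }
        if not landmarks:
            raise ValueError("the autoradiograph strategy requires landmark files")
        # intra-stack chain to slice 0
        chain: List[Rigid2D] = [Rigid2D()]
        for i in range(1, n):
            step = Rigid2D()
            if usable[i] and usable[i - 1]:
                try:
                    step = feature_match_rigid(stack.slices[i], stack.slices[i - 1], cfg.sift_max_ratio)
                except ValueError:
                    try:
                        step = cog_align(tissue_mask_2d(stack.slices[i]), tissue_mask_2d(stack.slices[i - 1]))
                        records[i]["flag"] = "feature_fallback_cog"
                    except ValueError:
                        records[i]["flag"] = "feature_fallback_identity"
            chain.append(chain[-1].compose(step))
        anchors: Dict[int, Rigid2D] = {}
        for k, pairs in sorted(landmarks.items()):
            pairs = np.asarray(pairs, dtype=float)
            s_pre = chain[k].apply(pairs[:, :2])
            anchors[k] = landmark_rigid(np.column_stack([s_pre, pairs[:, 2:]]))
        for i in range(n):
            fwd = interpolate_rigid(anchors, i).compose(chain[i])
            records[i]["forward"] = fwd
            records[i]["resample"] = fwd.inverse()

    else:
        for i in range(n):
            if not usable[i] or not _tissue_ok(bf_slices[i]):
                records[i]["flag"] = "insufficient_tissue"
                records[i]["resample"] = Rigid2D()
                continue
            if strategy == "histology":
                try:
                    fwd = _histology_forward(stack.slices[i], bf_slices[i], cfg)
                    records[i]["forward"] = fwd
                    records[i]["resample"] = fwd.inverse()
                except ValueError as err:
                    warnings.warn(f"slice {i}: {err}; passing through unaligned", stacklevel=2)
                    records[i]["flag"] = "alignment_failed"
                    records[i]["resample"] = Rigid2D()
            else:  # pli
                rigid_map, fld, info = pli_refine(
                    stack.slices[i], bf_slices[i], grid_size=cfg.grid_size
                )
                records[i]["flag"] = info["flag"]
                records[i]["forward"] = rigid_map.inverse()
                records[i]["resample"] = (
                    ComposedTransform([rigid_map, fld]) if fld.max_displacement() > 0 else rigid_map
                )

    sx, sy = blockface_volume.spacing[:2]
    nx, ny, _ = blockface_volume.shape_xyz
    scalar = _signal_2d if strategy == "pli" else (lambda im: Image2D(im.gray(), im.spacing))
    out = np.stack(
        [
            resample_image2d(
                scalar(stack.slices[i]),
                records[i]["resample"], "linear", spacing=(sx, sy), shape_xy=(nx, ny),
            ).pixels
            for i in range(n)
        ],
        axis=0,
    )
    return ImageVolume(out, (sx, sy, stack.sz)), records
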