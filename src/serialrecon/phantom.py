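"""Synthetic multi-modal phantom with full ground truth.

The phantom emulates the study situation end-to-end: a "brain" (ellipsoid)
with an internal hippocampus-like structure and a protruding bulb-like
appendage at one pole; blockface photographs carrying chuck markers, per-slice
translation jitter and sparse perspective offsets; per-slice rigidly (plus
optionally smoothly) deformed section stacks in three modalities (full-contrast
histology, autoradiography with zero-signal "empty regions", orientation-coded
PLI); and a template/label pair related to the truth by a known affine plus a
smooth cubic B-spline warp with an intensity remap standing in for the MRI
modality gap.

Every random choice flows through an explicit seed, and every applied
distortion is recorded so that reconstruction error is measurable exactly.
Stored per-slice transforms map *section* coordinates to *truth* coordinates
(the resampling map used to render, which is also the forward map a perfect
aligner should recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import gaussian_filter

from .geometry import BinaryMask, Image2D, ImageVolume, LabelVolume, SectionStack
from .resample import resample_image2d, resample_volume
from .transforms import (
    Affine3D,
    BSplineField,
    ComposedTransform,
    FixedPointInverse,
    Rigid2D,
)

__all__ = [
    "PhantomScene",
    "StructureParams",
    "SectionDeformParams",
    "MarkerLayout",
    "PerspectiveModel",
    "TemplateParams",
    "make_scene",
    "render_blockface",
    "render_sections",
    "make_template",
    "default_deform_params",
]

LABEL_TISSUE = 1
LABEL_INNER = 2
LABEL_BULB = 3

DEFAULT_SHAPE = (96, 96, 64)
DEFAULT_SPACING = (0.05, 0.05, 0.06)


@dataclass
class StructureParams:
    """Structure geometry as fractions of the volume shape (axis order x, y, z)."""

    brain_center: Tuple[float, float, float] = (0.5, 0.5, 0.47)
    brain_axes: Tuple[float, float, float] = (0.27, 0.24, 0.36)
    inner_center: Tuple[float, float, float] = (0.5, 0.42, 0.44)
    inner_axes: Tuple[float, float, float] = (0.13, 0.09, 0.16)
    bulb_radius: float = 0.095  # fraction of nz
    base_intensity: Dict[int, float] = field(
        default_factory=lambda: {LABEL_TISSUE: 0.45, LABEL_INNER: 0.8, LABEL_BULB: 0.6}
    )
    # Two texture scales, both smooth along the sectioning axis (receptor/cell
    # densities vary slowly from section to section) but detailed in-plane:
    # coarse regional variation plus fine structural detail (the texture that
    # keypoint detectors latch onto in real stained sections).
    texture_amp: float = 0.09
    texture_sigma: Tuple[float, float, float] = (6.0, 2.0, 2.0)
    texture_fine_amp: float = 0.05
    texture_fine_sigma: Tuple[float, float, float] = (6.0, 1.0, 1.0)
    noise_sigma: float = 0.0  # truth volume itself is noise-free by default


@dataclass
class MarkerLayout:
    """Circular fiducials on the microtome chuck, in pixels of the image frame."""

    centers_px: Tuple = ((7.0, 7.0), (89.0, 7.0), (7.0, 89.0), (89.0, 89.0))
    radius_px: float = 2.5
    value: float = 2.0

    @classmethod
    def for_shape(cls, nx: int, ny: int, inset_px: float = 7.0, radius_px: float = 2.5) -> "MarkerLayout":
        return cls(
            centers_px=(
                (inset_px, inset_px),
                (nx - 1 - inset_px, inset_px),
                (inset_px, ny - 1 - inset_px),
                (nx - 1 - inset_px, ny - 1 - inset_px),
            ),
            radius_px=radius_px,
        )


@dataclass
class PerspectiveModel:
    """Sparse tissue-vs-marker offsets emulating the camera perspective error."""

    amplitude_px: float = 2.0
    fraction: float = 0.3  # fraction of slices carrying a nonzero offset


@dataclass
class SectionDeformParams:
    """Per-slice deformation drawn independently for every section."""

    theta_max_deg: float = 10.0
    t_max_frac: float = 0.10  # of the field of view
    warp_amp_px: float = 0.0
    warp_spacing_px: float = 16.0
    noise_sigma: float = 0.02  # of the modality's dynamic range
    slice_step: int = 1  # sections per blockface slice ratio
    empty_label: int = LABEL_INNER
    empty_slices: str = "even"  # 'even' | 'all' | 'none'
    autorad_gamma: float = 2.0
    landmark_spacing: int = 10
    landmark_noise_px: float = 0.3
    min_tissue_px: int = 50


def default_deform_params(modality: str) -> SectionDeformParams:
    if modality == "histology":
        return SectionDeformParams(slice_step=3, empty_slices="none")
    if modality == "autoradiograph":
        return SectionDeformParams(slice_step=3, empty_slices="even")
    if modality == "pli":
        return SectionDeformParams(slice_step=1, empty_slices="none", warp_amp_px=1.5)
    raise ValueError(f"unknown modality {modality!r}")


@dataclass
class TemplateParams:
    """Known template-to-truth map: affine (fixed defaults inside moderate
    ranges: scales 0.9–1.1, rotations <= 10 degrees) plus a smooth warp."""

    scales: Tuple[float, float, float] = (0.93, 1.07, 0.96)
    rotations_deg: Tuple[float, float, float] = (5.0, -4.0, 7.0)
    translation_frac: Tuple[float, float, float] = (0.04, -0.03, 0.035)  # of extent
    warp_spacing_vox: float = 16.0
    warp_sigma_vox: float = 2.0
    appendage_shift_vox: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.01


@dataclass
class PhantomScene:
    """Ground-truth container produced by :func:`make_scene` and enriched by
    the render functions (stored truths for every rendered artefact)."""

    truth_volume: ImageVolume
    truth_labels: LabelVolume
    params: StructureParams
    seed: int
    expected_fractions: Dict[int, float] = field(default_factory=dict)
    section_truth: Dict[str, List[dict]] = field(default_factory=dict)
    blockface_truth: Optional[dict] = None
    template_warp: Optional[dict] = None

    @property
    def spacing(self) -> tuple:
        return self.truth_volume.spacing

    def brain_mask(self) -> BinaryMask:
        return self.truth_labels.mask(None)


def _ellipsoid(shape_xyz, center_vox, axes_vox) -> np.ndarray:
    nx, ny, nz = shape_xyz
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    cx, cy, cz = center_vox
    ax, ay, az = axes_vox
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def make_scene(
    shape: Tuple[int, int, int] = DEFAULT_SHAPE,
    structure_params: Optional[StructureParams] = None,
    seed: int = 0,
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
) -> PhantomScene:
    """Deterministic synthetic scene; ``shape`` is (nx, ny, nz), min 48 per axis."""
    nx, ny, nz = shape
    if min(shape) < 48:
        raise ValueError(f"phantom shape must be at least 48 per axis, got {shape}")
    sp = structure_params or StructureParams()
    rng = np.random.default_rng(seed)

    dims = np.array([nx, ny, nz], dtype=float)
    brain_c = np.asarray(sp.brain_center) * dims
    brain_a = np.asarray(sp.brain_axes) * dims
    inner_c = np.asarray(sp.inner_center) * dims
    inner_a = np.asarray(sp.inner_axes) * dims
    bulb_r = sp.bulb_radius * nz
    bulb_c = np.array([brain_c[0], brain_c[1], brain_c[2] + brain_a[2] + 0.35 * bulb_r])

    brain = _ellipsoid(shape, brain_c, brain_a)
    bulb = _ellipsoid(shape, bulb_c, (bulb_r, bulb_r, bulb_r))
    inner = _ellipsoid(shape, inner_c, inner_a)

    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    labels[brain] = LABEL_TISSUE
    labels[bulb & ~brain] = LABEL_BULB
    labels[inner & (labels > 0)] = LABEL_INNER

    fg = labels > 0
    if (
        fg[0].any() or fg[-1].any()
        or fg[:, 0].any() or fg[:, -1].any()
        or fg[:, :, 0].any() or fg[:, :, -1].any()
    ):
        raise ValueError(f"shape {shape} is too small to contain the configured structures")

    intensity = np.zeros_like(labels, dtype=float)
    for lab, base in sp.base_intensity.items():
        intensity[labels == lab] = base
    texture = gaussian_filter(rng.standard_normal(labels.shape), sp.texture_sigma)
    texture *= sp.texture_amp / max(texture.std(), 1e-12)
    if sp.texture_fine_amp > 0:
        fine = gaussian_filter(rng.standard_normal(labels.shape), sp.texture_fine_sigma)
        texture += fine * (sp.texture_fine_amp / max(fine.std(), 1e-12))
    intensity[fg] = np.clip(intensity[fg] + texture[fg], 0.15, 1.0)
    if sp.noise_sigma > 0:
        intensity[fg] += rng.normal(0, sp.noise_sigma, int(fg.sum()))
        intensity = np.clip(intensity, 0.0, None)

    total = float(labels.size)
    expected = {
        LABEL_TISSUE: 4 / 3 * np.pi * np.prod(brain_a) / total,
        LABEL_INNER: 4 / 3 * np.pi * np.prod(np.minimum(inner_a, brain_a)) / total,
        LABEL_BULB: 0.5 * 4 / 3 * np.pi * bulb_r**3 / total,
    }
    return PhantomScene(
        truth_volume=ImageVolume(intensity, spacing),
        truth_labels=LabelVolume(labels, spacing),
        params=sp,
        seed=seed,
        expected_fractions=expected,
    )


# ---------------------------------------------------------------------------
# Blockface rendering
# ---------------------------------------------------------------------------

def _draw_disks(canvas: np.ndarray, centers_px, radius_px: float, value: float) -> None:
    ny, nx = canvas.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cx, cy in centers_px:
        d = np.hypot(xx - cx, yy - cy)
        canvas += value * np.clip(radius_px + 0.5 - d, 0.0, 1.0)


def render_blockface(
    scene: PhantomScene,
    marker_layout: Optional[MarkerLayout] = None,
    perspective_model: Optional[PerspectiveModel] = None,
    seed: int = 0,
    jitter_px: float = 3.0,
    noise_sigma: float = 0.02,
) -> SectionStack:
    """Blockface stack: truth slices + chuck markers + translation jitter +
    sparse perspective offsets of tissue relative to the markers.

    Slice 0 is the reference camera frame (zero jitter and offset), so the
    reconstructed blockface space coincides with the truth frame.  True jitter
    and offsets are recorded in ``scene.blockface_truth``.
    """
    nx, ny, nz = scene.truth_volume.shape_xyz
    sx, sy = scene.spacing[:2]
    layout = marker_layout or MarkerLayout.for_shape(nx, ny)
    persp = perspective_model or PerspectiveModel()
    if len(layout.centers_px) < 2:
        raise ValueError("at least two markers are required")
    rng = np.random.default_rng(seed)

    fg = scene.truth_labels.labels > 0
    xs_any = np.where(fg.any(axis=(0, 1)))[0]
    ys_any = np.where(fg.any(axis=(0, 2)))[0]
    bbox = (xs_any.min(), xs_any.max(), ys_any.min(), ys_any.max())
    margin = layout.radius_px + jitter_px + persp.amplitude_px + 1.0
    for cx, cy in layout.centers_px:
        if (bbox[0] - margin <= cx <= bbox[1] + margin) and (bbox[2] - margin <= cy <= bbox[3] + margin):
            raise ValueError(f"marker at ({cx}, {cy}) px overlaps the tissue bounding box")

    jitter = rng.uniform(-jitter_px, jitter_px, (nz, 2))
    offsets = np.zeros((nz, 2))
    hit = rng.random(nz) < persp.fraction
    offsets[hit] = rng.uniform(-persp.amplitude_px, persp.amplitude_px, (int(hit.sum()), 2))
    jitter[0] = 0.0
    offsets[0] = 0.0

    slices, truths = [], []
    dyn = layout.value  # markers dominate the dynamic range
    for z in range(nz):
        shift_mm = (jitter[z] + offsets[z]) * np.array([sx, sy])
        tr = Rigid2D(theta=0.0, t=tuple(-shift_mm))  # rendered -> truth map
        tissue = resample_image2d(scene.truth_volume.slice_image(z), tr, "linear")
        canvas = tissue.pixels.copy()
        _draw_disks(canvas, np.asarray(layout.centers_px) + jitter[z], layout.radius_px, layout.value)
        if noise_sigma > 0:
            canvas = canvas + rng.normal(0, noise_sigma * dyn, canvas.shape)
        slices.append(Image2D(canvas, (sx, sy)))
        truths.append(tr)

    scene.blockface_truth = {
        "jitter_px": jitter,
        "perspective_px": offsets,
        "transforms": truths,
        "marker_layout": layout,
    }
    return SectionStack(slices=slices, modality="blockface", sz=scene.spacing[2])


# ---------------------------------------------------------------------------
# Section rendering
# ---------------------------------------------------------------------------

def _random_warp_2d(rng, field_mm, amp_px, spacing_px, pixel_mm) -> BSplineField:
    spacing_mm = (spacing_px * pixel_mm[0], spacing_px * pixel_mm[1])
    fld = BSplineField.zero(field_mm, spacing_mm)
    coeff = rng.normal(0.0, 1.0, fld.coefficients.shape)
    scale = amp_px * np.asarray(pixel_mm) / max(np.abs(coeff).max(), 1e-12)
    fld.coefficients = coeff * scale
    return fld


def _pli_colorize(gray: np.ndarray, scene: PhantomScene) -> np.ndarray:
    """Orientation-coded 3-channel image: hue follows a synthetic swirl fiber
    direction field, value follows tissue signal."""
    ny, nx = gray.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    phi = np.arctan2(yy - cy, xx - cx)  # in-plane fiber direction (mod pi)
    hue = np.mod(phi, np.pi) / np.pi
    v = np.clip(gray / max(gray.max(), 1e-9), 0, 1)
    hsv = np.stack([hue, np.full_like(hue, 0.9), v], axis=-1)
    return hsv_to_rgb(hsv)


def _slice_tissue_area(scene: PhantomScene, z: int) -> int:
    return int((scene.truth_labels.labels[z] > 0).sum())


def _anchor_points(mask2d: np.ndarray, spacing) -> np.ndarray:
    """Four well-spread landmark points (mm): bbox corners pulled toward the COG."""
    ys, xs = np.nonzero(mask2d)
    cog = np.array([xs.mean(), ys.mean()])
    corners = np.array(
        [[xs.min(), ys.min()], [xs.max(), ys.min()], [xs.min(), ys.max()], [xs.max(), ys.max()]], dtype=float
    )
    pts = cog + 0.6 * (corners - cog)
    return pts * np.asarray(spacing)


def render_sections(
    scene: PhantomScene,
    modality: str,
    deform_params: Optional[SectionDeformParams] = None,
    seed: int = 0,
) -> SectionStack:
    """Per-slice rigidly (plus optionally smoothly warped) deformed sections.

    Sections are rendered for every ``slice_step``-th truth slice that carries
    at least ``min_tissue_px`` tissue pixels; ``meta[i]['blockface_slice']``
    records the corresponding blockface slice.  Stored truth transforms (in
    ``scene.section_truth[modality]``) map section coordinates to truth
    coordinates.
    """
    dp = deform_params if deform_params is not None else default_deform_params(modality)
    if modality not in ("histology", "autoradiograph", "pli"):
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    nx, ny, nz = scene.truth_volume.shape_xyz
    sx, sy = scene.spacing[:2]
    field_mm = np.array([nx * sx, ny * sy])

    # Reject deformations that would push tissue outside the frame.
    fg_any = scene.truth_labels.labels > 0
    xs_any = np.where(fg_any.any(axis=(0, 1)))[0]
    ys_any = np.where(fg_any.any(axis=(0, 2)))[0]
    margin_px = min(xs_any.min(), nx - 1 - xs_any.max(), ys_any.min(), ny - 1 - ys_any.max())
    reach_px = max(xs_any.max() - xs_any.min(), ys_any.max() - ys_any.min()) / 2
    worst_px = dp.t_max_frac * max(nx, ny) + reach_px * np.deg2rad(dp.theta_max_deg) + dp.warp_amp_px
    if worst_px > margin_px:
        raise ValueError(
            f"deformation budget ({worst_px:.1f} px) exceeds the tissue-to-frame margin ({margin_px} px)"
        )

    zs = [z for z in range(0, nz, dp.slice_step) if _slice_tissue_area(scene, z) >= dp.min_tissue_px]
    center_mm = ((nx - 1) * sx / 2, (ny - 1) * sy / 2)

    slices, meta, truths = [], [], []
    for i, z in enumerate(zs):
        theta = rng.uniform(-np.deg2rad(dp.theta_max_deg), np.deg2rad(dp.theta_max_deg))
        t_mm = rng.uniform(-dp.t_max_frac, dp.t_max_frac, 2) * field_mm
        rigid = Rigid2D(theta=theta, t=tuple(t_mm), center=center_mm)
        warp = None
        if dp.warp_amp_px > 0:
            warp = _random_warp_2d(rng, field_mm, dp.warp_amp_px, dp.warp_spacing_px, (sx, sy))
        tr = ComposedTransform([rigid, warp]) if warp is not None else rigid

        base = scene.truth_volume.voxels[z].astype(float)
        lab = scene.truth_labels.labels[z]
        if modality == "autoradiograph":
            base = 2.0 * np.clip(base, 0, None) ** dp.autorad_gamma  # broader dynamic range
        img = Image2D(base, (sx, sy))
        rendered = resample_image2d(img, tr, "linear")
        lab_r = resample_image2d(Image2D(lab.astype(float), (sx, sy)), tr, "nearest").pixels.astype(int)

        if modality == "autoradiograph" and dp.empty_slices != "none":
            if dp.empty_slices == "all" or (dp.empty_slices == "even" and i % 2 == 0):
                px = rendered.pixels.copy()
                px[lab_r == dp.empty_label] = 0.0
                rendered = Image2D(px, (sx, sy))

        if modality == "pli":
            pix = _pli_colorize(rendered.pixels, scene)
        else:
            pix = rendered.pixels
        dyn = max(float(np.abs(pix).max()), 1e-9)
        if dp.noise_sigma > 0:
            pix = pix + rng.normal(0, dp.noise_sigma * dyn, pix.shape)

        m = {"index": i, "blockface_slice": z}
        is_anchor = (i % dp.landmark_spacing == 0) or (i == len(zs) - 1)
        if is_anchor and (lab > 0).sum() >= dp.min_tissue_px:
            b_pts = _anchor_points(lab > 0, (sx, sy))
            # rigid∘warp inverts as warp⁻¹∘rigid⁻¹; the warp inverse is a
            # fixed-point approximation (valid: small smooth displacements).
            inv = tr.inverse() if warp is None else ComposedTransform(
                [FixedPointInverse(warp), rigid.inverse()]
            )
            s_pts = inv.apply(b_pts)
            s_pts = s_pts + rng.normal(0, dp.landmark_noise_px, s_pts.shape) * np.array([sx, sy])
            m["landmarks"] = np.column_stack([s_pts, b_pts])
        meta.append(m)
        slices.append(Image2D(pix, (sx, sy)))
        truths.append({"rigid": rigid, "warp": warp, "transform": tr, "blockface_slice": z})

    scene.section_truth[modality] = truths
    return SectionStack(slices=slices, modality=modality, sz=scene.spacing[2] * dp.slice_step, meta=meta)


# ---------------------------------------------------------------------------
# Template / label pair
# ---------------------------------------------------------------------------

def make_template(
    scene: PhantomScene,
    template_params: Optional[TemplateParams] = None,
    seed: int = 0,
) -> Tuple[ImageVolume, LabelVolume]:
    """Synthetic template differing from the truth by a known affine plus
    smooth warp, with a monotone intensity remap emulating the MRI contrast.

    The stored map (``scene.template_warp``) sends template coordinates to
    truth coordinates: ``p -> A(p + d(p))``; the template is rendered through
    exactly this map, so the stored ground truth is closed by construction.
    """
    tp = template_params or TemplateParams()
    if tp.warp_spacing_vox < 8:
        raise ValueError("warp control-point spacing must be at least 8 voxels (smooth warp)")
    rng = np.random.default_rng(seed)
    nx, ny, nz = scene.truth_volume.shape_xyz
    spacing = np.asarray(scene.spacing)
    extent = np.array([nx, ny, nz]) * spacing
    center = (np.array([nx, ny, nz]) - 1) * spacing / 2

    affine = Affine3D.from_params(
        scales=tp.scales,
        rotations_deg=tp.rotations_deg,
        translation=np.asarray(tp.translation_frac) * extent,
        center=center,
    )

    warp = BSplineField.zero(extent, tp.warp_spacing_vox * spacing)
    if tp.warp_sigma_vox > 0:
        warp.coefficients = rng.normal(0.0, tp.warp_sigma_vox, warp.coefficients.shape) * spacing
    shift_vox = np.asarray(tp.appendage_shift_vox, dtype=float)
    if np.any(shift_vox != 0):
        # Displace the bulb-like appendage in the template: bump the control
        # points near the appendage's template-domain location.
        bulb_idx = np.argwhere(scene.truth_labels.labels == LABEL_BULB)[:, ::-1]  # (x,y,z)
        bulb_center_mm = bulb_idx.mean(axis=0) * spacing
        loc = affine.inverse().apply(bulb_center_mm)[0]
        gx, gy, gz = warp.grid_shape
        nodes = np.stack(np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij"), axis=-1)
        node_mm = warp.grid_origin + nodes * warp.grid_spacing
        bulb_extent = max((bulb_idx.max(axis=0) - bulb_idx.min(axis=0)) * spacing / 2)
        near = np.linalg.norm(node_mm - loc, axis=-1) < 2.0 * bulb_extent + warp.grid_spacing.max()
        warp.coefficients[near] += shift_vox * spacing

    tmap = ComposedTransform([affine, warp])
    moved = resample_volume(scene.truth_volume, tmap, "linear", reference=scene.truth_volume)
    labels = resample_volume(scene.truth_labels, tmap, "nearest", reference=scene.truth_labels)

    remapped = np.sqrt(np.clip(moved.voxels, 0.0, None))  # monotone contrast change
    if tp.noise_sigma > 0:
        remapped = remapped + rng.normal(0, tp.noise_sigma, remapped.shape)
        remapped = np.clip(remapped, 0.0, None)

    scene.template_warp = {"affine": affine, "warp": warp, "transform": tmap, "params": tp}
    return ImageVolume(remapped, scene.spacing), labels
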