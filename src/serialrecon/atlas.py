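"""Three-step 3D registration of a labeled template onto a reconstructed
blockface volume, and nearest-neighbour label propagation.

The strategy increases the degrees of freedom stage by stage — rigid, then
affine, then cubic B-spline free-form deformation — each stage initialized
with the previous stage's result and each run over a coarse-to-fine Gaussian
pyramid.  The template is masked to its labeled voxels before registration,
and structures whose position is known to be unreliable (the bulb-like
appendage, standing in for the olfactory bulb) can be excluded from the
metric through a fixed-image mask.

The optimization engine is SimpleITK; the similarity objective for the
mutual-information settings is Mattes mutual information, while a 32-bin
normalized-mutual-information value is computed in-repo before and after
every stage for provenance and for the metric-degradation guard.  All
randomness (metric sampling) is seeded; runs are single-threaded and
deterministic for a fixed config.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk

from .evaluation import evaluate_stages
from .geometry import BinaryMask, ImageVolume, LabelVolume
from .resample import resample_volume
from .similarity import normalized_mutual_information, ssd as ssd_metric
from .transforms import Affine3D, BSplineField, ComposedTransform, IdentityTransform

__all__ = [
    "RegistrationConfig",
    "TransformChain",
    "mask_template",
    "exclusion_mask",
    "register",
    "propagate_labels",
    "grid_sweep",
]

_METRICS = {"NMI", "MI", "SSD"}


@dataclass
class RegistrationConfig:
    """Settings for the three-step registration.

    ``metric`` may be a single name (NMI, MI or SSD) for all stages or a dict
    per stage; mutual-information variants use ``histogram_bins`` bins.  The
    B-spline grid is parameterized by control-point spacing in fixed-image
    voxels (the grid-flexibility axis of the sweep).
    """

    pyramid_levels: int = 6
    downsample_factor: int = 2
    metric: object = "NMI"
    iterations_per_level: int = 80
    bspline_iterations_per_level: int = 30
    sampling_fraction: float = 0.25
    bspline_sampling_fraction: float = 0.10
    histogram_bins: int = 32
    bspline_grid_spacing_vox: float = 20.0
    run_rigid: bool = True
    run_affine: bool = True
    run_bspline: bool = True
    exclusion_labels: Tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.bspline_grid_spacing_vox <= 0:
            raise ValueError("B-spline grid spacing must be positive")

    def metric_for(self, stage: str) -> str:
        m = self.metric.get(stage, "NMI") if isinstance(self.metric, dict) else self.metric
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r} for stage {stage!r}")
        return m


@dataclass
class TransformChain:
    """Cumulative fixed->moving resampling maps after each completed stage,
    plus per-stage provenance (metric values before/after, flags)."""

    stages: "OrderedDict[str, object]"
    provenance: Dict[str, dict] = dc_field(default_factory=dict)

    @property
    def final(self):
        return next(reversed(self.stages.values())) if self.stages else IdentityTransform(3)

    def at_stage(self, name: str):
        return self.stages[name]

    def stage_names(self) -> List[str]:
        return list(self.stages)


def mask_template(template: ImageVolume, labels: LabelVolume) -> ImageVolume:
    """Zero every template voxel whose label is 0 (separates brain from the
    rest of the head); labeled voxels pass through untouched."""
    if template.shape_xyz != labels.shape_xyz:
        raise ValueError("template and label volume geometries differ")
    out = template.voxels.copy()
    out[labels.labels == 0] = 0.0
    return ImageVolume(out, template.spacing)


def exclusion_mask(
    labels: LabelVolume,
    exclusion_labels: Sequence[int],
    slice_fraction_threshold: float = 0.5,
) -> BinaryMask:
    """Fixed-image metric mask: all foreground minus the excluded structures
    and minus the z-slices they dominate (excluded fraction of the slice's
    foreground above ``slice_fraction_threshold``)."""
    lab = labels.labels
    present = set(np.unique(lab).tolist())
    for ex in exclusion_labels:
        if ex not in present:
            warnings.warn(f"exclusion label {ex} not present in the label volume", stacklevel=2)
    bits = lab > 0
    excluded = np.isin(lab, list(exclusion_labels)) if len(exclusion_labels) else np.zeros_like(bits)
    bits = bits & ~excluded
    if len(exclusion_labels):
        fg_per_slice = (lab > 0).sum(axis=(1, 2))
        ex_per_slice = excluded.sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(fg_per_slice > 0, ex_per_slice / np.maximum(fg_per_slice, 1), 0.0)
        bits[frac > slice_fraction_threshold] = False
    if not bits.any():
        raise ValueError("exclusion removed every foreground voxel")
    return BinaryMask(bits, labels.spacing)


# ---------------------------------------------------------------------------
# SimpleITK plumbing
# ---------------------------------------------------------------------------

def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.astype(np.float64)))
    img.SetSpacing(tuple(vol.spacing))
    return img


def _affine_to_sitk(a: Affine3D) -> sitk.AffineTransform:
    tx = sitk.AffineTransform(3)
    tx.SetMatrix(tuple(a.M.ravel()))
    tx.SetTranslation(tuple(a.t))
    return tx


def _sitk_to_affine(tx) -> Affine3D:
    M = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    return Affine3D(M=M, t=tuple(c + t - M @ c))


def _bspline_to_field(tx: sitk.BSplineTransform) -> BSplineField:
    fp = np.asarray(tx.GetFixedParameters(), dtype=float)
    gsize = fp[0:3].astype(int)
    origin, spacing = fp[3:6], fp[6:9]
    coeff = np.asarray(tx.GetParameters(), dtype=float).reshape(3, gsize[2], gsize[1], gsize[0])
    coeff = np.transpose(coeff, (3, 2, 1, 0))  # -> (gx, gy, gz, 3)
    return BSplineField(grid_origin=origin, grid_spacing=spacing, coefficients=coeff)


def _pyramid(config: RegistrationConfig, shape_xyz) -> Tuple[List[int], List[float]]:
    f, L = config.downsample_factor, config.pyramid_levels
    max_shrink = max(1, min(shape_xyz) // 8)  # keep the coarsest level usable
    shrink = [min(f ** (L - 1 - l), max_shrink) for l in range(L)]
    sigmas = [s / 2.0 if s > 1 else 0.0 for s in shrink]
    return shrink, sigmas


def _set_metric(reg: sitk.ImageRegistrationMethod, name: str, config: RegistrationConfig) -> None:
    if name in ("NMI", "MI"):
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.histogram_bins)
    else:
        reg.SetMetricAsMeanSquares()


def _stage_registration(
    fixed: sitk.Image,
    moving: sitk.Image,
    stage: str,
    init_tx,
    moving_initial,
    config: RegistrationConfig,
    fixed_mask: Optional[sitk.Image],
) -> None:
    reg = sitk.ImageRegistrationMethod()
    _set_metric(reg, config.metric_for(stage), config)
    if fixed_mask is not None:
        reg.SetMetricFixedMask(fixed_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    shrink, sigmas = _pyramid(config, fixed.GetSize())
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    if stage == "bspline":
        # seeded random sampling (drawn once per level, so the LBFGSB line
        # searches see a deterministic objective)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(config.bspline_sampling_fraction, config.seed + 37)
        reg.SetOptimizerAsLBFGSB(numberOfIterations=config.bspline_iterations_per_level)
    else:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        stage_offset = {"rigid": 11, "affine": 23}.get(stage, 37)
        reg.SetMetricSamplingPercentage(config.sampling_fraction, config.seed + stage_offset)
        # capped-step gradient descent with automatic learning-rate estimation
        max_step = 0.5 * float(min(fixed.GetSpacing())) * max(fixed.GetSize())
        reg.SetOptimizerAsGradientDescent(
            learningRate=1.0,
            numberOfIterations=config.iterations_per_level,
            estimateLearningRate=reg.Once,
            maximumStepSizeInPhysicalUnits=0.02 * max_step,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
    if moving_initial is not None:
        reg.SetMovingInitialTransform(moving_initial)
    reg.SetInitialTransform(init_tx, inPlace=True)
    reg.Execute(fixed, moving)


def register(
    template_masked: ImageVolume,
    blockface_volume: ImageVolume,
    initial: Optional[Affine3D] = None,
    config: Optional[RegistrationConfig] = None,
    fixed_mask: Optional[BinaryMask] = None,
    moving_mask: Optional[BinaryMask] = None,
) -> TransformChain:
    """Rigid -> affine -> cubic-B-spline registration of the template (moving)
    onto the blockface volume (fixed).

    ``fixed_mask`` / ``moving_mask`` implement structure exclusion (see
    :func:`exclusion_mask`): voxels outside a given mask are blanked to
    background before optimization, so the excluded structures contribute no
    metric information while the output geometry stays untouched; the logged
    similarity values are restricted to the fixed mask.

    Returns cumulative fixed->moving resampling maps per stage.  A stage that
    worsens its similarity metric (measured in-repo at full resolution) is
    discarded: the previous result is kept and the stage flagged in the
    provenance.  Deterministic for a fixed config (single-threaded engine,
    seeded metric sampling).
    """
    config = config or RegistrationConfig()
    fixed_arr = blockface_volume.voxels
    mask_bits = None
    if fixed_mask is not None:
        mask_bits = fixed_mask.bits
        fixed_arr = np.where(fixed_mask.bits, fixed_arr, 0.0)
    moving_arr = template_masked.voxels
    if moving_mask is not None:
        moving_arr = np.where(moving_mask.bits, moving_arr, 0.0)
    blockface_opt = ImageVolume(fixed_arr, blockface_volume.spacing)
    template_opt = ImageVolume(moving_arr, template_masked.spacing)
    fixed = _to_sitk(blockface_opt)
    moving = _to_sitk(template_opt)
    mask_img = None

    def _score(transform, metric_name: str) -> float:
        moved = resample_volume(template_opt, transform, "linear", reference=blockface_opt)
        if metric_name in ("NMI", "MI"):
            return normalized_mutual_information(
                blockface_opt.voxels, moved.voxels, bins=config.histogram_bins, mask=mask_bits
            )
        return -ssd_metric(blockface_opt.voxels, moved.voxels, mask=mask_bits)

    n_threads = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        current: object = initial if initial is not None else IdentityTransform(3)
        current_affine: Affine3D = initial if initial is not None else Affine3D()
        stages: "OrderedDict[str, object]" = OrderedDict()
        provenance: Dict[str, dict] = {}

        center = (np.asarray(blockface_volume.shape_xyz) - 1) * np.asarray(blockface_volume.spacing) / 2

        if fixed_mask is not None and initial is None and config.run_rigid:
            # A metric mask sharpens the optimum but narrows the capture
            # range; a quick unmasked rigid pre-alignment plays the role of
            # the manual anchoring step and brings the masked stages into
            # that range.
            pre = sitk.Euler3DTransform()
            pre.SetCenter(tuple(center))
            try:
                _stage_registration(fixed, moving, "rigid", pre, None, config, None)
                pre_affine = _sitk_to_affine(pre)
                if _score(pre_affine, config.metric_for("rigid")) > _score(current, config.metric_for("rigid")):
                    current_affine = pre_affine
                    current = current_affine
                    initial = current_affine  # rigid stage starts from here
                    provenance["prealign"] = {"method": "unmasked_rigid", "flag": ""}
            except RuntimeError:
                provenance["prealign"] = {"method": "unmasked_rigid", "flag": "failed_discarded"}

        if config.run_rigid:
            name = config.metric_for("rigid")
            before = _score(current, name)
            euler = sitk.Euler3DTransform()
            euler.SetCenter(tuple(center))
            init_sitk = _affine_to_sitk(current_affine) if initial is not None else None
            try:
                _stage_registration(fixed, moving, "rigid", euler, init_sitk, config, mask_img)
                rigid_affine = (
                    current_affine.compose(_sitk_to_affine(euler)) if initial is not None
                    else _sitk_to_affine(euler)
                )
                after = _score(rigid_affine, name)
            except RuntimeError:
                rigid_affine, after = current_affine, -np.inf
            prov = {"metric": name, "before": before, "after": after, "flag": ""}
            if after < before:
                warnings.warn("rigid stage degraded the metric; keeping initialization", stacklevel=2)
                prov["flag"] = "degraded_discarded"
            else:
                current_affine = rigid_affine
            current = current_affine
            stages["rigid"] = current
            provenance["rigid"] = prov

        if config.run_affine:
            name = config.metric_for("affine")
            before = _score(current_affine, name)
            aff = sitk.AffineTransform(3)
            aff.SetMatrix(tuple(current_affine.M.ravel()))
            aff.SetTranslation(tuple(current_affine.t))
            try:
                _stage_registration(fixed, moving, "affine", aff, None, config, mask_img)
                cand = _sitk_to_affine(aff)
                after = _score(cand, name)
            except RuntimeError:
                cand, after = current_affine, -np.inf
            prov = {"metric": name, "before": before, "after": after, "flag": ""}
            if after < before:
                warnings.warn("affine stage degraded the metric; keeping previous result", stacklevel=2)
                prov["flag"] = "degraded_discarded"
            else:
                current_affine = cand
            current = current_affine
            stages["affine"] = current
            provenance["affine"] = prov

        if config.run_bspline:
            name = config.metric_for("bspline")
            before = _score(current_affine, name)
            extent_vox = np.asarray(blockface_volume.shape_xyz, dtype=float)
            mesh = [int(max(1, round(e / config.bspline_grid_spacing_vox))) for e in extent_vox]
            bsp = sitk.BSplineTransformInitializer(fixed, mesh, 3)
            try:
                _stage_registration(
                    fixed, moving, "bspline", bsp, _affine_to_sitk(current_affine), config, mask_img
                )
                fld = _bspline_to_field(bsp)
                cand_tr = ComposedTransform([current_affine, fld])
                after = _score(cand_tr, name)
            except RuntimeError:
                cand_tr, after = current, -np.inf
            prov = {"metric": name, "before": before, "after": after, "flag": "",
                    "grid_spacing_vox": config.bspline_grid_spacing_vox, "mesh": mesh}
            if after < before:
                warnings.warn("B-spline stage degraded the metric; keeping affine result", stacklevel=2)
                prov["flag"] = "degraded_discarded"
                stages["bspline"] = current
            else:
                current = cand_tr
                stages["bspline"] = current
            provenance["bspline"] = prov

        return TransformChain(stages=stages, provenance=provenance)
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(n_threads)


def propagate_labels(labels: LabelVolume, transform, reference) -> LabelVolume:
    """Carry the template's labels into the reference (blockface) geometry
    with nearest-neighbour interpolation (no label values are invented)."""
    tr = transform.final if isinstance(transform, TransformChain) else transform
    return resample_volume(labels, tr, "nearest", reference=reference)


def grid_sweep(
    template_masked: ImageVolume,
    template_labels: LabelVolume,
    blockface_volume: ImageVolume,
    truth_labels: LabelVolume,
    config: RegistrationConfig,
    spacings: Sequence[float],
    structures: Optional[dict] = None,
    fixed_mask: Optional[BinaryMask] = None,
):
    """Run the B-spline stage at several control-point spacings (the
    grid-flexibility axis) on top of one shared rigid+affine result and
    evaluate DC/HD/ASD per structure; returns ``[(spacing, report), ...]``."""
    if len(spacings) < 1:
        raise ValueError("at least one grid spacing is required")
    structures = structures or {"whole_brain": None, "inner": 2}
    base_cfg = replace(config, run_bspline=False)
    base_chain = register(template_masked, blockface_volume, None, base_cfg, fixed_mask)
    base_affine = base_chain.final

    results = []
    for sp in spacings:
        cfg = replace(config, run_rigid=False, run_affine=False, run_bspline=True,
                      bspline_grid_spacing_vox=float(sp))
        chain = register(template_masked, blockface_volume, base_affine, cfg, fixed_mask)
        prop = propagate_labels(template_labels, chain, blockface_volume)
        report = evaluate_stages(truth_labels, {"bspline": prop}, structures)
        results.append((float(sp), report))
    return results
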