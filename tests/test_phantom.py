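"""Synthetic phantom: determinism, structure geometry, rendering ground truth."""

import numpy as np
import pytest

import serialrecon as sr
from serialrecon.phantom import (
    LABEL_BULB,
    LABEL_INNER,
    LABEL_TISSUE,
    SectionDeformParams,
    StructureParams,
    TemplateParams,
)
from serialrecon.resample import resample_mask


class TestMakeScene:
    def test_same_seed_bitwise_identical(self):
        a = sr.make_scene((64, 64, 48), seed=5)
        b = sr.make_scene((64, 64, 48), seed=5)
        assert np.array_equal(a.truth_volume.voxels, b.truth_volume.voxels)
        assert np.array_equal(a.truth_labels.labels, b.truth_labels.labels)

    def test_volume_fractions_near_analytic_expectation(self, scene64):
        lab = scene64.truth_labels.labels
        for label in (LABEL_TISSUE, LABEL_INNER):
            measured = (lab == label).mean()
            expected = scene64.expected_fractions[label]
            assert abs(measured - expected) <= 0.2 * expected

    def test_internal_structure_nested_in_brain(self, scene64):
        lab = scene64.truth_labels.labels
        inner = lab == LABEL_INNER
        assert inner.sum() > 0
        assert not np.any(inner & (lab == 0))

    def test_whole_brain_connected(self, scene64):
        from scipy import ndimage as ndi

        _, n = ndi.label(scene64.truth_labels.labels > 0)
        assert n == 1

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            sr.make_scene((32, 32, 32))

    def test_structures_exceeding_volume_rejected(self):
        with pytest.raises(ValueError):
            sr.make_scene((48, 48, 48), StructureParams(brain_axes=(0.6, 0.6, 0.6)))


class TestRenderBlockface:
    def test_zero_jitter_zero_perspective_equals_truth_plus_markers(self, scene64):
        from serialrecon.phantom import PerspectiveModel

        stack = sr.render_blockface(
            scene64, perspective_model=PerspectiveModel(amplitude_px=0, fraction=0),
            jitter_px=0.0, noise_sigma=0.0, seed=0,
        )
        z = 24
        rendered = stack.slices[z].pixels
        truth = scene64.truth_volume.voxels[z]
        tissue = scene64.truth_labels.labels[z] > 0
        assert np.allclose(rendered[tissue], truth[tissue], atol=1e-9)
        assert rendered.max() > truth.max()  # markers present

    def test_recorded_jitter_matches_rendered_marker_positions(self, scene64):
        from serialrecon.blockface import detect_markers

        stack = sr.render_blockface(scene64, seed=3, noise_sigma=0.0)
        layout = scene64.blockface_truth["marker_layout"]
        jitter = scene64.blockface_truth["jitter_px"]
        sx = scene64.spacing[0]
        for z in (0, 10, 30):
            ms = detect_markers(stack.slices[z], 4)
            expected = (np.asarray(layout.centers_px) + jitter[z]) * sx
            expected = expected[np.lexsort((expected[:, 0], expected[:, 1]))]
            assert np.abs(ms.centers_mm - expected).max() / sx < 0.5

    def test_marker_overlapping_tissue_rejected(self, scene64):
        from serialrecon.phantom import MarkerLayout

        bad = MarkerLayout(centers_px=((32.0, 32.0),) * 2, radius_px=2.5)
        with pytest.raises(ValueError):
            sr.render_blockface(scene64, marker_layout=bad)


class TestRenderSections:
    def test_zero_deformation_equals_truth_slices(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        dp = SectionDeformParams(theta_max_deg=0, t_max_frac=0, warp_amp_px=0,
                                 noise_sigma=0, slice_step=3, empty_slices="none")
        stack = sr.render_sections(scene, "histology", deform_params=dp, seed=0)
        for im, t in zip(stack.slices, scene.section_truth["histology"]):
            z = t["blockface_slice"]
            assert np.allclose(im.pixels, scene.truth_volume.voxels[z], atol=1e-9)

    def test_autoradiograph_empty_region_is_exactly_zero(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        dp = SectionDeformParams(slice_step=3, empty_slices="all", noise_sigma=0)
        stack = sr.render_sections(scene, "autoradiograph", deform_params=dp, seed=4)
        sx, sy = scene.spacing[:2]
        for i, (im, t) in enumerate(zip(stack.slices, scene.section_truth["autoradiograph"])):
            z = t["blockface_slice"]
            lab = sr.Image2D(scene.truth_labels.labels[z].astype(float), (sx, sy))
            lab_r = sr.resample_image2d(lab, t["transform"], "nearest").pixels.astype(int)
            if (lab_r == LABEL_INNER).sum() > 0:
                assert im.pixels[lab_r == LABEL_INNER].mean() == 0.0

    def test_stored_inverse_restores_truth_mask(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        stack = sr.render_sections(scene, "histology", seed=6)
        sx, sy = scene.spacing[:2]
        for im, t in zip(stack.slices[::4], scene.section_truth["histology"][::4]):
            z = t["blockface_slice"]
            truth_mask = scene.truth_labels.labels[z] > 0
            if truth_mask.sum() < 300:
                continue
            sec_mask = resample_mask(sr.BinaryMask(truth_mask, (sx, sy)), t["transform"])
            restored = resample_mask(sec_mask, t["transform"].inverse(),
                                     spacing=(sx, sy), shape=(64, 64))
            d = sr.dice(restored, sr.BinaryMask(truth_mask, (sx, sy)))
            assert d >= 0.98

    def test_excessive_deformation_rejected(self, scene64):
        dp = SectionDeformParams(t_max_frac=0.4)
        with pytest.raises(ValueError):
            sr.render_sections(scene64, "histology", deform_params=dp)

    def test_pli_is_three_channel_orientation_coded(self, scene64):
        stack = sr.render_sections(scene64, "pli", seed=3)
        mid = stack.slices[len(stack) // 2]
        assert mid.pixels.ndim == 3 and mid.pixels.shape[2] == 3
        # hue varies across the tissue: channels are not all equal
        assert np.std(mid.pixels.max(axis=2) - mid.pixels.min(axis=2)) > 0.01


class TestMakeTemplate:
    def test_identity_parameters_preserve_labels(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        tp = TemplateParams(scales=(1, 1, 1), rotations_deg=(0, 0, 0),
                            translation_frac=(0, 0, 0), warp_sigma_vox=0.0, noise_sigma=0.0)
        _, labels = sr.make_template(scene, tp, seed=0)
        assert np.array_equal(labels.labels, scene.truth_labels.labels)

    def test_whole_brain_volume_within_15_percent(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        _, labels = sr.make_template(scene, seed=3)
        truth_count = (scene.truth_labels.labels > 0).sum()
        assert abs(int((labels.labels > 0).sum()) - truth_count) <= 0.15 * truth_count

    def test_intensity_remap_is_monotone_over_structures(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        tp = TemplateParams(scales=(1, 1, 1), rotations_deg=(0, 0, 0),
                            translation_frac=(0, 0, 0), warp_sigma_vox=0.0, noise_sigma=0.0)
        template, labels = sr.make_template(scene, tp, seed=0)
        truth_means, temp_means = [], []
        for lab in (LABEL_TISSUE, LABEL_BULB, LABEL_INNER):
            sel = scene.truth_labels.labels == lab
            truth_means.append(scene.truth_volume.voxels[sel].mean())
            temp_means.append(template.voxels[sel].mean())
        # rank correlation of paired structure means is exactly 1
        assert np.array_equal(np.argsort(truth_means), np.argsort(temp_means))

    def test_rough_warp_spacing_rejected(self, scene64):
        with pytest.raises(ValueError):
            sr.make_template(scene64, TemplateParams(warp_spacing_vox=4))

    def test_ground_truth_closure_template_reproducible(self):
        scene = sr.make_scene((64, 64, 48), seed=2)
        template, labels = sr.make_template(scene, seed=3)
        tmap = scene.template_warp["transform"]
        relabeled = sr.resample_volume(scene.truth_labels, tmap, "nearest", reference=scene.truth_labels)
        assert np.array_equal(relabeled.labels, labels.labels)
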