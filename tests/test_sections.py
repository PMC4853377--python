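"""Section-to-blockface alignment: masks, rotation search, landmark and
feature fits, rigid interpolation, and the PLI refinement."""

import numpy as np
import pytest

import serialrecon as sr
from serialrecon.phantom import SectionDeformParams
from serialrecon.resample import resample_mask
from serialrecon.sections import (
    brute_force_rotation,
    cog_align,
    feature_match_rigid,
    interpolate_rigid,
    landmark_rigid,
    pli_refine,
    tissue_mask_2d,
)


def blob_image(cx=32, cy=32, r=14, shape=(64, 64), texture_seed=None):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = 0.5 * (((xx - cx) / r) ** 2 + ((yy - cy) / r) ** 2 <= 1).astype(float)
    if texture_seed is not None:
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(texture_seed)
        img = img * (1 + 0.3 * gaussian_filter(rng.standard_normal(shape), 1.5))
    return sr.Image2D(img, (1.0, 1.0))


class TestTissueMask:
    def test_phantom_slice_mask_dice(self, scene64):
        z = 24
        img = scene64.truth_volume.slice_image(z)
        mask = tissue_mask_2d(img)
        truth = sr.BinaryMask(scene64.truth_labels.labels[z] > 0, scene64.spacing[:2])
        assert sr.dice(mask, truth) >= 0.95

    def test_two_blobs_keeps_larger(self):
        img = blob_image(20, 20, 12)
        img = sr.Image2D(img.pixels + blob_image(52, 52, 5).pixels, (1, 1))
        mask = tissue_mask_2d(img)
        assert mask.bits[20, 20] and not mask.bits[52, 52]

    def test_uniform_image_errors(self):
        with pytest.raises(ValueError):
            tissue_mask_2d(sr.Image2D(np.full((32, 32), 0.7), (1, 1)))


class TestCogAlign:
    def test_identical_masks_identity(self):
        m = tissue_mask_2d(blob_image())
        tr = cog_align(m, m)
        assert np.abs(np.asarray(tr.t)).max() < 1e-9

    def test_shifted_mask_exact_translation(self):
        a = tissue_mask_2d(blob_image(34, 29))  # shifted (+2, -3) from (32, 32)
        b = tissue_mask_2d(blob_image(32, 32))
        tr = cog_align(a, b)
        assert np.asarray(tr.t) == pytest.approx((-2.0, 3.0), abs=1e-9)

    def test_cog_uses_binary_weighting(self):
        # an intensity gradient across the blob must not move the mask COG
        img = blob_image(32, 32)
        ramp = sr.Image2D(img.pixels * np.linspace(0.5, 1.5, 64)[None, :], (1, 1))
        assert np.allclose(tissue_mask_2d(ramp).cog_mm(), tissue_mask_2d(img).cog_mm(), atol=0.6)

    def test_empty_mask_errors(self):
        m = sr.BinaryMask(np.zeros((8, 8), bool), (1, 1))
        with pytest.raises(ValueError):
            m.cog_mm()


class TestBruteForceRotation:
    def test_identical_images_zero_angle(self):
        img = blob_image(texture_seed=1)
        tr = brute_force_rotation(img, img, step_deg=1.0, range_deg=20.0)
        assert abs(np.rad2deg(tr.theta)) < 1e-9

    @pytest.mark.parametrize("true_deg", [-7.0, 3.25, 6.5])
    def test_known_rotation_recovered_within_step(self, scene64, true_deg):
        """Noiseless rotation about the tissue COG (translation already
        aligned, per the op's precondition) is recovered within the step."""
        z = 24
        img = scene64.truth_volume.slice_image(z)
        cog = tuple(tissue_mask_2d(img).cog_mm())
        truth = sr.Rigid2D(theta=np.deg2rad(true_deg), center=cog)
        section = sr.resample_image2d(img, truth)
        step = 0.5
        fwd = brute_force_rotation(section, img, step_deg=step, range_deg=10.0,
                                   cog_translation=sr.Rigid2D())
        assert np.rad2deg(fwd.theta) == pytest.approx(true_deg, abs=step + 1e-6)

    def test_returned_angle_minimizes_tested_ssd(self):
        img = blob_image(texture_seed=2)
        rot = sr.resample_image2d(img, sr.Rigid2D(theta=np.deg2rad(4), center=(32, 32)))
        tr, angles, ssds = brute_force_rotation(rot, img, 1.0, 10.0, full_output=True)
        best = np.rad2deg(tr.theta)
        assert ssds[np.argmin(np.abs(angles - best))] == ssds.min()

    def test_nonpositive_step_rejected(self):
        img = blob_image()
        with pytest.raises(ValueError):
            brute_force_rotation(img, img, step_deg=0.0)


class TestLandmarkRigid:
    def test_exact_recovery_of_constructed_rigid(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(0, 5, (6, 2))
        truth = sr.Rigid2D(theta=np.deg2rad(30), t=(1.0, 2.0))
        dst = truth.apply(src)
        fit = landmark_rigid(np.column_stack([src, dst]))
        assert fit.theta == pytest.approx(truth.theta, abs=1e-9)
        assert np.allclose(fit.apply(src), dst, atol=1e-9)

    def test_identical_pairs_identity(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        fit = landmark_rigid(np.column_stack([src, src]))
        assert fit.is_identity

    def test_least_squares_optimality_vs_grid_oracle(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(0, 5, (3, 2))
        dst = rng.uniform(0, 5, (3, 2))
        fit = landmark_rigid(np.column_stack([src, dst]))
        rms_fit = np.sqrt(((fit.apply(src) - dst) ** 2).sum(axis=1).mean())
        # oracle: dense sweep over theta with the optimal translation per angle
        for theta in np.linspace(-np.pi, np.pi, 721):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            t = dst.mean(axis=0) - R @ src.mean(axis=0)
            rms = np.sqrt(((src @ R.T + t - dst) ** 2).sum(axis=1).mean())
            assert rms_fit <= rms + 1e-9

    def test_coincident_points_rejected(self):
        pairs = np.array([[1.0, 1.0, 2.0, 2.0], [1.0, 1.0, 3.0, 3.0]])
        with pytest.raises(ValueError):
            landmark_rigid(pairs)


class TestFeatureMatchRigid:
    def test_image_vs_itself_identity(self, scene96):
        img = scene96.truth_volume.slice_image(30)
        fit = feature_match_rigid(img, img)
        assert np.abs(np.asarray(fit.t)).max() / scene96.spacing[0] < 0.5
        assert abs(np.rad2deg(fit.theta)) < 0.5

    def test_rotation_with_empty_region_recovered(self, scene96):
        """An image and its rotated copy with the internal structure zeroed in
        one of them: the feature fit tolerates the missing signal."""
        z = 30
        sx, sy = scene96.spacing[:2]
        full = scene96.truth_volume.slice_image(z)
        holey = full.pixels.copy()
        holey[scene96.truth_labels.labels[z] == 2] = 0.0
        rot = sr.Rigid2D(theta=np.deg2rad(5), center=(48 * sx, 48 * sy))
        rotated = sr.resample_image2d(sr.Image2D(holey, (sx, sy)), rot)
        fit = feature_match_rigid(rotated, full)
        # the forward map equals the render map: content of the rotated copy
        # sits at R(p) in the original
        assert np.rad2deg(fit.theta) == pytest.approx(5.0, abs=1.0)

    def test_pure_noise_pair_errors(self):
        rng = np.random.default_rng(0)
        a = sr.Image2D(rng.uniform(size=(64, 64)), (1, 1))
        b = sr.Image2D(rng.uniform(size=(64, 64)), (1, 1))
        with pytest.raises(ValueError):
            feature_match_rigid(a, b)


class TestInterpolateRigid:
    def test_anchor_returned_exactly(self):
        anchors = {0: sr.Rigid2D(theta=0.2, t=(1, 2)), 10: sr.Rigid2D(theta=-0.1, t=(0, 0))}
        got = interpolate_rigid(anchors, 0)
        assert got.theta == pytest.approx(0.2)
        assert np.asarray(got.t) == pytest.approx((1, 2))

    def test_linear_midpoint(self):
        anchors = {0: sr.Rigid2D(), 30: sr.Rigid2D(theta=np.deg2rad(10), t=(30.0, 0.0))}
        mid = interpolate_rigid(anchors, 15)
        assert np.rad2deg(mid.theta) == pytest.approx(5.0)
        assert np.asarray(mid.t) == pytest.approx((15.0, 0.0))

    def test_angle_unwrapping_through_pi(self):
        anchors = {0: sr.Rigid2D(theta=np.deg2rad(170)), 10: sr.Rigid2D(theta=np.deg2rad(-170))}
        mid = interpolate_rigid(anchors, 5)
        assert abs(abs(np.rad2deg(mid.theta)) - 180.0) < 1e-6

    def test_outside_range_holds_nearest_anchor(self):
        anchors = {5: sr.Rigid2D(theta=0.3, t=(1, 1)), 8: sr.Rigid2D(theta=0.1, t=(2, 2))}
        assert interpolate_rigid(anchors, 0).theta == pytest.approx(0.3)
        assert interpolate_rigid(anchors, 20).theta == pytest.approx(0.1)

    def test_no_anchors_errors(self):
        with pytest.raises(ValueError):
            interpolate_rigid({}, 3)


class TestPliRefine:
    def test_section_equal_to_blockface_slice(self, scene96, truth_as_blockface96):
        img = truth_as_blockface96.slice_image(32)
        rigid_map, field, info = pli_refine(img, img)
        sx = scene96.spacing[0]
        pts = np.array([[1.0, 1.0], [3.0, 2.0], [2.0, 3.5]])
        assert np.abs(rigid_map.apply(pts) - pts).max() / sx < 0.5
        assert field.max_displacement() / sx < 0.5

    def test_final_similarity_not_worse_than_init(self, scene96, truth_as_blockface96):
        stack = sr.render_sections(scene96, "pli", seed=5)
        i = len(stack) // 2
        z = stack.meta[i]["blockface_slice"]
        _, _, info = pli_refine(stack.slices[i], truth_as_blockface96.slice_image(z))
        assert info["mi_rigid"] >= info["mi_init"] - 1e-12

    def test_phantom_slice_alignment_dice(self, scene96, truth_as_blockface96):
        from serialrecon.transforms import ComposedTransform

        stack = sr.render_sections(scene96, "pli", seed=5)
        sx, sy = scene96.spacing[:2]
        for i in (len(stack) // 3, len(stack) // 2):
            t = scene96.section_truth["pli"][i]
            z = t["blockface_slice"]
            rigid_map, field, _ = pli_refine(stack.slices[i], truth_as_blockface96.slice_image(z))
            final = ComposedTransform([rigid_map, field]) if field.max_displacement() > 0 else rigid_map
            tm = sr.BinaryMask(scene96.truth_labels.labels[z] > 0, (sx, sy))
            sec_mask = resample_mask(tm, t["transform"])
            aligned = resample_mask(sec_mask, final, spacing=(sx, sy), shape=(96, 96))
            assert sr.dice(aligned, tm) >= 0.95

    def test_control_grid_size_is_5_by_6(self, scene96, truth_as_blockface96):
        img = truth_as_blockface96.slice_image(32)
        _, field, _ = pli_refine(img, img)
        assert field.grid_shape == (5, 6)
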