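"""Transform algebra, B-spline field evaluation, and resampling contracts."""

import numpy as np
import pytest
import SimpleITK as sitk
from hypothesis import given, settings, strategies as st

import serialrecon as sr
from serialrecon.resample import resample_volume
from serialrecon.transforms import (
    BSplineField,
    ComposedTransform,
    IdentityTransform,
    load_transforms,
    save_transforms,
    transform_from_dict,
    transform_to_dict,
)

finite = st.floats(-3, 3, allow_nan=False)


class TestRigid2D:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=st.floats(-np.pi, np.pi), tx=finite, ty=finite, cx=finite, cy=finite)
    def test_inverse_roundtrip(self, theta, tx, ty, cx, cy):
        tr = sr.Rigid2D(theta=theta, t=(tx, ty), center=(cx, cy))
        pts = np.array([[0.3, -1.2], [2.0, 0.5], [-0.7, 0.9]])
        back = tr.inverse().apply(tr.apply(pts))
        assert np.allclose(back, pts, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(-2, 2), b=st.floats(-2, 2), c=st.floats(-2, 2))
    def test_composition_matches_sequential_and_is_associative(self, a, b, c):
        t1 = sr.Rigid2D(theta=a, t=(1.0, 0.0))
        t2 = sr.Rigid2D(theta=b, t=(0.0, -1.0), center=(0.5, 0.5))
        t3 = sr.Rigid2D(theta=c, t=(0.3, 0.3))
        pts = np.array([[0.1, 0.2], [1.5, -0.4]])
        seq = t1.apply(t2.apply(t3.apply(pts)))
        assert np.allclose(t1.compose(t2).compose(t3).apply(pts), seq, atol=1e-9)
        assert np.allclose(t1.compose(t2.compose(t3)).apply(pts), seq, atol=1e-9)

    def test_composition_of_rigids_is_rigid(self):
        t = sr.Rigid2D(theta=0.7, t=(1, 2)).compose(sr.Rigid2D(theta=-0.2, t=(3, -1)))
        R = t.matrix()[:2, :2]
        assert np.allclose(R.T @ R, np.eye(2), atol=1e-12)


class TestAffine3D:
    def test_inverse_and_compose(self):
        A = sr.Affine3D(M=np.diag([1.1, 0.9, 1.0]) + 0.05, t=(1, -2, 3))
        B = sr.Affine3D.from_params(scales=(0.95, 1.05, 1.0), rotations_deg=(5, -3, 8), translation=(0.1, 0, 0))
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(A.inverse().apply(A.apply(pts)), pts, atol=1e-9)
        assert np.allclose(A.compose(B).apply(pts), A.apply(B.apply(pts)), atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            sr.Affine3D(M=np.zeros((3, 3)))


class TestBSplineField:
    def test_matches_itk_tensor_product_evaluation(self):
        """The in-repo FFD evaluation is checked against the engine's own
        transform-point computation on random coefficients."""
        rng = np.random.default_rng(0)
        img = sitk.GetImageFromArray(np.zeros((20, 24, 28), np.float32))
        img.SetSpacing((0.5, 0.6, 0.7))
        tx = sitk.BSplineTransformInitializer(img, (3, 2, 4), 3)
        params = rng.normal(0, 0.3, len(tx.GetParameters()))
        tx.SetParameters(params.tolist())
        fp = np.asarray(tx.GetFixedParameters())
        gsize = fp[0:3].astype(int)
        coeff = params.reshape(3, gsize[2], gsize[1], gsize[0]).transpose(3, 2, 1, 0)
        field = BSplineField(grid_origin=fp[3:6], grid_spacing=fp[6:9], coefficients=coeff)
        pts = rng.uniform([1, 1, 1], [12, 12, 12], (40, 3))
        ours = field.apply(pts)
        theirs = np.array([tx.TransformPoint(tuple(p)) for p in pts])
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_zero_outside_domain(self):
        field = BSplineField.zero((4.0, 4.0), (1.0, 1.0))
        field.coefficients += 1.0
        far = np.array([[50.0, 50.0], [-50.0, -10.0]])
        assert np.allclose(field.apply(far), far)

    def test_grid_covers_domain_with_cubic_margin(self):
        field = BSplineField.zero((4.0, 3.0, 2.0), (1.0, 1.0, 1.0))
        assert field.grid_shape == (7, 6, 5)  # ceil(size/spacing) + 3


class TestSerialization:
    def test_roundtrip_all_types(self, tmp_path):
        field = BSplineField.zero((2.0, 2.0), (1.0, 1.0))
        field.coefficients = np.random.default_rng(1).normal(size=field.coefficients.shape)
        transforms = [
            sr.Rigid2D(theta=0.3, t=(1, 2), center=(0.5, 0.5)),
            sr.Affine3D(M=np.eye(3) * 1.1, t=(0, 1, 2)),
            field,
            IdentityTransform(3),
            ComposedTransform([sr.Rigid2D(theta=0.1), field]),
        ]
        path = tmp_path / "transforms.json"
        save_transforms(transforms, path)
        loaded = load_transforms(path)
        pts2 = np.array([[0.4, 0.9], [1.2, 1.7]])
        pts3 = np.array([[0.4, 0.9, 1.1]])
        for orig, back in zip(transforms, loaded):
            pts = pts3 if getattr(orig, "ndim", 2) == 3 else pts2
            assert np.allclose(orig.apply(pts), back.apply(pts), atol=1e-12)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            transform_from_dict({"type": "teleport"})


class TestResample:
    def _volume(self):
        rng = np.random.default_rng(0)
        return sr.ImageVolume(rng.uniform(size=(10, 12, 14)), (0.5, 0.5, 0.5))

    def test_identity_nearest_returns_input(self):
        vol = self._volume()
        out = resample_volume(vol, IdentityTransform(3), "nearest", reference=vol)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_label_value_closure_under_any_transform(self):
        lab = np.zeros((10, 12, 14), dtype=np.int16)
        lab[2:6, 3:8, 4:9] = 5
        lab[4, 4, 5] = 9
        labels = sr.LabelVolume(lab, (0.5, 0.5, 0.5))
        tr = sr.Affine3D.from_params(scales=(1.1, 0.9, 1.0), rotations_deg=(4, 2, -3), translation=(0.2, 0.1, 0))
        out = resample_volume(labels, tr, reference=labels)
        assert set(np.unique(out.labels)) <= set(np.unique(lab)) | {0}

    def test_label_with_linear_interpolation_rejected(self):
        labels = sr.LabelVolume(np.ones((4, 4, 4), dtype=np.int16), (1, 1, 1))
        from serialrecon.resample import _order_for

        with pytest.raises(ValueError):
            _order_for("linear", is_label=True)

    def test_integer_translation_relocates_delta_exactly(self):
        vox = np.zeros((10, 12, 14))
        vox[5, 6, 7] = 1.0
        vol = sr.ImageVolume(vox, (1.0, 1.0, 1.0))
        # content moves by (+2, -1, +3) voxels in (x, y, z):
        # the resampling map sends output coords to input coords
        shift = np.array([2.0, -1.0, 3.0])
        tr = sr.Affine3D(M=np.eye(3), t=tuple(-shift))
        out = resample_volume(vol, tr, "linear", reference=vol)
        expected = np.zeros_like(vox)
        expected[5 + 3, 6 - 1, 7 + 2] = 1.0
        assert np.allclose(out.voxels, expected, atol=1e-12)

    def test_rigid_roundtrip_preserves_foreground(self):
        zz, yy, xx = np.mgrid[0:64, 0:64, 0:64]
        bits = (xx - 32) ** 2 + (yy - 32) ** 2 + (zz - 32) ** 2 <= 20**2
        labels = sr.LabelVolume(bits.astype(np.int16), (1, 1, 1))
        tr = sr.Affine3D.from_params(rotations_deg=(7, -4, 11), translation=(1.5, -2.5, 0.5), center=(32, 32, 32))
        fwd = resample_volume(labels, tr, reference=labels)
        back = resample_volume(fwd, tr.inverse(), reference=labels)
        recovered = np.logical_and(back.labels > 0, bits).sum()
        assert recovered / bits.sum() >= 0.99

    def test_composed_equals_sequential_within_interpolation_error(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        vox = gaussian_filter(rng.uniform(size=(16, 16, 16)), 2.0)
        vol = sr.ImageVolume(vox, (0.5, 0.5, 0.5))
        t1 = sr.Affine3D.from_params(rotations_deg=(0, 0, 5), translation=(0.3, 0, 0), center=(3, 3, 3))
        t2 = sr.Affine3D.from_params(rotations_deg=(0, 3, 0), translation=(0, -0.2, 0.1), center=(3, 3, 3))
        once = resample_volume(vol, t1.compose(t2), "linear", reference=vol)
        # resampling by t1 then by t2 composes content maps as t1 ∘ t2
        step = resample_volume(resample_volume(vol, t1, "linear", reference=vol), t2, "linear", reference=vol)
        core = (slice(3, -3),) * 3
        assert np.abs(once.voxels[core] - step.voxels[core]).max() < 5e-3
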