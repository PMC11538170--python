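"""Affine and demons-style nonlinear registration contracts."""

import numpy as np
import pytest
from scipy import ndimage

from atrspect.atr import similarity_mask, zncc
from atrspect.imaging_core import Volume, resample
from atrspect.phantom import (
    CAUDATE_CENTER,
    OCCIPITAL_MID_CENTER,
    PUTAMEN_CENTER,
    WHITE_LEVEL,
    PhantomSpec,
    generate_phantom,
)
from atrspect.registration import (
    AffineTransform,
    DeformationField,
    RegistrationError,
    affine_register,
    apply_normalization,
    nonlinear_register,
    params_to_matrix,
)


def _mirror(c):
    return (-c[0], c[1], c[2])


STRIATAL_CENTERS = [
    CAUDATE_CENTER,
    _mirror(CAUDATE_CENTER),
    PUTAMEN_CENTER,
    _mirror(PUTAMEN_CENTER),
]
OCCIPITAL_CENTERS = [OCCIPITAL_MID_CENTER, _mirror(OCCIPITAL_MID_CENTER)]


def image_landmarks(vol):
    """Structure centroids measured on the image: striatal centers of mass
    above the cortical level, occipital centers above the white-matter
    level, each within a generous ball around the canonical position."""
    w = vol.grid.world_coordinates()
    out = []
    for c, floor, radius in [(c, 1.0, 20.0) for c in STRIATAL_CENTERS] + [
        (c, WHITE_LEVEL, 22.0) for c in OCCIPITAL_CENTERS
    ]:
        ball = np.linalg.norm(w - np.array(c), axis=-1) < radius
        d = np.clip(vol.data - floor, 0, None) * ball
        out.append((w * d[..., None]).sum(axis=(0, 1, 2)) / d.sum())
    return np.array(out)


@pytest.fixture(scope="module")
def normal_subject(pair):
    spec = PhantomSpec(
        shape=(64, 64, 64), spacing=(3.44,) * 3,
        caudate_ratio_left=3.5, caudate_ratio_right=3.5,
        putamen_ratio_left=3.5, putamen_ratio_right=3.5,
    )
    vol, _, _ = generate_phantom(spec, seed=41)
    return vol


class TestAffineTransform:
    def test_identity_round_trip(self):
        t = AffineTransform.identity()
        xyz = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_allclose(t(xyz), xyz)

    def test_collapsed_transform_rejected(self):
        mat = np.diag([0.01, 0.01, 0.01, 1.0])
        with pytest.raises(ValueError, match="determinant"):
            AffineTransform(mat)

    def test_parameterization_identity_at_zero(self):
        np.testing.assert_allclose(params_to_matrix(np.zeros(12)), np.eye(4), atol=1e-12)

    def test_inverse_composes_to_identity(self):
        params = np.array([3, -2, 1, 0.1, -0.05, 0.2, 0.05, -0.03, 0.08, 0.02, -0.01, 0.03])
        t = AffineTransform(params_to_matrix(params))
        xyz = np.random.default_rng(0).random((10, 3)) * 50
        np.testing.assert_allclose(t.inverse()(t(xyz)), xyz, atol=1e-9)


class TestAffineRegister:
    def test_self_registration_is_identity(self, pair):
        mask = similarity_mask(pair)
        t = affine_register(pair.normal, pair.normal, mask=mask)
        assert np.abs(t.matrix[:3, 3]).max() < 0.5  # translation, mm
        assert np.abs(t.matrix[:3, :3] - np.eye(3)).max() < 0.01  # scale/rot

    def test_known_translation_recovered_within_one_mm(self, pair, normal_subject):
        mask = similarity_mask(pair)
        shift = np.array([6.0, -4.0, 2.0])
        moving = resample(normal_subject, normal_subject.grid, lambda x: x - shift)
        t = affine_register(moving, pair.normal, mask=mask)
        np.testing.assert_allclose(t.matrix[:3, 3], shift, atol=1.0)

    def test_known_isotropic_scale_recovered_within_two_percent(self, pair, normal_subject):
        mask = similarity_mask(pair)
        moving = resample(normal_subject, normal_subject.grid, lambda x: x / 1.1)
        t = affine_register(moving, pair.normal, mask=mask)
        scales = np.linalg.norm(t.matrix[:3, :3], axis=0)
        np.testing.assert_allclose(scales, 1.1, rtol=0.02)

    def test_final_similarity_not_below_start(self, pair, normal_subject):
        mask = similarity_mask(pair)
        t = affine_register(normal_subject, pair.normal, mask=mask)
        start = zncc(normal_subject, pair.normal, mask).value
        assert t.metric_value >= start - 1e-9

    def test_constant_volume_rejected(self, pair):
        flat = pair.normal.copy_with(np.full(pair.grid.shape, 1.0))
        with pytest.raises(ValueError, match="constant"):
            affine_register(flat, pair.normal)


class TestNonlinearRegister:
    def test_self_registration_gives_near_zero_field(self, pair):
        field = nonlinear_register(pair.normal, pair.normal, mask=similarity_mask(pair))
        assert field.max_displacement() < 1.0

    def test_zncc_never_decreases(self, pair, normal_subject):
        mask = similarity_mask(pair)
        before = zncc(normal_subject, pair.normal, mask).value
        field = nonlinear_register(normal_subject, pair.normal, mask=mask)
        after = zncc(field.warp(normal_subject), pair.normal, mask).value
        assert after >= before - 1e-12

    def test_no_folding_on_phantom_pairs(self, pair, normal_subject):
        field = nonlinear_register(normal_subject, pair.normal, mask=similarity_mask(pair))
        dets = field.jacobian_determinants()
        assert dets[1:-1, 1:-1, 1:-1].min() > 0

    def test_shortened_structure_recovered_within_ten_percent(self, pair):
        """A template with the putamen 20% shorter than the moving image:
        after warping, the moving structure's half-maximum length must be
        within 10% of the template's."""
        base = dict(shape=(64, 64, 64), spacing=(3.44,) * 3,
                    caudate_ratio_left=3.0, caudate_ratio_right=3.0,
                    putamen_ratio_left=3.0, putamen_ratio_right=3.0)
        mov, _, _ = generate_phantom(PhantomSpec(**base), seed=11)
        tpl, _, _ = generate_phantom(
            PhantomSpec(**base, putamen_posterior_fraction_left=0.8,
                        putamen_posterior_fraction_right=0.8),
            seed=12,
        )

        def putamen_length(vol):
            w = vol.grid.world_coordinates()
            sel = (np.abs(w[..., 0] - PUTAMEN_CENTER[0]) < 7) & (
                np.abs(w[..., 2] - PUTAMEN_CENTER[2]) < 7
            )
            prof = np.where(sel, vol.data, 0).max(axis=(0, 2))
            y = w[0, :, 0, 1]
            fy = np.linspace(y[0], y[-1], 2000)
            fv = np.interp(fy, y, prof)
            return (fv > 0.75 * fv.max()).mean() * (y[-1] - y[0])

        field = nonlinear_register(mov, tpl, mask=similarity_mask(pair))
        warped_len = putamen_length(field.warp(mov))
        assert warped_len == pytest.approx(putamen_length(tpl), rel=0.10)

    def test_known_deformation_landmarks_recovered_over_affine(self, pair, normal_subject):
        """Phantom warped by a known smooth non-affine field: the full
        normalization must cut the mean image-landmark error by >=50%
        relative to affine-only."""
        grid = normal_subject.grid
        w = grid.world_coordinates()

        def bump(center, sigma):
            return np.exp(-((w - np.array(center)) ** 2).sum(axis=-1) / (2 * sigma**2))

        u_true = np.zeros((3, *grid.shape))
        u_true[1] = (
            9.0 * bump(_mirror(PUTAMEN_CENTER), 14.0)
            - 9.0 * bump(PUTAMEN_CENTER, 14.0)
            - 6.0 * bump(CAUDATE_CENTER, 14.0)
            + 6.0 * bump(_mirror(CAUDATE_CENTER), 14.0)
        )
        idx = np.indices(grid.shape, dtype=float)
        coords = [idx[a] + u_true[a] / grid.spacing[a] for a in range(3)]
        subject = Volume(
            ndimage.map_coordinates(normal_subject.data, coords, order=1,
                                    mode="constant", cval=0.0, prefilter=False),
            grid,
        )
        mask = similarity_mask(pair)
        ref_lm = image_landmarks(normal_subject)
        t = affine_register(subject, pair.normal, mask=mask)
        aligned = resample(subject, grid, t)
        e_affine = np.linalg.norm(image_landmarks(aligned) - ref_lm, axis=1).mean()
        field = nonlinear_register(aligned, pair.normal, mask=mask)
        e_full = np.linalg.norm(image_landmarks(field.warp(aligned)) - ref_lm, axis=1).mean()
        assert e_full <= 0.5 * e_affine

    def test_grid_mismatch_rejected(self, pair):
        from atrspect.imaging_core import centered_grid

        other = Volume(np.ones((32, 32, 32)), centered_grid((32, 32, 32), 2.0))
        with pytest.raises(ValueError, match="template grid"):
            nonlinear_register(other, pair.normal)


class TestApplyNormalization:
    def test_identity_affine_and_zero_field_preserve_input(self, normal_subject):
        out = apply_normalization(
            normal_subject,
            AffineTransform.identity(),
            DeformationField.zero(normal_subject.grid),
        )
        np.testing.assert_allclose(out.data, normal_subject.data, atol=1e-10)

    def test_affine_with_zero_field_equals_plain_resample(self, normal_subject):
        shift = np.array([4.3, -1.1, 2.2])
        t = AffineTransform(params_to_matrix(np.r_[shift, np.zeros(9)]))
        out = apply_normalization(
            normal_subject, t, DeformationField.zero(normal_subject.grid)
        )
        expected = resample(normal_subject, normal_subject.grid, t)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-10)

    def test_single_interpolation_beats_two_step_resampling(self, pair, normal_subject):
        """Composing affine and field before one resample must match the
        ground truth at least as well as two sequential interpolations."""
        mask = similarity_mask(pair)
        grid = normal_subject.grid
        shift = np.array([3.7, -2.9, 1.3])
        t = AffineTransform(params_to_matrix(np.r_[shift, np.zeros(9)]))
        w = grid.world_coordinates()
        u = np.zeros((3, *grid.shape))
        u[0] = 2.0 * np.exp(-((w**2).sum(axis=-1)) / (2 * 30.0**2))
        field = DeformationField(u, grid)

        composed = apply_normalization(normal_subject, t, field)
        two_step = field.warp(resample(normal_subject, grid, t))
        # ground truth: sample the analytic subject definition once
        spec = PhantomSpec(
            shape=(64, 64, 64), spacing=(3.44,) * 3,
            caudate_ratio_left=3.5, caudate_ratio_right=3.5,
            putamen_ratio_left=3.5, putamen_ratio_right=3.5,
        )
        vol_hi, _, _ = generate_phantom(spec, seed=41)
        xyz = w.reshape(-1, 3) + field.displacement.reshape(3, -1).T
        truth_data = ndimage.map_coordinates(
            vol_hi.data,
            grid.world_to_voxel(t(xyz)).T,
            order=3, mode="constant", cval=0.0,
        ).reshape(grid.shape)
        truth = Volume(np.clip(truth_data, 0, None), grid)
        z_composed = zncc(composed, truth, mask).value
        z_twostep = zncc(two_step, truth, mask).value
        assert z_composed >= z_twostep - 1e-9

    def test_missing_field_is_an_error(self, normal_subject):
        with pytest.raises(ValueError, match="deformation field"):
            apply_normalization(normal_subject, AffineTransform.identity(), None)
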