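"""Atlas construction: one-pass warped averaging, label probability
maps, average inverse field, unbiasing."""

import numpy as np
import pytest

from bodyatlas.atlas import (
    Atlas,
    average_inverse_field,
    build_initial_atlas,
    build_label_atlas,
    unbias_atlas,
)
from bodyatlas.containers import DisplacementField, Grid, LabelVolume, Volume
from bodyatlas.transforms import integrate_velocity, invert, warp_volume

from conftest import smooth_random_field


def constant_field(grid, t):
    return DisplacementField(
        np.broadcast_to(np.asarray(t, float), grid.shape + (3,)).copy(), grid
    )


@pytest.fixture()
def grid():
    return Grid((12, 12, 12), (2.0, 2.0, 2.0))


class TestInitialAtlas:
    def test_single_subject_identity_field(self, grid, rng):
        img = Volume(rng.random(grid.shape), grid)
        atlas, cov = build_initial_atlas([img], [DisplacementField.zeros(grid)])
        np.testing.assert_allclose(atlas.data, img.data, atol=1e-12)
        np.testing.assert_allclose(cov.data, 1.0)

    def test_two_constant_images_average(self, grid):
        a = Volume(np.zeros(grid.shape), grid)
        b = Volume(np.ones(grid.shape), grid)
        z = DisplacementField.zeros(grid)
        atlas, _ = build_initial_atlas([a, b], [z, z])
        np.testing.assert_allclose(atlas.data, 0.5)

    def test_matches_warp_then_mean_oracle(self, grid, rng):
        imgs = [Volume(rng.random(grid.shape), grid) for _ in range(5)]
        fields = [smooth_random_field(grid, 1.5, seed=30 + i) for i in range(5)]
        atlas, _ = build_initial_atlas(imgs, fields)
        oracle = np.mean([warp_volume(i, f).data for i, f in zip(imgs, fields)], axis=0)
        np.testing.assert_allclose(atlas.data, oracle, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_initial_atlas([], [])


class TestLabelAtlas:
    def _labels(self, grid, data):
        return LabelVolume(data.astype(np.int16), grid, {0: "background", 1: "organ"})

    def test_single_subject_identity_equals_binary_mask(self, grid):
        data = np.zeros(grid.shape)
        data[3:6, 3:6, 3:6] = 1
        lab = self._labels(grid, data)
        probs = build_label_atlas([lab], [DisplacementField.zeros(grid)])
        np.testing.assert_allclose(probs["organ"].data, data, atol=1e-12)

    def test_identical_structures_probability_one(self, grid):
        data = np.zeros(grid.shape)
        data[4:8, 4:8, 4:8] = 1
        labs = [self._labels(grid, data) for _ in range(2)]
        z = DisplacementField.zeros(grid)
        probs = build_label_atlas(labs, [z, z])
        np.testing.assert_allclose(probs["organ"].data, data, atol=1e-12)

    def test_half_overlap_gives_half_on_symmetric_difference(self, grid):
        a = np.zeros(grid.shape)
        a[2:6, 4:8, 4:8] = 1
        b = np.zeros(grid.shape)
        b[4:8, 4:8, 4:8] = 1
        z = DisplacementField.zeros(grid)
        probs = build_label_atlas([self._labels(grid, a), self._labels(grid, b)], [z, z])
        sym_diff = (a.astype(bool)) ^ (b.astype(bool))
        np.testing.assert_allclose(probs["organ"].data[sym_diff], 0.5)
        np.testing.assert_allclose(probs["organ"].data[a.astype(bool) & b.astype(bool)], 1.0)

    def test_inconsistent_dictionaries_rejected(self, grid):
        a = self._labels(grid, np.zeros(grid.shape))
        b = LabelVolume(np.zeros(grid.shape, np.int16), grid, {0: "background", 1: "liver"})
        with pytest.raises(ValueError, match="dictionaries"):
            build_label_atlas([a, b], [DisplacementField.zeros(grid)] * 2)


class TestAverageInverseField:
    def test_symmetric_translations_cancel(self, grid):
        t = (1.5, -1.0, 0.5)
        fields = [constant_field(grid, t), constant_field(grid, tuple(-x for x in t))]
        phi = average_inverse_field(fields)
        np.testing.assert_allclose(phi.data, 0.0, atol=1e-9)

    def test_single_field_is_its_inverse(self, grid):
        f = integrate_velocity(smooth_random_field(grid, 2.0, seed=40), 6)
        phi = average_inverse_field([f])
        expected = invert(f)
        np.testing.assert_allclose(phi.data, expected.data, atol=1e-9)

    def test_matches_invert_each_then_mean_oracle(self, grid):
        fields = [
            integrate_velocity(smooth_random_field(grid, 2.0, seed=50 + i), 6)
            for i in range(5)
        ]
        phi = average_inverse_field(fields)
        oracle = np.mean([invert(f).data for f in fields], axis=0)
        np.testing.assert_allclose(phi.data, oracle, atol=1e-12)


def make_atlas(anat, probs=None, fields=None, n=1):
    return Atlas(
        anatomical=anat,
        probabilities=probs or {},
        coverage=Volume(np.ones(anat.grid.shape), anat.grid),
        n_subjects=n,
    )


class TestUnbiasing:
    def test_identity_fields_leave_atlas_unchanged(self, grid, rng):
        anat = Volume(rng.random(grid.shape), grid)
        atlas = make_atlas(anat)
        out = unbias_atlas(atlas, [DisplacementField.zeros(grid)])
        np.testing.assert_allclose(out.anatomical.data, anat.data, atol=1e-9)
        assert out.unbiased

    def test_single_subject_roundtrip_recovers_image(self):
        # n=1: A_u = (I ∘ phi) ∘ phi^{-1} ≈ I up to two interpolations
        grid = Grid((16, 16, 16), (2.0, 2.0, 2.0))
        from scipy import ndimage

        r = np.random.default_rng(3)
        raw = ndimage.gaussian_filter(r.random(grid.shape), 2.5)
        img = Volume((raw - raw.min()) / (raw.max() - raw.min()), grid)
        phi = integrate_velocity(smooth_random_field(grid, 2.0, seed=60), 6)
        warped, cov = build_initial_atlas([img], [phi])
        atlas = make_atlas(warped)
        out = unbias_atlas(atlas, [phi])
        dyn = img.data.max() - img.data.min()
        interior = (slice(3, -3),) * 3
        err = np.abs(out.anatomical.data - img.data)[interior]
        assert err.max() < 0.02 * dyn

    def test_translation_population_closed_form(self, grid, rng):
        # for pure translations the unbiased atlas equals the initial atlas
        # translated by mean(-t_i), exactly
        from scipy import ndimage

        img = Volume(ndimage.gaussian_filter(rng.random(grid.shape), 1.5), grid)
        ts = [np.array([2.0, 0.0, -2.0]), np.array([-1.0, 1.0, 0.0]), np.array([0.5, -0.5, 1.0])]
        fields = [constant_field(grid, tuple(t)) for t in ts]
        a_init, _ = build_initial_atlas([img] * 3, fields)
        out = unbias_atlas(make_atlas(a_init, n=3), fields)
        phi_bar = average_inverse_field(fields)
        np.testing.assert_allclose(
            phi_bar.data, np.broadcast_to(-np.mean(ts, axis=0), phi_bar.data.shape), atol=1e-9
        )
        expected = warp_volume(a_init, constant_field(grid, tuple(-np.mean(ts, axis=0))))
        np.testing.assert_allclose(out.anatomical.data, expected.data, atol=1e-12)

    def test_bias_reduction_on_symmetric_population(self):
        # population deformed symmetrically about the template; reference
        # deliberately off-centre: unbiasing moves the atlas centroid back
        grid = Grid((24, 16, 16), (2.0, 2.0, 2.0))
        data = np.zeros(grid.shape)
        data[8:16, 5:11, 5:11] = 1.0
        from scipy import ndimage

        template = Volume(ndimage.gaussian_filter(data, 1.0), grid)
        shifts = [np.array([4.0, 0.0, 0.0]), np.array([-4.0, 0.0, 0.0]), np.zeros(3)]
        # subjects are template translated by s_i; reference = subject 0 (off-centre)
        subjects = [
            warp_volume(template, constant_field(grid, tuple(-s))) for s in shifts
        ]
        reference = subjects[0]
        # fields mapping reference space -> subject space found by translation:
        # subject_i = template shifted by s_i, reference = template shifted by s_0
        fields = [constant_field(grid, tuple(shifts[0] - s)) for s in shifts]
        a_init, _ = build_initial_atlas(subjects, fields)
        out = unbias_atlas(make_atlas(a_init, n=3), fields)

        def centroid(v):
            w = np.clip(v.data, 0, None)
            pts = v.grid.coordinates()
            return (w[..., None] * pts).sum(axis=(0, 1, 2)) / w.sum()

        c_template = centroid(template)
        bias_init = np.linalg.norm(centroid(a_init) - c_template)
        bias_unbiased = np.linalg.norm(centroid(out.anatomical) - c_template)
        assert bias_unbiased < bias_init

    def test_probability_range_preserved(self, grid, rng):
        prob = Volume(np.clip(rng.random(grid.shape), 0, 1), grid)
        atlas = make_atlas(Volume(rng.random(grid.shape), grid), probs={"organ": prob})
        f = integrate_velocity(smooth_random_field(grid, 2.0, seed=70), 6)
        out = unbias_atlas(atlas, [f])
        assert out.probabilities["organ"].data.min() >= 0.0
        assert out.probabilities["organ"].data.max() <= 1.0


class TestWarpingConsistency:
    def test_average_then_warp_equals_warp_then_average(self, grid, rng):
        # shared field commutes with averaging to interpolation tolerance
        from scipy import ndimage

        maps = [
            Volume(ndimage.gaussian_filter(rng.random(grid.shape), 1.5), grid)
            for _ in range(3)
        ]
        shared = integrate_velocity(smooth_random_field(grid, 1.5, seed=80), 6)
        warped_mean = warp_volume(
            Volume(np.mean([m.data for m in maps], axis=0), grid), shared
        )
        mean_warped = np.mean([warp_volume(m, shared).data for m in maps], axis=0)
        np.testing.assert_allclose(warped_mean.data, mean_warped, atol=1e-9)
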