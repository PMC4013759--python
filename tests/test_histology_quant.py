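"""Optical density, stain unmixing round trips, DAB means, vacuolation."""

import numpy as np
import pytest

import sod1mri as s
from oracles import vacuole_pixel_count_brute


class TestOpticalDensity:
    @pytest.mark.parametrize("ratio,od", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decade_definition(self, ratio, od):
        i0 = (255.0, 255.0, 255.0)
        img = np.full((2, 2, 3), 255.0) * ratio
        np.testing.assert_allclose(s.rgb_to_od(img, i0), od, atol=1e-12)

    def test_nonpositive_i0_rejected(self):
        with pytest.raises(ValueError):
            s.rgb_to_od(np.ones((2, 2, 3)), (0.0, 255.0, 255.0))

    def test_od_clipped_nonnegative_above_white(self):
        img = np.full((2, 2, 3), 300.0)  # brighter than I0
        assert (s.rgb_to_od(img, (255.0,) * 3) == 0).all()


class TestColorDeconvolution:
    def test_zero_od_gives_zero_densities(self):
        out = s.color_deconvolve(np.zeros((4, 4, 3)))
        for name in out.stain_names:
            np.testing.assert_array_equal(out[name], 0.0)

    def test_round_trip_recovers_generated_density_fields(self, rng):
        dab = rng.uniform(0.0, 1.5, (32, 32))
        hem = rng.uniform(0.0, 1.0, (32, 32))
        spec = s.HistologySpec(
            image_shape=(32, 32), dab_density=dab, hematoxylin_density=hem
        )
        image, truth = s.generate_histology_image(spec)
        od = s.rgb_to_od(image, spec.i0)
        out = s.color_deconvolve(od, spec.stain_vectors)
        assert np.abs(out["dab"] - truth.dab_density).max() < 1e-6
        assert np.abs(out["hematoxylin"] - truth.hematoxylin_density).max() < 1e-6
        np.testing.assert_allclose(out["residual"], 0.0, atol=1e-6)

    def test_pure_hematoxylin_pixel_has_zero_dab(self):
        spec = s.HistologySpec(
            image_shape=(4, 4), dab_density=0.0, hematoxylin_density=0.8
        )
        image, _ = s.generate_histology_image(spec)
        out = s.color_deconvolve(s.rgb_to_od(image, spec.i0), spec.stain_vectors)
        np.testing.assert_allclose(out["dab"], 0.0, atol=1e-10)

    def test_matches_skimage_unmixing(self, rng):
        # independent reference: skimage separate_stains on the same matrix,
        # rescaled from its log-1e-6 units to log10 optical density
        from skimage.color import separate_stains

        dab = rng.uniform(0.1, 1.0, (16, 16))
        spec = s.HistologySpec(image_shape=(16, 16), dab_density=dab)
        image, truth = s.generate_histology_image(spec)
        out = s.color_deconvolve(s.rgb_to_od(image, spec.i0), spec.stain_vectors)
        conv = np.linalg.inv(out.stain_vectors)
        sk = separate_stains(image / np.asarray(spec.i0), conv)
        scale = -np.log(1e-6) / np.log(10)
        np.testing.assert_allclose(sk[..., 1] * scale, out["dab"], atol=1e-4)

    def test_negative_densities_clipped_and_counted(self):
        od = np.full((2, 2, 3), 0.0)
        od[..., 0] = 0.5  # off-simplex OD -> some negative solution entries
        out = s.color_deconvolve(od)
        assert out.n_negative_clipped > 0
        for name in out.stain_names:
            assert (out[name] >= 0).all()

    def test_collinear_vectors_rejected(self):
        v = np.tile(np.array([[0.5, 0.5, np.sqrt(0.5)]]), (2, 1))
        with pytest.raises(ValueError, match="collinear|ill-conditioned"):
            s.color_deconvolve(np.zeros((2, 2, 3)), v)


class TestMeanDabOd:
    def test_uniform_density_any_circle(self):
        d = np.full((64, 64), 0.37)
        assert s.mean_dab_od([d], (32, 32), 20.0) == pytest.approx(0.37)

    def test_unweighted_mean_over_sections(self):
        secs = [np.full((32, 32), v) for v in (0.1, 0.2, 0.3)]
        assert s.mean_dab_od(secs, (16, 16), 10.0) == pytest.approx(0.2)

    def test_half_disc_approaches_half_density(self):
        d = np.zeros((512, 512))
        d[:, 256:] = 1.0  # axis-aligned split through the circle center
        val = s.mean_dab_od([d], (255.5, 255.5), 400.0)
        assert val == pytest.approx(0.5, abs=0.01)

    def test_pixels_outside_circle_are_ignored(self, rng):
        d = np.full((64, 64), 0.5)
        d2 = d.copy()
        mask = s.circle_mask((64, 64), (32, 32), 20.0)
        d2[~mask] = rng.uniform(0, 10, (~mask).sum())
        assert s.mean_dab_od([d], (32, 32), 20.0) == s.mean_dab_od([d2], (32, 32), 20.0)

    def test_out_of_bounds_circle_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            s.mean_dab_od([np.zeros((32, 32))], (2, 2), 20.0)

    def test_needs_at_least_one_section(self):
        with pytest.raises(ValueError):
            s.mean_dab_od([], (2, 2), 2.0)


class TestVacuolation:
    def test_no_vacuoles_scores_zero(self):
        spec = s.HistologySpec(image_shape=(64, 64), hematoxylin_density=0.6)
        image, _ = s.generate_histology_image(spec)
        roi = np.ones((64, 64), bool)
        score = s.score_vacuolation(image, roi, binarization=200.0)
        assert score.total_vacuolation == 0.0

    def test_total_equals_brute_force_pixel_count(self):
        spec = s.HistologySpec(
            image_shape=(96, 96),
            hematoxylin_density=0.6,
            vacuoles=(
                s.EllipseSpec(center=(30, 30), axes=(8, 5), angle=0.2),
                s.EllipseSpec(center=(64, 60), axes=(6, 6)),
            ),
        )
        image, truth = s.generate_histology_image(spec)
        roi = s.circle_mask((96, 96), (48, 48), 80.0)
        score = s.score_vacuolation(image, roi, binarization="otsu")
        binary = image.mean(axis=-1) > score.threshold
        expected = vacuole_pixel_count_brute(binary, roi)
        assert score.total_vacuolation == expected
        assert score.mean_binary == expected / roi.sum()
        # clean synthetic image: binarization recovers exactly the true mask
        assert expected == truth.vacuole_mask[roi].sum()

    def test_roi_inside_one_vacuole_is_saturated(self):
        spec = s.HistologySpec(
            image_shape=(64, 64), hematoxylin_density=0.6,
            vacuoles=(s.EllipseSpec(center=(32, 32), axes=(20, 20)),),
        )
        image, _ = s.generate_histology_image(spec)
        roi = s.circle_mask((64, 64), (32, 32), 16.0)
        score = s.score_vacuolation(image, roi, binarization="otsu")
        assert score.mean_binary == 1.0
        assert score.total_vacuolation == score.roi_area

    def test_degenerate_image_falls_back_with_warning(self):
        image = np.full((16, 16), 100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            score = s.score_vacuolation(image, np.ones((16, 16), bool))
        assert score.total_vacuolation == 0.0

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            s.score_vacuolation(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_rolling_ball_background_subtraction_keeps_vacuoles(self):
        # smooth uneven illumination must not defeat the bright-hole rule
        spec = s.HistologySpec(
            image_shape=(96, 96), hematoxylin_density=0.7,
            vacuoles=(s.EllipseSpec(center=(48, 48), axes=(8, 8)),),
        )
        image, truth = s.generate_histology_image(spec)
        gradient = np.linspace(0, 30, 96)[None, :, None]
        roi = np.ones((96, 96), bool)
        score = s.score_vacuolation(
            image + gradient, roi, binarization="otsu", rolling_ball_radius=25
        )
        assert score.total_vacuolation == truth.vacuole_mask.sum()
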