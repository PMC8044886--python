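"""Stain separation and reference-based normalization."""

import numpy as np
import pytest

import patchvote as pv
from patchvote.stain import (concentration_percentiles, optical_density_to_rgb,
                             rgb_to_optical_density, tissue_mask_from_od)


def vec_angle(a, b):
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1.0, 1.0)))


class TestOpticalDensity:
    def test_background_pixel_has_zero_density(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(rgb_to_optical_density(img, 256.0) == 0.0)

    def test_black_pixel_density_matches_hand_formula(self):
        od = rgb_to_optical_density(np.zeros((1, 1, 3), dtype=np.uint8), 256.0)
        assert od[0, 0, 0] == pytest.approx(-np.log10(1.0 / 256.0), abs=1e-12)

    def test_round_trip_within_one_level(self, rng):
        img = rng.integers(0, 256, size=(10, 10, 3)).astype(np.uint8)
        back = optical_density_to_rgb(rgb_to_optical_density(img))
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 1

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_background_rejected(self, bad):
        with pytest.raises(pv.InvalidParameterError):
            rgb_to_optical_density(np.zeros((2, 2, 3)), bad)
        with pytest.raises(pv.InvalidParameterError):
            optical_density_to_rgb(np.zeros((2, 2, 3)), bad)


class TestBasisEstimation:
    def test_recovers_known_vectors_within_two_degrees(self, known_basis_od):
        od, _, _ = known_basis_od
        basis = pv.estimate_stain_basis(od)
        assert vec_angle(basis.h_vector, pv.CANONICAL_HEMATOXYLIN) < 2.0
        assert vec_angle(basis.e_vector, pv.CANONICAL_EOSIN) < 2.0

    def test_hematoxylin_assignment_by_blue_component(self, known_basis_od):
        basis = pv.estimate_stain_basis(known_basis_od[0])
        assert basis.h_vector[2] >= basis.e_vector[2]

    def test_single_stain_is_degenerate(self, rng):
        h = rng.uniform(0.2, 2.0, (50, 50))
        od = h[..., None] * pv.CANONICAL_HEMATOXYLIN
        with pytest.raises(pv.DegenerateInputError):
            pv.estimate_stain_basis(od)

    def test_too_few_tissue_pixels_is_degenerate(self):
        od = np.zeros((5, 5, 3))
        with pytest.raises(pv.DegenerateInputError):
            pv.estimate_stain_basis(od)

    def test_pixel_order_invariance(self, known_basis_od, rng):
        od = known_basis_od[0].reshape(-1, 3)
        shuffled = od[rng.permutation(len(od))]
        b1 = pv.estimate_stain_basis(od)
        b2 = pv.estimate_stain_basis(shuffled)
        np.testing.assert_allclose(b1.h_vector, b2.h_vector, atol=1e-9)
        np.testing.assert_allclose(b1.e_vector, b2.e_vector, atol=1e-9)

    def test_basis_invariants(self, known_basis_od):
        basis = pv.estimate_stain_basis(known_basis_od[0])
        assert np.linalg.norm(basis.h_vector) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(basis.e_vector) == pytest.approx(1.0, abs=1e-9)
        assert vec_angle(basis.h_vector, basis.e_vector) > 1.0


class TestConcentrations:
    def test_exact_synthetic_mixture(self):
        basis = pv.StainBasis(pv.CANONICAL_HEMATOXYLIN, pv.CANONICAL_EOSIN)
        od = np.broadcast_to(2.0 * basis.h_vector + 0.5 * basis.e_vector,
                             (6, 7, 3))
        h_map, e_map = pv.compute_concentrations(od, basis)
        np.testing.assert_allclose(h_map, 2.0, atol=1e-6)
        np.testing.assert_allclose(e_map, 0.5, atol=1e-6)

    def test_zero_od_gives_zero_maps(self):
        basis = pv.StainBasis(pv.CANONICAL_HEMATOXYLIN, pv.CANONICAL_EOSIN)
        h_map, e_map = pv.compute_concentrations(np.zeros((4, 4, 3)), basis)
        assert not h_map.any() and not e_map.any()

    def test_projection_matches_lstsq_oracle(self, rng):
        basis = pv.StainBasis(pv.CANONICAL_HEMATOXYLIN, pv.CANONICAL_EOSIN)
        od = rng.uniform(0, 1.5, (50, 3))
        h_map, e_map = pv.compute_concentrations(od.reshape(5, 10, 3), basis)
        coef, *_ = np.linalg.lstsq(basis.matrix, od.T, rcond=None)
        np.testing.assert_allclose(h_map.ravel(), np.clip(coef[0], 0, None),
                                   atol=1e-9)
        np.testing.assert_allclose(e_map.ravel(), np.clip(coef[1], 0, None),
                                   atol=1e-9)

    def test_negative_solutions_clipped(self):
        basis = pv.StainBasis(pv.CANONICAL_HEMATOXYLIN, pv.CANONICAL_EOSIN)
        # od orthogonal-ish to the stain plane induces a negative coefficient
        od = np.array([[[0.9, 0.0, 0.0]]])
        h_map, e_map = pv.compute_concentrations(od, basis)
        assert h_map.min() >= 0 and e_map.min() >= 0


class TestPercentileMapping:
    def _profile(self, image):
        return pv.compute_reference_profile(image)

    def test_identity_mapping(self, seg_image):
        profile = self._profile(seg_image.image)
        od = rgb_to_optical_density(seg_image.image)
        h_map, e_map = pv.compute_concentrations(od, profile.basis)
        tissue = tissue_mask_from_od(od)
        h2, e2 = pv.map_to_reference(h_map, e_map, profile, profile, tissue)
        np.testing.assert_allclose(h2[tissue], h_map[tissue], atol=1e-9)

    def test_mapped_percentiles_match_target(self):
        specs = pv.rct_class_specs()
        src = pv.render_image(specs["MCT"], dims=(480, 640), seed=3).image
        ref = pv.render_image(specs["PLA"], dims=(480, 640), seed=4).image
        target = self._profile(ref)
        out = pv.normalize_image(src, target)
        od = rgb_to_optical_density(out)
        h_map, _ = pv.compute_concentrations(od, target.basis)
        tissue = tissue_mask_from_od(od)
        for q in (10.0, 50.0, 90.0):
            got = np.percentile(h_map[tissue], q)
            want = np.interp(q, target.percentile_grid, target.h_percentiles)
            assert got == pytest.approx(want, abs=max(0.02 * want, 0.02))

    def test_mapping_is_monotone(self, seg_image, rng):
        src_prof = self._profile(seg_image.image)
        other = pv.render_image(pv.rct_class_specs()["LYM"],
                                dims=(320, 320), seed=9).image
        tgt_prof = self._profile(other)
        values = np.sort(rng.uniform(0, 2.5, 300)).reshape(10, 30)
        mapped, _ = pv.map_to_reference(values, values * 0.5, src_prof,
                                        tgt_prof, np.ones_like(values, bool))
        flat = mapped.ravel()
        assert np.all(np.diff(flat) >= -1e-12)

    def test_empty_tissue_mask_rejected(self, seg_image):
        profile = self._profile(seg_image.image)
        with pytest.raises(pv.DegenerateInputError):
            pv.map_to_reference(np.ones((4, 4)), np.ones((4, 4)), profile,
                                profile, np.zeros((4, 4), bool))


class TestNormalizeImage:
    def test_self_normalization_near_identity(self, seg_image):
        profile = pv.compute_reference_profile(seg_image.image)
        out = pv.normalize_image(seg_image.image, profile)
        mad = np.abs(out.astype(float) - seg_image.image.astype(float)).mean()
        assert mad <= 3.0
        assert out.shape == seg_image.image.shape

    def test_white_image_untouched(self, seg_image):
        profile = pv.compute_reference_profile(seg_image.image)
        white = np.full((100, 80, 3), 255, dtype=np.uint8)
        np.testing.assert_array_equal(pv.normalize_image(white, profile), white)

    def test_near_idempotence(self, seg_image):
        profile = pv.compute_reference_profile(seg_image.image)
        once = pv.normalize_image(seg_image.image, profile)
        twice = pv.normalize_image(once, profile)
        assert np.abs(twice.astype(float) - once.astype(float)).mean() <= 2.0

    def test_scaled_stain_pair_converges(self, seg_image):
        profile = pv.compute_reference_profile(seg_image.image)
        img = pv.render_image(pv.rct_class_specs()["MCT"],
                              dims=(480, 640), seed=5).image
        od = rgb_to_optical_density(img)
        scaled = optical_density_to_rgb(od * 1.3)
        n1 = pv.normalize_image(img, profile).astype(float)
        n2 = pv.normalize_image(scaled, profile).astype(float)
        assert np.abs(n1 - n2).mean() <= 3.0


class TestReferenceProfile:
    def test_json_round_trip_bit_exact(self, seg_image, tmp_path):
        profile = pv.compute_reference_profile(seg_image.image)
        path = tmp_path / "profile.json"
        profile.to_json(path)
        back = pv.ReferenceProfile.from_json(path)
        np.testing.assert_array_equal(back.h_percentiles, profile.h_percentiles)
        np.testing.assert_array_equal(back.e_percentiles, profile.e_percentiles)
        np.testing.assert_array_equal(back.basis.h_vector, profile.basis.h_vector)
        assert back.od_threshold == profile.od_threshold

    def test_percentiles_non_decreasing(self, seg_image):
        profile = pv.compute_reference_profile(seg_image.image)
        assert np.all(np.diff(profile.h_percentiles) >= 0)
        assert np.all(np.diff(profile.e_percentiles) >= 0)


class TestStainNormalizerEstimator:
    def test_transform_list_and_single(self, seg_image):
        norm = pv.StainNormalizer().fit(seg_image.image)
        single = norm.transform(seg_image.image)
        listed = norm.transform([seg_image.image])
        np.testing.assert_array_equal(single, listed[0])

    def test_unfitted_raises(self, seg_image):
        with pytest.raises(pv.InvalidParameterError):
            pv.StainNormalizer().transform(seg_image.image)

    def test_get_params_round_trip(self):
        norm = pv.StainNormalizer(od_threshold=0.2)
        clone = pv.StainNormalizer(**norm.get_params())
        assert clone.od_threshold == 0.2
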