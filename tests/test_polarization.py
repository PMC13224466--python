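"""AQP4 polarization pipeline: each stage against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from glymphoquant.polarization import (
    DualChannelImage,
    PolarizationConfig,
    RegionMasks,
    build_perivascular_rois,
    mean_perivascular_intensity,
    polarization_index,
    quantify_batch,
    quantify_image,
    regional_intensity,
    segment_vessels,
    subtract_background,
)
from glymphoquant.simulate import ImageSimParams, simulate_if_image

from conftest import brute_force_index


class TestSubtractBackground:
    def test_zero_plane_unchanged(self):
        plane = np.zeros((8, 8))
        assert np.array_equal(subtract_background(plane), plane)

    def test_constant_plane_becomes_zero(self):
        assert (subtract_background(np.full((8, 8), 123.0)) == 0).all()

    def test_known_offset_removed(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 200, (64, 64))
        base[:2] = 0.0  # guarantee a true zero-background floor
        offset = 37.0
        corrected = subtract_background(base + offset)
        assert abs(corrected.min()) <= 1.0
        assert np.allclose(corrected, np.clip(base + offset - np.percentile(base + offset, 1), 0, None))

    def test_idempotent_once_background_is_zero(self):
        plane = np.zeros((16, 16))
        plane[8, 8] = 50.0
        once = subtract_background(plane)
        assert np.array_equal(subtract_background(once), once)

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.empty((0, 0)))

    def test_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((4, 4)), percentile=60)


class TestSegmentVessels:
    def test_blank_plane_fixed_threshold_empty(self):
        mask = segment_vessels(np.zeros((32, 32)), min_area_px=1, threshold=10.0)
        assert not mask.any()

    def test_recovers_simulated_disks(self, noiseless_image_factory):
        image, truth = noiseless_image_factory(n_vessels=5)
        mask = segment_vessels(image.cd31, min_area_px=20)
        from skimage.measure import label

        assert label(mask).max() == 5
        iou = (mask & truth.vessel_mask).sum() / (mask | truth.vessel_mask).sum()
        assert iou >= 0.95

    def test_min_area_filters_everything(self, noiseless_image_factory):
        image, _ = noiseless_image_factory(n_vessels=3)
        mask = segment_vessels(image.cd31, min_area_px=10_000)
        assert not mask.any()

    def test_constant_plane_otsu_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_vessels(np.full((16, 16), 5.0))


class TestPerivascularRois:
    def test_ring_area_close_to_annulus(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = np.mgrid[0:64, 0:64]
        r, w = 8, 3
        mask |= (rr - 32) ** 2 + (cc - 32) ** 2 <= r**2
        ring = build_perivascular_rois(mask, ring_width_px=w)
        expected = np.pi * ((r + w) ** 2 - r**2)
        assert ring.sum() == pytest.approx(expected, rel=0.15)

    def test_empty_mask_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            ring = build_perivascular_rois(np.zeros((8, 8), dtype=bool))
        assert not ring.any()

    def test_touching_rings_merge_without_double_counting(self):
        mask = np.zeros((40, 80), dtype=bool)
        rr, cc = np.mgrid[0:40, 0:80]
        left = (rr - 20) ** 2 + (cc - 30) ** 2 <= 36
        right = (rr - 20) ** 2 + (cc - 44) ** 2 <= 36
        joint = build_perivascular_rois(left | right, 4)
        separate = build_perivascular_rois(left, 4).sum() + build_perivascular_rois(right, 4).sum()
        assert joint.sum() < separate

    def test_ring_never_intersects_vessel(self, noiseless_image_factory):
        image, truth = noiseless_image_factory()
        vessels = segment_vessels(image.cd31, min_area_px=20)
        ring = build_perivascular_rois(vessels, 3)
        assert not (ring & vessels).any()

    def test_ring_width_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_perivascular_rois(np.ones((4, 4), dtype=bool), 0)


class TestMeanPerivascularIntensity:
    def test_uniform_ring(self):
        plane = np.full((10, 10), 300.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True
        assert mean_perivascular_intensity(plane, mask) == 300.0

    def test_single_pixel_mask(self):
        plane = np.arange(16.0).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 3] = True
        assert mean_perivascular_intensity(plane, mask) == 11.0

    def test_enrichment_times_parenchyma(self, noiseless_image_factory):
        image, truth = noiseless_image_factory(enrichment=2.5)
        m_pv = mean_perivascular_intensity(image.aqp4, truth.perivascular_mask)
        assert m_pv == pytest.approx(2.5 * 60.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_perivascular_intensity(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestPolarizationIndex:
    def test_uniform_plane_at_mean_is_zero(self):
        # strict inequality: pixels equal to the mean do not count
        assert polarization_index(np.full((8, 8), 42.0), 42.0) == 0.0

    def test_all_below_is_hundred(self):
        assert polarization_index(np.zeros((8, 8)), 1.0) == 100.0

    def test_hand_built_4x4_fixture(self):
        plane = np.full((4, 4), 10.0)
        plane.flat[:5] = 1.0  # exactly 5 of 16 pixels below the mean
        assert polarization_index(plane, 5.0) == pytest.approx(31.25)

    def test_empty_analysis_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            polarization_index(np.ones((4, 4)), 1.0, np.zeros((4, 4), dtype=bool))

    @settings(derandomize=True, max_examples=100)
    @given(
        plane=npst.arrays(
            np.float64,
            npst.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=32),
            elements=st.floats(0, 1000),
        ),
        m_pv=st.floats(0, 1000),
    )
    def test_oracle_equality_and_bounds(self, plane, m_pv):
        """Vectorized index agrees exactly with a per-pixel loop counter."""
        index = polarization_index(plane, m_pv)
        assert index == brute_force_index(plane, m_pv)
        assert 0.0 <= index <= 100.0

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.25, 4.0),
        b=st.floats(0.0, 500.0),
    )
    def test_affine_invariance(self, seed, a, b):
        """The index is unchanged under I -> aI + b applied jointly with M_pv."""
        rng = np.random.default_rng(seed)
        plane = rng.integers(0, 256, (24, 24)).astype(float)
        m_pv = float(rng.integers(1, 256)) - 0.5
        assert polarization_index(a * plane + b, a * m_pv + b) == polarization_index(
            plane, m_pv
        )


class TestQuantifyImage:
    @pytest.mark.parametrize("enrichment", [1.0, 1.5, 2.0, 3.0, 4.0])
    def test_noiseless_matches_ground_truth(self, noiseless_image_factory, enrichment):
        image, truth = noiseless_image_factory(enrichment=enrichment)
        result = quantify_image(image)
        assert result.valid
        assert result.polarization_index == pytest.approx(
            truth.true_polarization_index, abs=1e-6
        )

    def test_monotone_in_enrichment(self, noiseless_image_factory):
        indices = [
            quantify_image(noiseless_image_factory(enrichment=e)[0]).polarization_index
            for e in (1.0, 2.0, 4.0)
        ]
        assert indices[0] == 0.0
        assert indices[0] <= indices[1] <= indices[2]

    def test_same_image_twice_in_batch_identical(self, noiseless_image_factory):
        image, _ = noiseless_image_factory()
        config = PolarizationConfig(global_threshold="otsu")
        r1, r2 = quantify_batch([image, image], config)
        assert r1 == r2
        assert r1.global_threshold == r2.global_threshold

    def test_absent_vessels_flagged_invalid(self):
        blank = DualChannelImage(aqp4=np.full((32, 32), 50.0), cd31=np.zeros((32, 32)))
        config = PolarizationConfig(vessel_threshold=10.0)
        result = quantify_image(blank, config)
        assert not result.valid
        assert np.isnan(result.polarization_index)
        assert result.n_vessels == 0

    def test_user_supplied_masks_bypass_segmentation(self, noiseless_image_factory):
        image, truth = noiseless_image_factory()
        masks = RegionMasks(truth.vessel_mask, truth.perivascular_mask)
        auto = quantify_image(image)
        manual = quantify_image(image, masks=masks)
        assert manual.polarization_index == pytest.approx(
            auto.polarization_index, abs=1e-6
        )

    def test_noisy_image_index_tracks_truth(self):
        image, truth = simulate_if_image(
            ImageSimParams(perivascular_enrichment=3.0, noise_sd=5.0, seed=21)
        )
        result = quantify_image(image)
        assert result.valid
        assert result.polarization_index == pytest.approx(
            truth.true_polarization_index, abs=5.0
        )


class TestRegionalIntensity:
    def test_uniform_plane(self):
        plane = np.full((10, 10), 7.0)
        regions = {"dorsal": np.zeros((10, 10), dtype=bool)}
        regions["dorsal"][:5] = True
        assert regional_intensity(plane, regions) == {"dorsal": 7.0}

    def test_planted_regional_means(self):
        plane = np.zeros((30, 10))
        plane[:10] = 50.0
        plane[10:20] = 100.0
        plane[20:] = 150.0
        masks = {
            "dorsal_horn": np.zeros((30, 10), dtype=bool),
            "central_canal": np.zeros((30, 10), dtype=bool),
            "ventral_horn": np.zeros((30, 10), dtype=bool),
        }
        masks["dorsal_horn"][:10] = True
        masks["central_canal"][10:20] = True
        masks["ventral_horn"][20:] = True
        means = regional_intensity(plane, masks)
        assert means == {"dorsal_horn": 50.0, "central_canal": 100.0, "ventral_horn": 150.0}

    def test_empty_region_omitted(self):
        plane = np.ones((8, 8))
        full = np.ones((8, 8), dtype=bool)
        means = regional_intensity(plane, {"a": full, "b": np.zeros((8, 8), dtype=bool)})
        assert means == {"a": 1.0}


def test_region_masks_reject_overlap():
    m = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError, match="intersect"):
        RegionMasks(vessel_mask=m, perivascular_mask=m)
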