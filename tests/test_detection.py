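"""Haar blob features, particle probability image, and seed extraction."""

import numpy as np
import pytest
from scipy import ndimage

from ulm2d.detection import (DetectionParams, calibrate_noise_threshold,
                             detect_seeds, estimate_noise_level, haar_kernel,
                             haar_feature_image, particle_probability_image,
                             significance_threshold)
from ulm2d.simulate.echoes import EchoAppearance, sample_echo_appearance
from ulm2d.simulate.particles import GroundTruthRecord
from ulm2d.simulate.render import render_frame

PITCH = 132.0


def _echo_frame(xy, apps, shape=(30, 30), noise=0.0, seed=0):
    xy = np.asarray(xy, float)
    gt = GroundTruthRecord(0, np.arange(len(xy)), xy, np.arange(len(xy)))
    return render_frame(gt, dict(enumerate(apps)), shape, PITCH, noise,
                        rng=seed)


class TestHaar:
    def test_kernels_are_zero_mean_unit_positive_mass(self):
        for s in (1.6, 2.0, 2.5):
            k = haar_kernel(s)
            assert k.sum() == pytest.approx(0.0, abs=1e-12)
            assert k[k > 0].sum() == pytest.approx(1.0)

    def test_flat_frame_gives_identically_zero_feature(self):
        feat = haar_feature_image(np.full((20, 20), 37.0))
        np.testing.assert_allclose(feat.values, 0.0, atol=1e-9)

    def test_single_echo_feature_maximum_at_echo_peak(self):
        app = EchoAppearance(300.0, 220.0, 0.3, 120.0)
        frame = _echo_frame([[1500.0, 1700.0]], [app])
        feat = haar_feature_image(frame)
        fr, fc = np.unravel_index(np.argmax(feat.values), frame.shape)
        er, ec = np.unravel_index(np.argmax(frame), frame.shape)
        assert abs(fr - er) <= 1 and abs(fc - ec) <= 1
        assert feat.values.max() == pytest.approx(1.0)

    def test_large_echo_responds_maximally_at_largest_scale(self):
        # footprint ~20 px -> the scale tuned to the Q3 area wins
        area = 20.0
        sigma = PITCH * np.sqrt(area / (2 * np.pi * np.log(2)))
        app = EchoAppearance(sigma, sigma, 0.0, 100.0)
        frame = _echo_frame([[1980.0, 1980.0]], [app])
        center = (int(1980 // PITCH), int(1980 // PITCH))
        responses = [ndimage.convolve(frame, haar_kernel(s), mode="reflect")[center]
                     for s in (1.6, 2.0, 2.5)]
        assert int(np.argmax(responses)) == 2

    def test_oversized_scale_rejected(self):
        with pytest.raises(ValueError):
            haar_feature_image(np.zeros((6, 6)), haar_scales=(5.0,))


class TestNoiseCalibration:
    def test_estimated_sigma_recovers_clipped_gaussian(self):
        rng = np.random.default_rng(2)
        frames = [np.clip(rng.normal(0, 20.0, (64, 64)), 0, None)
                  for _ in range(6)]
        est = estimate_noise_level(frames)
        assert est == pytest.approx(20.0, rel=0.1)

    def test_calibrated_threshold_hits_nominal_tail_probability(self):
        alpha = 1e-3
        thr = calibrate_noise_threshold((96, 96), 15.0, alpha=alpha,
                                        n_frames=12, seed=3)
        rng = np.random.default_rng(99)
        frac = []
        for _ in range(10):
            f = np.clip(rng.normal(0, 15.0, (96, 96)), 0, None)
            feat = haar_feature_image(f)
            frac.append((feat.raw > thr).mean())
        assert np.mean(frac) <= alpha * 1.5
        assert np.mean(frac) >= alpha * 0.5


class TestPPI:
    def test_bright_compact_echo_has_dense_core(self):
        app = EchoAppearance(300.0, 250.0, 0.0, 150.0)
        frame = _echo_frame([[1980.0, 1980.0]], [app])
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, noise_threshold=5.0)
        center = (int(1980 // PITCH), int(1980 // PITCH))
        assert ppi[center] >= 0.5
        assert ppi.max() <= 1.0 and ppi.min() >= 0.0

    def test_ppi_zero_outside_significant_components(self):
        app = EchoAppearance(300.0, 250.0, 0.0, 150.0)
        frame = _echo_frame([[1980.0, 1980.0]], [app])
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, noise_threshold=5.0)
        assert ppi[feat.raw <= 5.0].max() == 0.0

    def test_artifact_mask_suppresses_ppi(self):
        app = EchoAppearance(300.0, 250.0, 0.0, 150.0)
        frame = _echo_frame([[1000.0, 1000.0], [3000.0, 3000.0]], [app, app])
        feat = haar_feature_image(frame)
        mask = np.zeros(frame.shape, bool)
        mask[:, :15] = True        # covers the first echo
        ppi = particle_probability_image(frame, feat, 5.0, mask=mask)
        assert ppi[mask].max() == 0.0
        assert ppi[~mask].max() > 0.5


class TestSeeds:
    def test_two_separated_echoes_give_two_seeds(self):
        app = EchoAppearance(280.0, 220.0, 0.2, 140.0)
        frame = _echo_frame([[800.0, 800.0], [3100.0, 3100.0]], [app, app])
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, 5.0)
        seeds, regions = detect_seeds(frame, ppi, DetectionParams())
        assert len(seeds) == 2

    def _merged_pair_frame(self):
        # two echoes 330 um apart: below the 385-um merge threshold, minor
        # axis along the separation so a fine-smoothed pass can resolve them
        app = EchoAppearance(180.0, 141.0, np.pi / 2, 140.0)
        return _echo_frame([[1980.0, 1980.0], [2310.0, 1980.0]], [app, app],
                           noise=8.0, seed=0)

    def test_merged_pair_single_seed_with_wide_smoothing(self):
        frame = self._merged_pair_frame()
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, 20.0)
        merged = DetectionParams.for_mode("merged")
        seeds, _ = detect_seeds(frame, ppi, merged)
        assert len(seeds) == 1

    def test_merged_pair_splits_with_small_smoothing(self):
        frame = self._merged_pair_frame()
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, 20.0)
        fine = DetectionParams(gaussian_sigma=0.5, local_maxima_width=3)
        seeds, _ = detect_seeds(frame, ppi, fine)
        assert len(seeds) >= 2

    def test_raising_noise_threshold_never_adds_seeds(self):
        rng = np.random.default_rng(6)
        apps = [sample_echo_appearance(rng) for _ in range(6)]
        xy = rng.uniform(500, 3500, size=(6, 2))
        frame = _echo_frame(xy, apps, noise=15.0, seed=7)
        feat = haar_feature_image(frame)
        params = DetectionParams()
        counts = []
        for thr in [5.0, 10.0, 20.0, 40.0, 80.0]:
            ppi = particle_probability_image(frame, feat, thr)
            seeds, _ = detect_seeds(frame, ppi, params)
            counts.append(len(seeds))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_every_seed_lies_inside_a_region(self):
        rng = np.random.default_rng(8)
        apps = [sample_echo_appearance(rng) for _ in range(5)]
        xy = rng.uniform(500, 3500, size=(5, 2))
        frame = _echo_frame(xy, apps, noise=15.0, seed=9)
        feat = haar_feature_image(frame)
        ppi = particle_probability_image(frame, feat, 15.0)
        seeds, regions = detect_seeds(frame, ppi, DetectionParams())
        for r, c in seeds:
            assert regions[r, c] > 0

    def test_isolated_echoes_yield_exactly_one_seed_each(self):
        rng = np.random.default_rng(10)
        params = DetectionParams()
        misses = 0
        for _ in range(500):
            app = sample_echo_appearance(rng)
            off = tuple(rng.uniform(-PITCH / 2, PITCH / 2, 2))
            frame = _echo_frame([[1980.0 + off[0], 1980.0 + off[1]]], [app])
            feat = haar_feature_image(frame)
            ppi = particle_probability_image(frame, feat, 5.0)
            seeds, _ = detect_seeds(frame, ppi, params)
            if len(seeds) != 1:
                misses += 1
        assert misses == 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DetectionParams(min_echo_area_px=0)
    with pytest.raises(ValueError):
        DetectionParams(max_echo_area_px=4)
    with pytest.raises(ValueError):
        DetectionParams(region_threshold=1.5)
    with pytest.raises(ValueError):
        DetectionParams(local_maxima_width=4)
    with pytest.raises(ValueError):
        DetectionParams(haar_scales=())


def test_significance_threshold_scales_with_noise():
    p = DetectionParams()
    k = (0.3, 0.4)
    assert significance_threshold(20.0, p, k) == pytest.approx(
        2 * significance_threshold(10.0, p, k))
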