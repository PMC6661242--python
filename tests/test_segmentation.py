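"""Watershed segmentation, size/intensity filtering, and localization."""

import numpy as np
import pytest

from ulm2d.detection import DetectionParams
from ulm2d.segmentation import (DegenerateEventError, filter_regions,
                                localize, process_frame, watershed_segment)
from ulm2d.simulate.echoes import EchoAppearance, sample_echo_appearance
from ulm2d.simulate.particles import GroundTruthRecord
from ulm2d.simulate.render import render_frame

PITCH = 132.0


def _render(xy, apps, shape=(30, 30), noise=0.0, seed=0):
    xy = np.asarray(xy, float)
    gt = GroundTruthRecord(0, np.arange(len(xy)), xy, np.arange(len(xy)))
    return render_frame(gt, dict(enumerate(apps)), shape, PITCH, noise,
                        rng=seed)


def _half_max_regions(frame):
    return (frame >= 0.5 * frame.max()).astype(int)


class TestWatershed:
    def test_inverted_gaussian_recovers_above_floor_footprint(self):
        # an isolated echo whose above-floor footprint is 12 px
        sigma = PITCH * np.sqrt(12.0 / (2 * np.pi * np.log(2) * 1.5))
        app = EchoAppearance(1.5 * sigma, sigma, 0.3, 150.0)
        frame = _render([[1980.0, 1980.0]], [app])
        regions = _half_max_regions(frame)
        seed = [tuple(np.unravel_index(np.argmax(frame), frame.shape))]
        labels = watershed_segment(frame, seed, "inverted_gaussian", 1.0,
                                   initial_regions=regions)
        area = int((labels == 1).sum())
        assert abs(area - 12) <= 2

    def test_gradient_relief_shrinks_the_segmented_area(self):
        # the detection floor sits well below half maximum here, so the
        # initial region covers the echo flanks; the gradient watershed
        # line forms on the maximum-slope ring inside it
        sigma = PITCH * np.sqrt(12.0 / (2 * np.pi * np.log(2) * 1.5))
        app = EchoAppearance(1.5 * sigma, sigma, 0.3, 150.0)
        frame = _render([[1980.0, 1980.0]], [app])
        regions = (frame >= 0.2 * frame.max()).astype(int)
        seed = [tuple(np.unravel_index(np.argmax(frame), frame.shape))]
        a_ig = (watershed_segment(frame, seed, "inverted_gaussian", 1.0,
                                  regions) == 1).sum()
        a_gr = (watershed_segment(frame, seed, "gradient", 1.0,
                                  regions) == 1).sum()
        assert a_gr < a_ig

    def test_two_seeds_partition_a_merged_blob(self):
        app = EchoAppearance(300.0, 240.0, 0.0, 120.0)
        frame = _render([[1700.0, 1980.0], [2300.0, 1980.0]], [app, app])
        regions = (frame >= 0.3 * frame.max()).astype(int)
        seeds = [(15, int(1700 // PITCH)), (15, int(2300 // PITCH))]
        labels = watershed_segment(frame, seeds, "inverted_gaussian", 1.0,
                                   regions)
        r1 = labels == 1
        r2 = labels == 2
        assert r1.any() and r2.any()
        assert not (r1 & r2).any()
        assert r1[seeds[0]] and r2[seeds[1]]

    def test_seed_outside_frame_is_contract_violation(self):
        with pytest.raises(ValueError):
            watershed_segment(np.zeros((10, 10)), [(12, 3)])

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            watershed_segment(np.zeros((10, 10)), [])


class TestFilterRegions:
    def _label_disc(self, shape, center, n_px, label, canvas, value):
        rr, cc = np.ogrid[:shape[0], :shape[1]]
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        order = np.argsort(d2.ravel())
        flat = canvas.ravel()
        flat[order[:n_px]] = label
        return value

    def test_size_and_intensity_gates(self):
        labels = np.zeros((40, 40), int)
        frame = np.zeros((40, 40))
        specs = [(1, (8, 8), 4, 100.0),     # too small -> eliminated
                 (2, (8, 30), 12, 100.0),   # kept, single
                 (3, (30, 8), 12, 5.0),     # too dim  -> eliminated
                 (4, (30, 30), 40, 100.0)]  # over the single-size gate
        for lab, center, n_px, val in specs:
            rr, cc = np.ogrid[:40, :40]
            d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
            order = np.argsort(d2.ravel())
            sel = np.zeros(1600, bool)
            sel[order[:n_px]] = True
            labels.ravel()[sel] = lab
            frame.ravel()[sel] = val

        single = DetectionParams()                       # max area 20
        events = filter_regions(labels, frame, single)
        assert [e.area_px for e in events] == [12]
        assert events[0].kind == "single"

        merged = DetectionParams.for_mode("merged")      # large max area
        events = filter_regions(labels, frame, merged)
        assert sorted(e.area_px for e in events) == [12, 40]
        kinds = {e.area_px: e.kind for e in events}
        assert kinds[12] == "single" and kinds[40] == "merged"


class TestLocalize:
    def test_symmetric_echo_at_pixel_center_localizes_exactly(self):
        app = EchoAppearance(264.0, 264.0, 0.0, 100.0)
        x = (15 + 0.5) * PITCH
        frame = _render([[x, x]], [app], shape=(31, 31))
        px = np.column_stack(np.nonzero(frame > 1.0))
        cx, cy = localize(px, frame[px[:, 0], px[:, 1]], PITCH)
        assert cx == pytest.approx(x, abs=1e-9)
        assert cy == pytest.approx(x, abs=1e-9)

    def test_two_pixel_hand_computed_weighted_mean(self):
        px = np.array([[0, 0], [0, 1]])
        cx, cy = localize(px, np.array([1.0, 3.0]), PITCH)
        assert cx - 0.5 * PITCH == pytest.approx(0.75 * PITCH)  # 99 um
        assert cy == pytest.approx(0.5 * PITCH)

    def test_zero_intensity_is_degenerate(self):
        with pytest.raises(DegenerateEventError):
            localize(np.array([[0, 0]]), np.array([0.0]), PITCH)
        with pytest.raises(DegenerateEventError):
            localize(np.empty((0, 2)), np.empty(0), PITCH)

    def test_merged_pair_centroid_stays_near_vessel_axis(self):
        # two echoes 59 um apart straddling an axis: localized as one
        # event, the centroid is much closer to the axis than either
        # forced-split component would be
        axis_y = 1980.0
        app = EchoAppearance(280.0, 220.0, 0.0, 120.0)
        gt = [[1950.0, axis_y - 29.5], [2009.0, axis_y + 29.5]]
        frame = _render(gt, [app, app])
        params = DetectionParams.for_mode("merged")
        events = process_frame(frame, params, 10.0, pixel_pitch_um=PITCH)
        assert len(events) == 1
        assert abs(events[0].centroid_y_um - axis_y) < 30.0


class TestSubPixelAccuracy:
    def test_noiseless_rmse_below_a_fifth_of_a_pixel(self):
        rng = np.random.default_rng(12)
        params = DetectionParams(max_echo_area_px=400,
                                 mean_echo_intensity=5.0)
        errs = []
        for _ in range(200):
            app = sample_echo_appearance(rng)
            off = rng.uniform(-PITCH / 2, PITCH / 2, 2)
            x, y = 1980.0 + off[0], 1980.0 + off[1]
            frame = _render([[x, y]], [app])
            events = process_frame(frame, params, 5.0, pixel_pitch_um=PITCH)
            assert len(events) == 1
            e = events[0]
            errs.append((e.centroid_x_um - x) ** 2 + (e.centroid_y_um - y) ** 2)
        rmse = float(np.sqrt(np.mean(errs)))
        assert rmse < PITCH / 5

    def test_localization_translation_equivariance(self):
        app = EchoAppearance(310.0, 230.0, 0.6, 130.0)
        params = DetectionParams(max_echo_area_px=400)
        f0 = _render([[1831.4, 1718.9]], [app], shape=(40, 40))
        f1 = _render([[1831.4 + 3 * PITCH, 1718.9 + 5 * PITCH]], [app],
                     shape=(40, 40))
        e0 = process_frame(f0, params, 5.0, pixel_pitch_um=PITCH)[0]
        e1 = process_frame(f1, params, 5.0, pixel_pitch_um=PITCH)[0]
        assert e1.centroid_x_um - e0.centroid_x_um == pytest.approx(
            3 * PITCH, abs=1e-6)
        assert e1.centroid_y_um - e0.centroid_y_um == pytest.approx(
            5 * PITCH, abs=1e-6)
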