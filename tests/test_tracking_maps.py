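"""Nearest-neighbor linking, super-resolution maps, FWHM measurement."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ulm2d.mapping import (MeasurementError, SRMap, measure_fwhm,
                           render_density_map, render_velocity_map)
from ulm2d.segmentation import DetectionEvent
from ulm2d.tracking import Track, default_gate_um, link_tracks


def _event(frame, x, y, kind="single"):
    return DetectionEvent(frame, np.empty((0, 2), int), 10, 50.0, 80.0,
                          x, y, kind)


def _straight_track(n, x0, y0, dx, dy, t0=0):
    tr = Track(track_id=0)
    for k in range(n):
        tr.append(_event(t0 + k, x0 + k * dx, y0 + k * dy))
    return tr


class TestLinking:
    def test_single_mover_forms_one_full_track(self):
        events = [_event(t, 1000.0 + 132.0 * t, 2000.0) for t in range(10)]
        tracks = link_tracks(events, 500.0, 10.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        np.testing.assert_allclose(tracks[0].step_speeds_um_s(10.0), 1320.0)

    def test_parallel_movers_never_cross_over(self):
        events = []
        for t in range(8):
            events.append(_event(t, 1000.0 + 100.0 * t, 1000.0))
            events.append(_event(t, 1000.0 + 100.0 * t, 1500.0))
        tracks = link_tracks(events, 2000.0, 10.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {xy[1] for xy in tr.xy_um}
            assert len(ys) == 1

        # the mutual-nearest links coincide with the optimal assignment
        for t in range(7):
            prev = [e for e in events if e.frame_index == t]
            nxt = [e for e in events if e.frame_index == t + 1]
            d = np.array([[np.hypot(a.centroid_x_um - b.centroid_x_um,
                                    a.centroid_y_um - b.centroid_y_um)
                           for b in nxt] for a in prev])
            rows, cols = linear_sum_assignment(d)
            for i, j in zip(rows, cols):
                assert d[i, j] <= 2000.0
                assert prev[i].centroid_y_um == nxt[j].centroid_y_um

    def test_gate_fragments_fast_tracks(self):
        events = [_event(t, 1000.0 + 900.0 * t, 1000.0) for t in range(6)]
        tracks = link_tracks(events, 500.0, 10.0)
        assert len(tracks) == 6                  # all births, no links
        for tr in tracks:
            for v in tr.step_speeds_um_s(10.0):
                assert v <= 500.0 * 10.0

    def test_every_event_belongs_to_exactly_one_track(self):
        rng = np.random.default_rng(3)
        events = [_event(t, *rng.uniform(0, 5000, 2)) for t in range(5)
                  for _ in range(6)]
        tracks = link_tracks(events, 800.0, 10.0)
        assert sum(len(t) for t in tracks) == len(events)

    def test_merged_event_records_parent_links(self):
        events = [_event(0, 1000.0, 1000.0), _event(0, 1000.0, 1600.0),
                  _event(1, 1000.0, 1300.0, kind="merged")]
        tracks = link_tracks(events, 1000.0, 10.0)
        absorber = [t for t in tracks if len(t) == 2]
        assert len(absorber) == 1
        assert len(absorber[0].parent_ids) == 1

    def test_default_gate_covers_arterial_speed(self):
        assert default_gate_um(12.0) == pytest.approx(20000.0 / 12.0)


class TestMaps:
    def test_single_track_draws_unit_line(self):
        tr = _straight_track(5, 500.0, 1000.0, 500.0, 0.0)
        m = render_density_map([tr], (20, 25), 132.0, 3, 10.0)
        assert m.values.max() == 1
        row = int(1000.0 / 44.0 - 0.5 + 0.5)
        touched = np.nonzero(m.values)
        assert set(touched[0].tolist()) <= {row - 1, row, row + 1}

    def test_coincident_tracks_count_twice(self):
        t1 = _straight_track(5, 500.0, 1000.0, 500.0, 0.0)
        t2 = _straight_track(5, 500.0, 1000.0, 500.0, 0.0)
        t2.track_id = 1
        m = render_density_map([t1, t2], (20, 25), 132.0, 3, 10.0)
        assert m.values.max() == 2

    def test_density_mass_equals_traversed_subpixels(self):
        rng = np.random.default_rng(4)
        tracks = []
        for i in range(5):
            x0, y0 = rng.uniform(500, 1500, 2)
            tr = _straight_track(4, x0, y0, rng.uniform(100, 400),
                                 rng.uniform(-200, 200))
            tr.track_id = i
            tracks.append(tr)
        m = render_density_map(tracks, (20, 25), 132.0, 3, 10.0)
        total = 0
        for tr in tracks:
            single = render_density_map([tr], (20, 25), 132.0, 3, 10.0)
            total += int((single.values > 0).sum())
        assert int(m.values.sum()) == total

    def test_constant_speed_track_paints_its_speed(self):
        tr = _straight_track(5, 500.0, 1000.0, 100.0, 0.0)  # 1 mm/s at 10 Hz
        m = render_velocity_map([tr], (20, 25), 132.0, 3, 10.0)
        vals = m.values[m.values > 0]
        np.testing.assert_allclose(vals, 1000.0)

    def test_coincident_tracks_average_their_speeds(self):
        t1 = _straight_track(5, 500.0, 1000.0, 100.0, 0.0)   # 1 mm/s
        t2 = _straight_track(5, 500.0, 1000.0, 300.0, 0.0)   # 3 mm/s
        t2.track_id = 1
        m = render_velocity_map([t1, t2], (20, 25), 132.0, 3, 10.0)
        start = m.values[:, int(500 / 44):int(900 / 44)]
        vals = start[start > 0]
        assert vals.min() >= 1000.0 - 1e-6
        np.testing.assert_allclose(vals[vals > 1500], 2000.0)

    def test_velocity_support_equals_density_support(self):
        rng = np.random.default_rng(5)
        tracks = []
        for i in range(4):
            tr = _straight_track(4, *rng.uniform(500, 1500, 2),
                                 rng.uniform(100, 300), rng.uniform(-100, 100))
            tr.track_id = i
            tracks.append(tr)
        d = render_density_map(tracks, (20, 25), 132.0, 3, 10.0)
        v = render_velocity_map(tracks, (20, 25), 132.0, 3, 10.0)
        np.testing.assert_array_equal(d.values > 0, v.values > 0)


class TestFWHM:
    def test_single_subpixel_ridge_measures_one_subpixel(self):
        tr = _straight_track(5, 200.0, 1012.0, 500.0, 0.0)
        m = render_density_map([tr], (20, 25), 132.0, 3, 10.0)
        w = measure_fwhm(m, (1000.0, 500.0), (1000.0, 1500.0))
        assert w == pytest.approx(44.0, abs=22.0)

    def test_gaussian_ridge_fwhm_matches_closed_form(self):
        sigma_um = 150.0
        sub = 44.0
        rows = np.arange(120)
        vals = np.exp(-((rows - 60.0) * sub) ** 2 / (2 * sigma_um ** 2))
        m = SRMap(values=np.tile(vals[:, None], (1, 90)),
                  subpixel_pitch_um=sub, subdivision=3, kind="density")
        w = measure_fwhm(m, (1500.0, 500.0), (1500.0, 4800.0))
        assert w == pytest.approx(2.355 * sigma_um, rel=0.05)

    def test_vessel_fixture_fwhm_within_band(self):
        # straight vessel of diameter 236 um filled uniformly with tracks
        rng = np.random.default_rng(6)
        tracks = []
        for i in range(300):
            off = rng.uniform(-118.0, 118.0)
            tr = _straight_track(5, 200.0, 1500.0 + off, 600.0, 0.0)
            tr.track_id = i
            tracks.append(tr)
        m = render_density_map(tracks, (25, 25), 132.0, 3, 10.0)
        w = measure_fwhm(m, (1500.0, 800.0), (1500.0, 2200.0))
        assert w == pytest.approx(236.0, abs=30.0)
        # and a 300-um vessel lands in the in-vitro tube band
        tracks = []
        for i in range(300):
            off = rng.uniform(-150.0, 150.0)
            tr = _straight_track(5, 200.0, 1500.0 + off, 600.0, 0.0)
            tr.track_id = i
            tracks.append(tr)
        m = render_density_map(tracks, (25, 25), 132.0, 3, 10.0)
        w = measure_fwhm(m, (1500.0, 800.0), (1500.0, 2200.0))
        assert 200.0 <= w <= 320.0

    def test_zero_profile_raises(self):
        m = SRMap(values=np.zeros((30, 30)), subpixel_pitch_um=44.0,
                  subdivision=3, kind="density")
        with pytest.raises(MeasurementError):
            measure_fwhm(m, (100.0, 100.0), (100.0, 1200.0))


def test_network_velocity_map_matches_simulator_speed(solved_tube):
    """Perfect detections from ground truth -> the velocity map reads the
    simulator's segment mean velocity to within 15%."""
    from ulm2d.simulate.network import solve_flow
    from ulm2d.simulate.particles import advect_particles
    from tests.conftest import straight_tube

    net = solve_flow(straight_tube(radius_um=100.0, length_um=2500.0),
                     target_max_speed_um_s=3000.0)
    recs = advect_particles(net, 6, 2.0, 10.0, seed=8)
    # ideal tracker: chain each particle identity through the frames
    by_pid = {}
    for rec in recs:
        for pid, (x, y) in zip(rec.particle_ids, rec.xy_um):
            by_pid.setdefault(int(pid), []).append(
                _event(rec.frame_index, x, y))
    tracks = []
    for i, events in enumerate(by_pid.values()):
        tr = Track(track_id=i)
        for e in sorted(events, key=lambda e: e.frame_index):
            tr.append(e)
        tracks.append(tr)
    renderable = [t for t in tracks if len(t) >= 2]
    m = render_velocity_map(renderable, (12, 32), 132.0, 3, 10.0)
    vals = m.values[m.values > 0]
    assert np.median(vals) == pytest.approx(3000.0, rel=0.15)
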