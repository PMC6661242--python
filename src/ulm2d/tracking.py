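"""Frame-to-frame event linking by mutual nearest neighbors.

At the low frame rates of focused contrast imaging, consecutive echoes of
one microbubble do not overlap, so linking is association, not
correlation: two events in consecutive frames are linked when each is the
other's nearest neighbor within a distance gate.  Events that find no
partner start tracks (birth) or end them (death).  A merged-flagged event
may absorb several predecessors or emit several successors; those
relations are recorded as parent/child links between tracks while every
event keeps exactly one track identity.

The default gate is the distance the fastest expected blood (20 mm/s)
covers in one frame interval, so genuine links are never gated away at
the cited arterial speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import DetectionEvent

__all__ = ["Track", "link_tracks", "tracks_to_frame",
           "default_gate_um"]

#: Fastest blood speed the gate must accommodate, um/s.
MAX_BLOOD_SPEED_UM_S = 20000.0


def default_gate_um(frame_rate_hz: float) -> float:
    """Gate = expected maximum blood speed over one frame interval."""
    return MAX_BLOOD_SPEED_UM_S / frame_rate_hz


@dataclass
class Track:
    """Time-ordered chain of events with per-step speeds."""

    track_id: int
    frame_indices: list[int] = field(default_factory=list)
    xy_um: list[tuple[float, float]] = field(default_factory=list)
    events: list[DetectionEvent] = field(default_factory=list)
    parent_ids: list[int] = field(default_factory=list)   # merge sources
    child_ids: list[int] = field(default_factory=list)    # split products

    def append(self, event: DetectionEvent) -> None:
        if self.frame_indices and event.frame_index != self.frame_indices[-1] + 1:
            raise ValueError("track frames must increase by exactly 1")
        self.frame_indices.append(event.frame_index)
        self.xy_um.append(event.xy_um)
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.frame_indices)

    def step_speeds_um_s(self, frame_rate_hz: float) -> np.ndarray:
        xy = np.asarray(self.xy_um)
        if len(xy) < 2:
            return np.empty(0)
        steps = np.hypot(*np.diff(xy, axis=0).T)
        return steps * frame_rate_hz

    def mean_speed_um_s(self, frame_rate_hz: float) -> float:
        v = self.step_speeds_um_s(frame_rate_hz)
        return float(v.mean()) if len(v) else 0.0


def _mutual_nearest(prev_xy: np.ndarray, next_xy: np.ndarray,
                    gate_um: float) -> list[tuple[int, int]]:
    """Mutually-nearest pairs within the gate; ties broken by the earlier
    event index (KD-tree returns the smallest index among equidistant)."""
    if len(prev_xy) == 0 or len(next_xy) == 0:
        return []
    t_prev, t_next = cKDTree(prev_xy), cKDTree(next_xy)
    d_fwd, j_fwd = t_next.query(prev_xy, distance_upper_bound=gate_um)
    d_bwd, j_bwd = t_prev.query(next_xy, distance_upper_bound=gate_um)
    pairs = []
    for i, (d, j) in enumerate(zip(d_fwd, j_fwd)):
        if np.isfinite(d) and j < len(next_xy) and j_bwd[j] == i:
            pairs.append((i, int(j)))
    return pairs


def link_tracks(events: list[DetectionEvent],
                max_link_distance_um: float,
                frame_rate_hz: float) -> list[Track]:
    """Link localized events into tracks.

    ``events`` may be any order; they are grouped by frame internally.
    Returns all tracks, including single-point ones (map rendering
    excludes those downstream since they carry no displacement).
    """
    if max_link_distance_um <= 0:
        raise ValueError("max_link_distance_um must be positive")
    by_frame: dict[int, list[DetectionEvent]] = {}
    for e in events:
        by_frame.setdefault(e.frame_index, []).append(e)
    if not by_frame:
        return []

    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}       # index within current frame -> track

    frames = range(min(by_frame), max(by_frame) + 1)
    prev_events: list[DetectionEvent] = []
    for t in frames:
        cur = by_frame.get(t, [])
        cur_xy = np.array([e.xy_um for e in cur]) if cur else np.empty((0, 2))
        prev_xy = np.array([e.xy_um for e in prev_events]) if prev_events \
            else np.empty((0, 2))
        pairs = _mutual_nearest(prev_xy, cur_xy, max_link_distance_um)
        matched_prev = {i for i, _ in pairs}
        matched_cur = {j for _, j in pairs}

        new_open: dict[int, Track] = {}
        for i, j in pairs:
            tr = open_tracks[i]
            tr.append(cur[j])
            new_open[j] = tr

        # births
        for j, e in enumerate(cur):
            if j in matched_cur:
                continue
            tr = Track(track_id=len(tracks))
            tr.append(e)
            tracks.append(tr)
            new_open[j] = tr

        # merge/split annotations through merged-flagged events
        if prev_events and cur:
            tree_cur = cKDTree(cur_xy)
            for i, e in enumerate(prev_events):
                if i in matched_prev:
                    continue
                d, j = tree_cur.query(e.xy_um,
                                      distance_upper_bound=max_link_distance_um)
                if np.isfinite(d) and j < len(cur) and cur[j].kind == "merged":
                    absorber = new_open.get(int(j))
                    dying = open_tracks.get(i)
                    if absorber is not None and dying is not None \
                            and absorber is not dying:
                        absorber.parent_ids.append(dying.track_id)
            tree_prev = cKDTree(prev_xy)
            for j, e in enumerate(cur):
                if j in matched_cur:
                    continue
                d, i = tree_prev.query(e.xy_um,
                                       distance_upper_bound=max_link_distance_um)
                if np.isfinite(d) and i < len(prev_events) \
                        and prev_events[i].kind == "merged":
                    src = open_tracks.get(int(i))
                    if src is not None:
                        src.child_ids.append(new_open[j].track_id)
                        new_open[j].parent_ids.append(src.track_id)

        open_tracks = new_open
        prev_events = cur
    return tracks


def tracks_to_frame(tracks: list[Track], frame_rate_hz: float) -> pd.DataFrame:
    """Tracks as a tidy table: track_id, frame, x_um, y_um, speed_um_s."""
    rows = []
    for tr in tracks:
        speeds = tr.step_speeds_um_s(frame_rate_hz)
        for k, (f, (x, y)) in enumerate(zip(tr.frame_indices, tr.xy_um)):
            v = speeds[min(k, len(speeds) - 1)] if len(speeds) else np.nan
            rows.append((tr.track_id, f, x, y, v))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "speed_um_s"])
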