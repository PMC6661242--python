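"""Particle advection through a solved vessel network, with ground truth.

Dimensionless particles ride the solved flow: within a segment each
particle advances by the segment's mean velocity divided by the frame
rate, and at a junction it picks a downstream segment with probability
proportional to the outgoing volumetric flow, so expected mass transport
is preserved.  Each particle keeps a fixed lateral offset (uniform within
the lumen radius, redrawn per segment) so that reported positions fill
the vessel cross-section while staying inside the lumen.

A particle that reaches an outlet is replaced by a fresh particle (new
identity) injected at an inlet with probability proportional to inlet
flow; the number of particles in the field is therefore constant, which
emulates a steady infusion.  The initial population is placed along the
flowing segments weighted by lumen volume, i.e. at the uniform
steady-state concentration, so no wash-in transient needs to be burned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..reporting import merge_threshold_um
from .network import VesselNetwork

__all__ = ["GroundTruthRecord", "advect_particles", "merge_labels"]

DEFAULT_MERGE_THRESHOLD_UM = merge_threshold_um()  # 385 um = 3/4 lambda


@dataclass
class GroundTruthRecord:
    """Per-frame ground truth: particle identities, positions, merge labels.

    ``merged_labels[i]`` is the label of the rendered event particle ``i``
    belongs to; two particles share a label iff they are connected by a
    chain of center-to-center distances below the merge threshold
    (single linkage).  A particle alone in its label is a well-separated
    single event.
    """

    frame_index: int
    particle_ids: np.ndarray          # (n,) int
    xy_um: np.ndarray                 # (n, 2) float, canvas coordinates
    merged_labels: np.ndarray         # (n,) int, frame-local labels

    def __post_init__(self) -> None:
        ids = self.particle_ids
        if len(np.unique(ids)) != len(ids):
            raise ValueError("particle ids must be unique within a frame")

    @property
    def n_particles(self) -> int:
        return len(self.particle_ids)

    def groups(self) -> dict[int, np.ndarray]:
        """Map merged label -> indices of member particles."""
        out: dict[int, np.ndarray] = {}
        for lab in np.unique(self.merged_labels):
            out[int(lab)] = np.flatnonzero(self.merged_labels == lab)
        return out


def merge_labels(xy_um: np.ndarray,
                 threshold_um: float = DEFAULT_MERGE_THRESHOLD_UM) -> np.ndarray:
    """Single-linkage cluster labels of points at a distance threshold.

    Implemented with a KD-tree pair query plus union-find; equivalent to
    cutting a single-linkage dendrogram at ``threshold_um``.
    """
    n = len(xy_um)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1:
        tree = cKDTree(xy_um)
        for i, j in tree.query_pairs(threshold_um):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


class _ParticleState:
    __slots__ = ("pid", "seg", "direction", "s_um", "offset_frac")

    def __init__(self, pid, seg, direction, s_um, offset_frac):
        self.pid = pid
        self.seg = seg
        self.direction = direction    # +1: a->b, -1: b->a
        self.s_um = s_um              # arclength from the entry node
        self.offset_frac = offset_frac


def _segment_frame(network: VesselNetwork):
    a = network.node_xy_um[network.seg_nodes[:, 0]]
    b = network.node_xy_um[network.seg_nodes[:, 1]]
    d = b - a
    length = np.hypot(d[:, 0], d[:, 1])
    axis = d / length[:, None]
    normal = np.column_stack([-axis[:, 1], axis[:, 0]])
    return a, b, axis, normal, length


def _position(state: _ParticleState, a, b, axis, normal, radius) -> np.ndarray:
    k = state.seg
    start = a[k] if state.direction > 0 else b[k]
    return (start + state.direction * state.s_um * axis[k]
            + state.offset_frac * radius[k] * normal[k])


def advect_particles(network: VesselNetwork,
                     n_particles: int,
                     duration_s: float,
                     frame_rate_hz: float,
                     seed: int = 0,
                     merge_threshold_um: float = DEFAULT_MERGE_THRESHOLD_UM,
                     warm_start: bool = True) -> list[GroundTruthRecord]:
    """Advect ``n_particles`` through a solved network and record ground truth.

    Returns one :class:`GroundTruthRecord` per frame (``round(duration *
    frame_rate)`` frames), positions sampled every ``1/frame_rate``.
    Particle identities are new integers for every injection, so a
    re-injected particle never continues an exited track.
    """
    if not network.solved:
        raise RuntimeError("network flow must be solved before advection")
    if n_particles <= 0:
        raise ValueError("n_particles must be positive")
    n_frames = int(round(duration_s * frame_rate_hz))
    rng = np.random.default_rng(seed)
    a, b, axis, normal, length = _segment_frame(network)
    radius = network.radius_um
    q = network.flow_um3_s
    speed = np.abs(network.mean_velocity_um_s)
    dt = 1.0 / frame_rate_hz

    # Outgoing segments per node: segment k leaves node u if flow points away.
    n_nodes = network.n_nodes
    out_segs: list[list[int]] = [[] for _ in range(n_nodes)]
    for k, (na, nb) in enumerate(network.seg_nodes):
        if q[k] > 0:
            out_segs[na].append(k)
        elif q[k] < 0:
            out_segs[nb].append(k)

    boundary = set(int(n) for n in network.boundary_nodes)
    net_out = network.node_net_outflow()
    inlets = [int(n) for n in network.boundary_nodes if net_out[n] > 0]
    inlet_w = np.array([net_out[n] for n in inlets], float)
    if not inlets or inlet_w.sum() <= 0:
        # Zero pressure drop: no flow anywhere, particles just sit still.
        inlets, inlet_w = [], np.array([])

    next_pid = 0

    def inject() -> _ParticleState:
        nonlocal next_pid
        node = inlets[rng.choice(len(inlets), p=inlet_w / inlet_w.sum())]
        segs = out_segs[node]
        w = np.array([abs(q[k]) for k in segs])
        k = segs[rng.choice(len(segs), p=w / w.sum())]
        direction = 1 if network.seg_nodes[k, 0] == node else -1
        st = _ParticleState(next_pid, k, direction,
                            rng.uniform(0, min(speed[k] * dt, length[k])),
                            rng.uniform(-1, 1))
        next_pid += 1
        return st

    def spawn_steady() -> _ParticleState:
        nonlocal next_pid
        flowing = np.flatnonzero(np.abs(q) > 0)
        if len(flowing) == 0:
            # stagnant network: place uniformly by volume over all segments
            flowing = np.arange(network.n_segments)
        vol = np.pi * radius[flowing] ** 2 * length[flowing]
        k = int(flowing[rng.choice(len(flowing), p=vol / vol.sum())])
        direction = 1 if q[k] >= 0 else -1
        st = _ParticleState(next_pid, k, direction,
                            rng.uniform(0, length[k]), rng.uniform(-1, 1))
        next_pid += 1
        return st

    def step(st: _ParticleState) -> _ParticleState | None:
        """Advance one frame interval; None means the particle exited."""
        remaining = speed[st.seg] * dt
        hops = 0
        while remaining > 0 and hops < 1000:
            room = length[st.seg] - st.s_um
            if remaining <= room:
                st.s_um += remaining
                return st
            # consume time, not distance, across the junction
            v_here = speed[st.seg]
            remaining -= room
            time_left = remaining / v_here if v_here > 0 else 0.0
            end_node = int(network.seg_nodes[st.seg, 1] if st.direction > 0
                           else network.seg_nodes[st.seg, 0])
            if end_node in boundary:
                return None
            segs = [k for k in out_segs[end_node] if k != st.seg]
            if not segs:
                return None
            w = np.array([abs(q[k]) for k in segs])
            k = segs[rng.choice(len(segs), p=w / w.sum())]
            st.seg = k
            st.direction = 1 if network.seg_nodes[k, 0] == end_node else -1
            st.s_um = 0.0
            st.offset_frac = rng.uniform(-1, 1)
            remaining = time_left * speed[k]
            hops += 1
        return st

    particles = [spawn_steady() if warm_start else inject()
                 for _ in range(n_particles)]
    if not warm_start and not inlets:
        particles = [spawn_steady() for _ in range(n_particles)]

    records: list[GroundTruthRecord] = []
    for frame in range(n_frames):
        if frame > 0:
            advanced = []
            for st in particles:
                nxt = step(st)
                if nxt is None:
                    nxt = inject() if inlets else spawn_steady()
                advanced.append(nxt)
            particles = advanced
        xy = np.array([_position(st, a, b, axis, normal, radius)
                       for st in particles])
        ids = np.array([st.pid for st in particles])
        records.append(GroundTruthRecord(
            frame_index=frame,
            particle_ids=ids,
            xy_um=xy,
            merged_labels=merge_labels(xy, merge_threshold_um),
        ))
    return records
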