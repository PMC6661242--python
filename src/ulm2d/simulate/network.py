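"""Synthetic microvascular network: geometry and Poiseuille flow.

The network is a planar graph of cylindrical segments spanning a
1.1 x 2.2 cm field, with segment diameters between 10 and 500 um and
lengths between 25 um and 2 mm.  Flow is laminar: each segment carries
``Q = pi r^4 dP / (8 mu L)`` and mass is conserved at every interior node,
which yields a linear system in the nodal pressures (a weighted graph
Laplacian with Dirichlet conditions on the inlet/outlet nodes).

The topology generator builds a rectangular lattice, assigns each segment
a random diameter, and prunes a fraction of the segments while keeping the
graph connected.  This is a deliberately simple "grid of interconnecting
vessels"; it is not meant to reproduce any particular anatomy, only to
span the stated geometric ranges and exercise junctions of varying degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "VesselNetwork",
    "ConfigurationError",
    "FlowSolveError",
    "build_vessel_network",
    "solve_flow",
]

#: Blood-like dynamic viscosity, Pa s.  Only relative flows matter for
#: particle advection, so the absolute value is a free scale.
DEFAULT_VISCOSITY_PA_S = 3.5e-3

RADIUS_RANGE_UM = (5.0, 250.0)
LENGTH_RANGE_UM = (25.0, 2000.0)


class ConfigurationError(ValueError):
    """Invalid network specification (empty, disconnected, out of range)."""


class FlowSolveError(RuntimeError):
    """The pressure system is singular (isolated subgraph without boundary)."""


@dataclass(frozen=True)
class NetworkSpec:
    """Configuration of the lattice vessel-network generator.

    extent is (x, y) in micrometers; defaults span the 2.2 x 1.1 cm field.
    Diameters are drawn log-uniformly so that small vessels are not
    swamped by the wide range.
    """

    extent_um: tuple[float, float] = (22000.0, 11000.0)
    n_cols: int = 12
    n_rows: int = 7
    diameter_range_um: tuple[float, float] = (10.0, 500.0)
    prune_fraction: float = 0.25
    origin_um: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.extent_um[0] <= 0 or self.extent_um[1] <= 0:
            raise ConfigurationError("extent must be positive")
        dmin, dmax = self.diameter_range_um
        if not (10.0 <= dmin <= dmax <= 500.0):
            raise ConfigurationError(
                f"diameter range {self.diameter_range_um} outside [10, 500] um")
        if self.n_cols < 2 or self.n_rows < 1:
            raise ConfigurationError("lattice needs at least 2 columns and 1 row")
        sx = self.extent_um[0] / (self.n_cols - 1)
        sy = self.extent_um[1] / max(self.n_rows - 1, 1)
        lo, hi = LENGTH_RANGE_UM
        if not (lo <= sx <= hi) or (self.n_rows > 1 and not (lo <= sy <= hi)):
            raise ConfigurationError(
                f"lattice spacing ({sx:.0f}, {sy:.0f}) um outside segment "
                f"length range {LENGTH_RANGE_UM}")
        if not (0.0 <= self.prune_fraction < 1.0):
            raise ConfigurationError("prune_fraction must be in [0, 1)")


@dataclass
class VesselNetwork:
    """Graph of nodes and cylindrical vessel segments.

    Arrays are parallel over segments.  ``node_xy_um`` is (n_nodes, 2) in
    physical (x, y) micrometers.  Boundary nodes hold fixed pressures;
    after :func:`solve_flow`, ``pressure_pa`` holds nodal pressures,
    ``flow_um3_s`` the signed volumetric flow of each segment (positive
    from node_a to node_b), and ``mean_velocity_um_s`` = Q / (pi r^2).
    """

    node_xy_um: np.ndarray
    seg_nodes: np.ndarray            # (n_segments, 2) int node indices
    radius_um: np.ndarray            # (n_segments,)
    boundary_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    boundary_pressure_pa: np.ndarray = field(default_factory=lambda: np.empty(0))
    pressure_pa: np.ndarray | None = None
    flow_um3_s: np.ndarray | None = None
    mean_velocity_um_s: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_xy_um)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def length_um(self) -> np.ndarray:
        a = self.node_xy_um[self.seg_nodes[:, 0]]
        b = self.node_xy_um[self.seg_nodes[:, 1]]
        return np.hypot(*(b - a).T)

    @property
    def solved(self) -> bool:
        return self.flow_um3_s is not None

    @property
    def inlet_nodes(self) -> np.ndarray:
        """Boundary nodes whose net solved flow enters the network."""
        if not self.solved:
            raise RuntimeError("flow not solved")
        net = self.node_net_outflow()
        return self.boundary_nodes[net[self.boundary_nodes] > 0]

    def node_net_outflow(self) -> np.ndarray:
        """Signed sum of flows out of each node (zero at interior nodes)."""
        if not self.solved:
            raise RuntimeError("flow not solved")
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.seg_nodes[:, 0], self.flow_um3_s)
        np.add.at(out, self.seg_nodes[:, 1], -self.flow_um3_s)
        return out

    def validate(self) -> None:
        r = self.radius_um
        if np.any(r < RADIUS_RANGE_UM[0] - 1e-9) or np.any(r > RADIUS_RANGE_UM[1] + 1e-9):
            raise ConfigurationError("segment radii outside [5, 250] um")
        L = self.length_um
        if np.any(L < LENGTH_RANGE_UM[0] - 1e-6) or np.any(L > LENGTH_RANGE_UM[1] * (1 + 1e-9)):
            raise ConfigurationError("segment lengths outside [25, 2000] um")
        if self.n_segments == 0:
            raise ConfigurationError("network has zero segments")
        if not _is_connected(self.n_nodes, self.seg_nodes):
            raise ConfigurationError("network graph is disconnected")


def _is_connected(n_nodes: int, seg_nodes: np.ndarray) -> bool:
    if n_nodes == 0:
        return False
    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    for a, b in seg_nodes:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n_nodes, bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                stack.append(v)
    return bool(seen.all())


def build_vessel_network(spec: NetworkSpec) -> VesselNetwork:
    """Build a pruned rectangular lattice of vessels spanning the extent.

    The left edge nodes are inlets (high pressure) and the right edge nodes
    outlets (zero pressure); :func:`solve_flow` sets the pressure scale.
    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny = spec.n_cols, spec.n_rows
    x0, y0 = spec.origin_um
    xs = x0 + np.linspace(0.0, spec.extent_um[0], nx)
    ys = y0 + np.linspace(0.0, spec.extent_um[1], ny)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    def nid(row: int, col: int) -> int:
        return row * nx + col

    edges = []
    for r in range(ny):
        for c in range(nx):
            if c + 1 < nx:
                edges.append((nid(r, c), nid(r, c + 1)))
            if r + 1 < ny:
                edges.append((nid(r, c), nid(r + 1, c)))
    edges = np.array(edges)

    left = np.array([nid(r, 0) for r in range(ny)])
    right = np.array([nid(r, nx - 1) for r in range(ny)])

    # Random pruning, keeping the graph connected and every boundary node
    # attached.  Pruned in a random order up to the requested fraction.
    n_target = int(round(spec.prune_fraction * len(edges)))
    keep = np.ones(len(edges), bool)
    order = rng.permutation(len(edges))
    removed = 0
    for idx in order:
        if removed >= n_target:
            break
        keep[idx] = False
        trial = edges[keep]
        degree = np.zeros(len(nodes), int)
        np.add.at(degree, trial.ravel(), 1)
        if degree.min() >= 1 and _is_connected(len(nodes), trial):
            removed += 1
        else:
            keep[idx] = True
    edges = edges[keep]

    dmin, dmax = spec.diameter_range_um
    diam = np.exp(rng.uniform(np.log(dmin), np.log(dmax), size=len(edges)))

    boundary = np.concatenate([left, right])
    pressures = np.concatenate([np.ones(ny), np.zeros(ny)])
    net = VesselNetwork(
        node_xy_um=nodes,
        seg_nodes=edges,
        radius_um=diam / 2.0,
        boundary_nodes=boundary,
        boundary_pressure_pa=pressures,
    )
    net.validate()
    return net


def segment_conductance(network: VesselNetwork,
                        viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S) -> np.ndarray:
    """Poiseuille conductance g = pi r^4 / (8 mu L) per segment, um^3/(s Pa)."""
    r = network.radius_um
    L = network.length_um
    return np.pi * r ** 4 / (8.0 * viscosity_pa_s * L)


def solve_flow(network: VesselNetwork,
               pressure_drop_pa: float = 1.0,
               viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S,
               target_max_speed_um_s: float | None = None) -> VesselNetwork:
    """Solve nodal pressures and per-segment Poiseuille flows.

    Boundary pressures are ``pressure_drop_pa`` times the stored unit
    boundary profile.  If ``target_max_speed_um_s`` is given, the solution
    is rescaled afterwards (the system is linear in the pressure drop) so
    the fastest segment's mean velocity equals that target; this is how the
    generator pins the kinematics to a physiologic speed scale without
    committing to an absolute pressure.

    Returns a new :class:`VesselNetwork` carrying pressures, signed flows
    and mean velocities.  Raises :class:`FlowSolveError` naming the
    offending nodes if some connected component holds no boundary node.
    """
    if len(network.boundary_nodes) < 2:
        raise FlowSolveError("need at least one inlet and one outlet boundary node")
    n = network.n_nodes
    g = segment_conductance(network, viscosity_pa_s)
    a_idx, b_idx = network.seg_nodes[:, 0], network.seg_nodes[:, 1]

    lap = np.zeros((n, n))
    np.add.at(lap, (a_idx, a_idx), g)
    np.add.at(lap, (b_idx, b_idx), g)
    np.add.at(lap, (a_idx, b_idx), -g)
    np.add.at(lap, (b_idx, a_idx), -g)

    fixed = np.zeros(n, bool)
    fixed[network.boundary_nodes] = True
    p = np.zeros(n)
    p[network.boundary_nodes] = pressure_drop_pa * network.boundary_pressure_pa

    free = ~fixed
    if free.any():
        a_sub = lap[np.ix_(free, free)]
        rhs = -lap[np.ix_(free, fixed)] @ p[fixed]
        diag = np.abs(np.diag(a_sub))
        if np.any(diag == 0):
            bad = np.flatnonzero(free)[diag == 0]
            raise FlowSolveError(
                f"interior nodes {bad.tolist()} have no incident segments")
        try:
            p[free] = np.linalg.solve(a_sub, rhs)
        except np.linalg.LinAlgError as exc:
            raise FlowSolveError(
                "singular pressure system: some interior nodes are not "
                "connected to any boundary node") from exc

    q = g * (p[a_idx] - p[b_idx])
    v = q / (np.pi * network.radius_um ** 2)

    if target_max_speed_um_s is not None:
        vmax = np.abs(v).max()
        if vmax > 0:
            scale = target_max_speed_um_s / vmax
            p, q, v = p * scale, q * scale, v * scale

    solved = replace(network, pressure_pa=p, flow_um3_s=q, mean_velocity_um_s=v)
    # Mass-conservation sanity: interior net flow ~ 0 relative to max flow.
    out = solved.node_net_outflow()
    interior = np.ones(n, bool)
    interior[network.boundary_nodes] = False
    qmax = np.abs(q).max() if len(q) else 0.0
    if qmax > 0 and interior.any() \
            and np.abs(out[interior]).max() > 1e-9 * qmax:
        raise FlowSolveError("mass conservation violated beyond tolerance")
    return solved
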