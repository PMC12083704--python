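"""Instantaneous dynamics of visually and hydrodynamically coupled swimmers.

Each swimmer is a self-propelled particle in the plane with position ``x_i``
and heading angle ``theta_i``.  Three dimensionless intensities control the
behaviour: rotational noise ``In``, alignment ``Ia`` and the strength ``If``
of the dipolar flow field every swimmer sheds (attraction is normalised to
one by the choice of time/length scales).  A swimmer reacts only to its
first-shell Voronoi neighbours, weighted by an asymmetric visual field
``1 + gamma*cos(theta_ij)`` that favours neighbours ahead and blinds the
swimmer to neighbours directly behind.

This module contains the pure per-configuration functions: neighbour graph
construction, visual weighting, the attraction/alignment heading drift, the
superposed dipolar flow field and the flow-gradient angular velocity.  Time
integration lives in :mod:`hydroschool.simulator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "DegenerateGeometryError",
    "SingularConfigurationError",
    "ModelParams",
    "SchoolState",
    "NeighborGraph",
    "PairGeometry",
    "wrap_angle",
    "voronoi_neighbors",
    "visual_weight",
    "heading_drift",
    "heading_drift_all",
    "dipole_flow",
    "flow_angular_velocity",
    "flow_field_and_omega",
]

#: below this pair distance the dipole sum is treated as singular
R_SINGULAR = 1e-6
#: below this pair distance a near-contact warning is emitted
R_WARN = 1e-2


class DegenerateGeometryError(ValueError):
    """Raised when a Voronoi tessellation of the positions does not exist."""


class SingularConfigurationError(FloatingPointError):
    """Raised when two swimmers come close enough to blow up the dipole sum."""


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -np.mod(-a + np.pi, 2.0 * np.pi) + np.pi  # maps to (-pi, pi]
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless swimmer parameters.

    Parameters
    ----------
    In : float
        Rotational noise intensity (>= 0).
    Ia : float
        Alignment intensity (>= 0).  Attraction intensity is 1 by the
        non-dimensionalisation.
    If : float
        Dipolar flow intensity (>= 0); ``If = pi * (a/2)**2 * U`` for a
        swimmer of bodylength ``a``.
    U : float
        Self-propulsion speed; fixed at 1 in dimensionless units.
    gamma : float
        Visual-bias strength in [0, 1]; 1 gives a full rear blind spot.
    dt : float
        Integration timestep.
    seed : int
        RNG seed used by the simulator.
    """

    In: float = 0.5
    Ia: float = 9.0
    If: float = 0.01
    U: float = 1.0
    gamma: float = 1.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.In < 0 or self.Ia < 0 or self.If < 0:
            raise ValueError("intensities In, Ia, If must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.U != 1.0:
            raise ValueError("the non-dimensionalisation fixes U = 1")

    @property
    def bodylength(self) -> float:
        """Swimmer bodylength ``a = 2*sqrt(If / (pi*U))`` implied by If."""
        return 2.0 * np.sqrt(self.If / (np.pi * self.U))


@dataclass
class SchoolState:
    """Positions, headings and (derived) velocities of N swimmers at time t."""

    t: float
    x: np.ndarray          # (N, 2)
    theta: np.ndarray      # (N,), wrapped to (-pi, pi]
    v: np.ndarray | None = None  # (N, 2), U*p + flow, filled by the simulator

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.x.shape != (self.theta.size, 2):
            raise ValueError("x must be (N, 2) matching theta of length N")
        if not (np.isfinite(self.x).all() and np.isfinite(self.theta).all()):
            raise ValueError("non-finite entries in state")
        self.theta = wrap_angle(self.theta)
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float).reshape(self.x.shape)

    @property
    def n(self) -> int:
        return self.theta.size

    @property
    def p(self) -> np.ndarray:
        """Unit heading vectors (N, 2)."""
        return np.column_stack([np.cos(self.theta), np.sin(self.theta)])


@dataclass
class NeighborGraph:
    """Symmetric first-shell Voronoi (= Delaunay edge) adjacency."""

    n: int
    edges: np.ndarray  # (E, 2) unique undirected pairs, each row sorted

    _adj: list | None = field(default=None, repr=False, compare=False)

    def directed_edges(self) -> np.ndarray:
        """Both orientations of every edge, shape (2E, 2)."""
        return np.vstack([self.edges, self.edges[:, ::-1]])

    def neighbors_of(self, i: int) -> np.ndarray:
        if self._adj is None:
            adj = [[] for _ in range(self.n)]
            for a, b in self.edges:
                adj[a].append(b)
                adj[b].append(a)
            self._adj = [np.array(sorted(l), dtype=int) for l in adj]
        return self._adj[i]

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


@dataclass(frozen=True)
class PairGeometry:
    """Relative geometry of an ordered swimmer pair (i, j).

    ``theta_ij`` is the viewing angle of j as seen by i, measured from i's
    heading; ``phi_ij`` the heading difference ``theta_j - theta_i``.
    """

    r_ij: float
    theta_ij: float
    theta_ji: float
    phi_ij: float


def pair_geometry(x: np.ndarray, theta: np.ndarray, i: int, j: int) -> PairGeometry:
    d = x[j] - x[i]
    r = float(np.hypot(d[0], d[1]))
    bear_ij = np.arctan2(d[1], d[0])          # absolute bearing of j from i
    bear_ji = np.arctan2(-d[1], -d[0])
    return PairGeometry(
        r_ij=r,
        theta_ij=wrap_angle(bear_ij - theta[i]),
        theta_ji=wrap_angle(bear_ji - theta[j]),
        phi_ij=wrap_angle(theta[j] - theta[i]),
    )


def voronoi_neighbors(x: np.ndarray) -> NeighborGraph:
    """Delaunay-edge adjacency of the positions (= Voronoi facet sharing).

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points, or collinear/coincident configurations
        where no 2-D tessellation exists.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("positions must be (N, 2)")
    n = x.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points for a tessellation")
    try:
        tri = Delaunay(x)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point configuration: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGeometryError("degenerate point configuration (no simplices)")
    s = tri.simplices
    pairs = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    pairs.sort(axis=1)
    edges = np.unique(pairs, axis=0)
    return NeighborGraph(n=n, edges=edges)


def visual_weight(theta_ij, gamma: float = 1.0):
    """Frontal-bias visual weight ``1 + gamma*cos(theta_ij)``.

    With ``gamma = 1`` the weight is 2 for a neighbour dead ahead, 1 for a
    lateral neighbour and 0 for one directly behind (rear blind spot).
    """
    return 1.0 + gamma * np.cos(theta_ij)


def heading_drift(i: int, state: SchoolState, graph: NeighborGraph,
                  params: ModelParams) -> float:
    """Deterministic visual part of ``dtheta_i/dt`` for one swimmer.

    Weighted mean, over i's Voronoi neighbours, of the attraction term
    ``r_ij*sin(theta_ij)`` plus ``Ia*sin(phi_ij)``, with visual weights
    ``1 + gamma*cos(theta_ij)``.  If the total weight vanishes (all
    neighbours exactly behind — a measure-zero event) the drift is 0.
    """
    nbrs = graph.neighbors_of(i)
    if nbrs.size == 0:
        raise ValueError(f"swimmer {i} has no Voronoi neighbors")
    d = state.x[nbrs] - state.x[i]
    r = np.hypot(d[:, 0], d[:, 1])
    theta_ij = wrap_angle(np.arctan2(d[:, 1], d[:, 0]) - state.theta[i])
    phi_ij = wrap_angle(state.theta[nbrs] - state.theta[i])
    w = visual_weight(theta_ij, params.gamma)
    wtot = w.sum()
    if wtot <= 0.0:
        return 0.0
    return float(np.sum(w * (r * np.sin(theta_ij) + params.Ia * np.sin(phi_ij))) / wtot)


def heading_drift_all(state: SchoolState, graph: NeighborGraph,
                      params: ModelParams) -> np.ndarray:
    """Vectorised :func:`heading_drift` for every swimmer (used per step)."""
    de = graph.directed_edges()
    i_idx, j_idx = de[:, 0], de[:, 1]
    d = state.x[j_idx] - state.x[i_idx]
    r = np.hypot(d[:, 0], d[:, 1])
    theta_ij = wrap_angle(np.arctan2(d[:, 1], d[:, 0]) - state.theta[i_idx])
    phi_ij = wrap_angle(state.theta[j_idx] - state.theta[i_idx])
    w = visual_weight(theta_ij, params.gamma)
    num = np.bincount(i_idx, weights=w * (r * np.sin(theta_ij)
                                          + params.Ia * np.sin(phi_ij)),
                      minlength=state.n)
    den = np.bincount(i_idx, weights=w, minlength=state.n)
    drift = np.zeros(state.n)
    ok = den > 0.0
    drift[ok] = num[ok] / den[ok]
    return drift


def _check_min_distance(rmin: float):
    if rmin < R_SINGULAR:
        raise SingularConfigurationError(
            f"pair distance {rmin:.3e} below singular threshold {R_SINGULAR:g}")
    if rmin < R_WARN:
        # constant message so the default warning filter dedupes per process
        warnings.warn(
            f"near-contact pair below distance {R_WARN:g}; dipole flow may be "
            "inaccurate in the near field", RuntimeWarning, stacklevel=3)


def dipole_flow(x: np.ndarray, theta: np.ndarray, If: float) -> np.ndarray:
    """Flow velocity at every swimmer from the dipoles of all others.

    ``U_i = sum_{j != i} (If/pi) * [p_j_perp*sin(2*theta_ji)
    + p_j*cos(2*theta_ji)] / r_ij**2``, with ``theta_ji`` the viewing angle
    of i from j and ``p_j_perp`` the +90-degree rotation of ``p_j``.  The
    far-field dipole decays as 1/r^2 and superposes linearly.

    This reference implementation is O(N^2) in memory; the simulator uses a
    compiled streaming kernel that this function cross-validates in tests.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = x.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    diff = x[:, None, :] - x[None, :, :]        # x_i - x_j
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, np.inf)
    rmin = float(np.sqrt(r2.min())) if n > 1 else np.inf
    _check_min_distance(rmin)
    bearing = np.arctan2(diff[..., 1], diff[..., 0])  # bearing of i from j
    theta_ji = bearing - theta[None, :]
    p = np.column_stack([np.cos(theta), np.sin(theta)])
    p_perp = np.column_stack([-np.sin(theta), np.cos(theta)])
    amp = If / np.pi
    s2, c2 = np.sin(2.0 * theta_ji), np.cos(2.0 * theta_ji)
    contrib = (p_perp[None, :, :] * s2[..., None]
               + p[None, :, :] * c2[..., None]) / r2[..., None]
    return amp * contrib.sum(axis=1)


def _fprime_sum(x: np.ndarray, theta: np.ndarray, If: float, i: int) -> complex:
    """Sum over j != i of the complex derivative of conj-velocity f_j'(z_i).

    The dipole of swimmer j has conjugate complex velocity
    ``f_j(z) = (If/pi) * exp(i*theta_j) / (z - z_j)**2`` (holomorphic), so
    the ambient-flow Jacobian at x_i follows from
    ``f'(z) = -2*(If/pi)*exp(i*theta_j)/(z - z_j)**3``.
    """
    z = (x[:, 0] - x[i, 0]) + 1j * (x[:, 1] - x[i, 1])   # z_j - z_i
    z = np.delete(-z, i)                                  # z_i - z_j, j != i
    th = np.delete(theta, i)
    return complex(np.sum(-2.0 * (If / np.pi) * np.exp(1j * th) / z**3))


def flow_angular_velocity(i: int, x: np.ndarray, theta: np.ndarray,
                          If: float) -> float:
    """Angular velocity ``Omega_i = p_i . (dU/dx at x_i) . p_i_perp``.

    The gradient is of the ambient flow only (swimmer i's own dipole is
    excluded) and uses the closed-form Jacobian of the dipole field.  For an
    incompressible, irrotational dipole the Jacobian is symmetric traceless,
    ``[[A, -B], [-B, -A]]`` with ``A + i*B`` the summed complex derivative,
    giving ``Omega_i = -(A*sin(2*theta_i) + B*cos(2*theta_i))``.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if x.shape[0] == 1:
        return 0.0
    d = x - x[i]
    r = np.hypot(d[:, 0], d[:, 1])
    rmin = float(np.min(np.delete(r, i)))
    _check_min_distance(rmin)
    s = _fprime_sum(x, theta, If, i)
    return float(-(s.real * np.sin(2.0 * theta[i]) + s.imag * np.cos(2.0 * theta[i])))


def flow_field_and_omega(x: np.ndarray, theta: np.ndarray, If: float):
    """Flow velocities and flow-gradient angular velocities for all swimmers.

    Thin wrapper around the compiled O(N^2) pair-sum kernel; checks the
    minimum pair distance and returns ``(flow (N,2), omega (N,))``.
    """
    from hydroschool._kernels import dipole_pair_sums

    x = np.ascontiguousarray(x, dtype=float)
    theta = np.ascontiguousarray(theta, dtype=float)
    if x.shape[0] == 1:
        return np.zeros((1, 2)), np.zeros(1)
    flow, omega, rmin = dipole_pair_sums(x, theta, If / np.pi)
    _check_min_distance(rmin)
    return flow, omega
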