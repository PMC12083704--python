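"""Unit and property tests for the instantaneous swimmer dynamics."""

import numpy as np
import pytest

from hydroschool.model_core import (
    DegenerateGeometryError,
    ModelParams,
    SchoolState,
    SingularConfigurationError,
    dipole_flow,
    flow_angular_velocity,
    flow_field_and_omega,
    heading_drift,
    heading_drift_all,
    pair_geometry,
    visual_weight,
    voronoi_neighbors,
    wrap_angle,
)


class TestModelParams:
    def test_defaults_and_bodylength(self):
        p = ModelParams(If=0.01)
        assert p.U == 1.0
        # If = pi (a/2)^2 U  =>  a = 2 sqrt(If/(pi U))
        assert p.bodylength == pytest.approx(2.0 * np.sqrt(0.01 / np.pi))
        assert round(p.bodylength, 2) == 0.11

    @pytest.mark.parametrize("kw", [
        {"In": -0.1}, {"Ia": -1.0}, {"If": -0.01}, {"gamma": 1.5},
        {"gamma": -0.1}, {"dt": 0.0}, {"U": 2.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)


def test_wrap_angle_range_and_identity():
    a = np.linspace(-10, 10, 1001)
    w = wrap_angle(a)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    assert np.allclose(np.exp(1j * w), np.exp(1j * a))


class TestVoronoiNeighbors:
    def test_triangle_fully_connected(self):
        g = voronoi_neighbors(np.array([[0.0, 0], [1, 0], [0.5, 1]]))
        assert len(g.edges) == 3
        assert set(map(tuple, g.edges)) == {(0, 1), (0, 2), (1, 2)}

    def test_unit_square_has_five_edges_and_diagonal(self):
        g = voronoi_neighbors(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        assert len(g.edges) == 5
        deg = g.degree()
        assert sorted(deg) == [2, 2, 3, 3]  # the two diagonal corners see 3

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            voronoi_neighbors(np.array([[0.0, 0], [1, 1], [2, 2]]))  # collinear
        with pytest.raises(DegenerateGeometryError):
            voronoi_neighbors(np.array([[0.0, 0], [1, 0]]))          # too few

    def test_symmetry_and_connectivity_random(self, rng):
        x = rng.uniform(0, 10, (40, 2))
        g = voronoi_neighbors(x)
        # symmetric adjacency with no self edges
        assert np.all(g.edges[:, 0] < g.edges[:, 1])
        # connected: BFS reaches every swimmer
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in g.neighbors_of(i):
                if j not in seen:
                    seen.add(j)
                    frontier.append(j)
        assert len(seen) == 40


@pytest.mark.parametrize("angle,gamma,expected", [
    (0.0, 1.0, 2.0),          # dead ahead
    (np.pi, 1.0, 0.0),        # rear blind spot
    (np.pi / 2, 1.0, 1.0),    # lateral
    (0.0, 0.0, 1.0),          # no visual bias
])
def test_visual_weight(angle, gamma, expected):
    assert visual_weight(angle, gamma) == pytest.approx(expected)


class TestHeadingDrift:
    def _state(self, x, theta):
        return SchoolState(t=0.0, x=np.asarray(x, float),
                           theta=np.asarray(theta, float))

    def test_neighbor_dead_ahead_same_heading_gives_zero(self):
        # front neighbour contributes nothing; the symmetric rear pair
        # cancels, so the aligned configuration is a drift fixed point
        st = self._state([[0, 0], [2, 0], [-2, 1], [-2, -1]], [0, 0, 0, 0])
        g = voronoi_neighbors(st.x)
        p = ModelParams(Ia=9.0)
        assert heading_drift(0, st, g, p) == pytest.approx(0.0, abs=1e-12)

    def test_pure_attraction_lateral_neighbor(self):
        r = 3.0
        st = self._state([[0, 0], [0, r], [-50, 0]], [0, 0, 0])
        g = voronoi_neighbors(st.x)
        p = ModelParams(Ia=5.0)
        # lateral neighbour at theta_ij = pi/2, same heading: drift = r
        assert heading_drift(0, st, g, p) == pytest.approx(r, rel=1e-12)

    def test_mirror_configuration_negates_drift(self, rng):
        p = ModelParams(Ia=7.0)
        for _ in range(10):
            x = rng.uniform(-5, 5, (6, 2))
            th = rng.uniform(-np.pi, np.pi, 6)
            # focal swimmer at origin heading +x; mirror about its heading axis
            x[0] = 0.0
            th[0] = 0.0
            st = self._state(x, th)
            xm = x * np.array([1.0, -1.0])
            stm = self._state(xm, -th)
            g = voronoi_neighbors(x)
            gm = voronoi_neighbors(xm)
            d = heading_drift(0, st, g, p)
            dm = heading_drift(0, stm, gm, p)
            assert dm == pytest.approx(-d, rel=1e-10, abs=1e-12)

    def test_vectorised_matches_scalar(self, rng):
        x = rng.uniform(0, 8, (15, 2))
        th = rng.uniform(-np.pi, np.pi, 15)
        st = self._state(x, th)
        g = voronoi_neighbors(x)
        p = ModelParams(Ia=9.0, gamma=0.7)
        all_d = heading_drift_all(st, g, p)
        for i in range(15):
            assert all_d[i] == pytest.approx(heading_drift(i, st, g, p), rel=1e-12)

    def test_aligned_interior_lattice_swimmer_is_fixed_point(self):
        from conftest import triangular_patch

        x = triangular_patch(7, 7, 1.0)
        st = self._state(x, np.zeros(len(x)))
        g = voronoi_neighbors(x)
        p = ModelParams(Ia=9.0, If=0.0, In=0.0)
        drift = heading_drift_all(st, g, p)
        # interior swimmers: attraction cancels by symmetry, alignment is 0
        centre = np.array([3.25, 3.0 * np.sqrt(3) / 2])
        interior = np.flatnonzero(np.hypot(*(x - centre).T) < 2.0)
        assert len(interior) >= 5
        assert np.max(np.abs(drift[interior])) < 1e-10


class TestDipoleFlow:
    def test_point_evaluations_against_closed_form(self):
        # a source at the origin heading +x with If = pi
        x = np.array([[0.0, 0.0], [1.0, 0.0]])
        th = np.array([0.0, 0.3])
        assert dipole_flow(x, th, np.pi)[1] == pytest.approx([1.0, 0.0], abs=1e-14)
        x2 = np.array([[0.0, 0.0], [0.0, 1.0]])
        assert dipole_flow(x2, th, np.pi)[1] == pytest.approx([-1.0, 0.0], abs=1e-14)

    def test_superposition(self, rng):
        th = rng.uniform(-np.pi, np.pi, 3)
        x = np.array([[0.0, 0], [3, 1], [1, 4]])
        full = dipole_flow(x, th, 0.02)[2]
        only0 = dipole_flow(x[[0, 2]], th[[0, 2]], 0.02)[1]
        only1 = dipole_flow(x[[1, 2]], th[[1, 2]], 0.02)[1]
        assert full == pytest.approx(only0 + only1, rel=1e-12)

    def test_inverse_square_decay(self, rng):
        x = rng.uniform(0, 5, (6, 2))
        th = rng.uniform(-np.pi, np.pi, 6)
        f1 = dipole_flow(x, th, 0.01)
        f2 = dipole_flow(3.0 * x, th, 0.01)
        assert f2 == pytest.approx(f1 / 9.0, rel=1e-10)

    def test_translation_invariance_and_rotation_equivariance(self, rng):
        x = rng.uniform(0, 5, (5, 2))
        th = rng.uniform(-np.pi, np.pi, 5)
        f = dipole_flow(x, th, 0.01)
        assert dipole_flow(x + [7.0, -3.0], th, 0.01) == pytest.approx(f, rel=1e-12)
        beta = 0.8
        R = np.array([[np.cos(beta), -np.sin(beta)], [np.sin(beta), np.cos(beta)]])
        f_rot = dipole_flow(x @ R.T, th + beta, 0.01)
        assert f_rot == pytest.approx(f @ R.T, rel=1e-10)

    def test_singular_configuration_raises(self):
        x = np.array([[0.0, 0.0], [1e-8, 0.0]])
        with pytest.raises(SingularConfigurationError):
            dipole_flow(x, np.zeros(2), 0.01)

    def test_near_contact_warns(self):
        x = np.array([[0.0, 0.0], [5e-3, 0.0]])
        with pytest.warns(RuntimeWarning, match="near-contact"):
            dipole_flow(x, np.zeros(2), 0.01)

    def test_compiled_kernel_matches_reference_sum(self, rng):
        """Dual route: streaming kernel vs direct superposition formula."""
        x = rng.uniform(0, 12, (60, 2))
        th = rng.uniform(-np.pi, np.pi, 60)
        ref = dipole_flow(x, th, 0.01)
        flow, omega = flow_field_and_omega(x, th, 0.01)
        assert flow == pytest.approx(ref, rel=1e-10, abs=1e-14)
        ana = np.array([flow_angular_velocity(i, x, th, 0.01) for i in range(60)])
        assert omega == pytest.approx(ana, rel=1e-10, abs=1e-14)


def _omega_finite_difference(i, x, th, If, h=1e-6):
    """Central-difference oracle for the flow-gradient angular velocity."""
    xs = np.delete(x, i, axis=0)
    ts = np.delete(th, i)

    def ambient(pt):
        xa = np.vstack([xs, pt])
        ta = np.append(ts, 0.0)
        return dipole_flow(xa, ta, If)[-1]

    J = np.zeros((2, 2))
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        J[:, k] = (ambient(x[i] + e) - ambient(x[i] - e)) / (2 * h)
    p = np.array([np.cos(th[i]), np.sin(th[i])])
    return float(p @ J @ np.array([-p[1], p[0]]))


class TestFlowAngularVelocity:
    def test_single_swimmer_is_zero(self):
        assert flow_angular_velocity(0, np.zeros((1, 2)), np.zeros(1), 0.01) == 0.0

    def test_matches_finite_difference_oracle(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 6, (3, 2))
            th = rng.uniform(-np.pi, np.pi, 3)
            for i in range(3):
                ana = flow_angular_velocity(i, x, th, 0.01)
                fd = _omega_finite_difference(i, x, th, 0.01)
                assert ana == pytest.approx(fd, rel=1e-5, abs=1e-12)

    def test_mirror_parity(self):
        x = np.array([[0.0, 0.0], [2.0, 1.0]])
        th = np.array([0.4, -1.1])
        om = flow_angular_velocity(0, x, th, 0.01)
        om_m = flow_angular_velocity(0, x * [1, -1], -th, 0.01)
        assert om_m == pytest.approx(-om, rel=1e-12)


def test_pair_geometry_conventions():
    x = np.array([[0.0, 0.0], [1.0, 1.0]])
    th = np.array([0.0, np.pi / 2])
    g = pair_geometry(x, th, 0, 1)
    assert g.r_ij == pytest.approx(np.sqrt(2))
    assert g.theta_ij == pytest.approx(np.pi / 4)
    assert g.theta_ji == pytest.approx(3 * np.pi / 4)  # wrap(-3pi/4 - pi/2)
    assert g.phi_ij == pytest.approx(np.pi / 2)
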