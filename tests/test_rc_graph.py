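"""Reaction-coordinate graphs: forward values, chain-rule forces, matrices."""

import numpy as np
import pytest

from fearcf import rc_graph as rg
from fearcf.constants import MASS_H, MASS_O

from conftest import WATER_MASSES, make_random_dimer


# ---------------------------------------------------------------------------
# independent flat vector-algebra oracle (no graph machinery)
# ---------------------------------------------------------------------------

def oracle_dimer_rcs(x, ndim):
    """Direct formulas for the 1D/2D/4D water-dimer RCs, one geometry."""
    m = WATER_MASSES
    if ndim == 1:
        return np.array([np.linalg.norm(x[3] - x[0])])
    w1 = (m[:, None] * x[:3]).sum(0) / m.sum()
    w2 = (m[:, None] * x[3:6]).sum(0) / m.sum()
    b1 = w1 - x[0]
    b2 = w2 - x[3]
    r = np.linalg.norm(w2 - w1)
    if ndim == 2:
        c = b1 @ b2 / (np.linalg.norm(b1) * np.linalg.norm(b2))
        return np.array([r, np.degrees(np.arccos(np.clip(c, -1, 1)))])
    rv = w2 - w1
    def ang(a, b):
        c = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))
    mm = np.cross(b1, rv)
    nn = np.cross(b2, rv)
    phi = ang(mm, nn)
    if np.cross(mm, nn) @ rv < 0:
        phi = 360.0 - phi
    return np.array([r, ang(b1, rv), ang(b2, rv), phi])


def fd_jacobian(graph, x, h=1e-5):
    J = np.zeros((graph.ndim, graph.n_atoms, 3))
    for a in range(graph.n_atoms):
        for c in range(3):
            xp = x.copy(); xp[a, c] += h
            xm = x.copy(); xm[a, c] -= h
            d = rg.evaluate(graph, xp) - rg.evaluate(graph, xm)
            d = np.where(d > 300, d - 360, np.where(d < -300, d + 360, d))
            J[:, a, c] = d / (2 * h)
    return J


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

class TestBuild:
    def test_simple_distance_graph(self):
        g = rg.build_graph({
            "nodes": {"O1": {"kind": "atom_point", "atom": 0},
                      "O2": {"kind": "atom_point", "atom": 1},
                      "r": {"kind": "distance", "parents": ["O1", "O2"]}},
            "rcs": ["r"]})
        assert len(g.nodes) == 3
        assert g.adjacency.sum() == 4          # one edge pair per parent link
        assert set(g.derivative_paths) == {(2, 0), (2, 1)}

    def test_self_reference_is_cycle_error(self):
        with pytest.raises(rg.GraphError, match="parent"):
            rg.build_graph({
                "nodes": {"v": {"kind": "vector", "parents": ["v", "v"]}},
                "rcs": ["v"]})

    def test_four_d_graph_reaches_all_atoms(self):
        g = rg.water_dimer_graph(4)
        assert g.ndim == 4
        for rc in g.rc_node_ids:
            atoms = {g.nodes[a].atom_index
                     for (r, a) in g.derivative_paths if r == rc}
            assert atoms == set(range(6))

    @pytest.mark.parametrize("spec, err", [
        ({"nodes": {"a": {"kind": "atom_point", "atom": 0},
                    "r": {"kind": "distance", "parents": ["a"]}},
          "rcs": ["r"]}, "parents"),
        ({"nodes": {"a": {"kind": "atom_point"}}, "rcs": ["a"]}, "atom"),
        ({"nodes": {"a": {"kind": "atom_point", "atom": 0}},
          "rcs": ["a"]}, "non-scalar"),
        ({"nodes": {"a": {"kind": "wiggle"}}, "rcs": ["a"]}, "kind"),
        ({"nodes": {"a": {"kind": "atom_point", "atom": 0},
                    "c": {"kind": "center_of_mass", "parents": ["a"],
                          "masses": [-1.0]}},
          "rcs": ["c"]}, "mass"),
    ])
    def test_invalid_specs_rejected(self, spec, err):
        with pytest.raises(rg.GraphError, match=err):
            rg.build_graph(spec)

    def test_adjacency_symmetric_zero_diagonal(self):
        g = rg.water_dimer_graph(4)
        A = g.adjacency
        assert np.array_equal(A, A.T)
        assert not A.diagonal().any()

    def test_adjacency_dump_is_parseable(self):
        g = rg.water_dimer_graph(1)
        lines = g.adjacency_dump().strip().splitlines()
        mat = np.array([[int(v) for v in ln.split()] for ln in lines[1:]])
        assert np.array_equal(mat, g.adjacency)


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_oxygen_distance(self):
        g = rg.water_dimer_graph(1)
        x = np.zeros((6, 3))
        x[3, 0] = 2.9
        assert rg.evaluate(g, x)[0] == pytest.approx(2.9)

    def test_orthogonal_vectors_give_right_angle(self):
        g = rg.build_graph({
            "nodes": {"o": {"kind": "atom_point", "atom": 0},
                      "a": {"kind": "atom_point", "atom": 1},
                      "b": {"kind": "atom_point", "atom": 2},
                      "v1": {"kind": "vector", "parents": ["o", "a"]},
                      "v2": {"kind": "vector", "parents": ["o", "b"]},
                      "ang": {"kind": "angle", "parents": ["v1", "v2"]}},
            "rcs": ["ang"]})
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        assert rg.evaluate(g, x)[0] == pytest.approx(90.0)

    def test_planar_trans_dihedral_is_180(self):
        g = rg.build_graph({
            "nodes": {
                "p0": {"kind": "atom_point", "atom": 0},
                "p1": {"kind": "atom_point", "atom": 1},
                "p2": {"kind": "atom_point", "atom": 2},
                "p3": {"kind": "atom_point", "atom": 3},
                "u": {"kind": "vector", "parents": ["p1", "p0"]},
                "v": {"kind": "vector", "parents": ["p1", "p2"]},
                "w": {"kind": "vector", "parents": ["p2", "p3"]},
                "m": {"kind": "cross_vector", "parents": ["u", "v"]},
                "n": {"kind": "cross_vector", "parents": ["w", "v"]},
                "phi": {"kind": "dihedral", "parents": ["m", "n"]}},
            "rcs": ["phi"]})
        x = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], float)
        assert rg.evaluate(g, x)[0] == pytest.approx(180.0)

    @pytest.mark.parametrize("ndim", [1, 2, 4])
    def test_matches_flat_vector_algebra_oracle(self, ndim, rng):
        g = rg.water_dimer_graph(ndim)
        for x in make_random_dimer(rng, 1000):
            np.testing.assert_allclose(
                rg.evaluate(g, x), oracle_dimer_rcs(x, ndim),
                rtol=1e-10, atol=1e-10)

    def test_rigid_motion_invariance(self, rng, random_dimers):
        g = rg.water_dimer_graph(4)
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, xq, yq, zq = q
        R = np.array([
            [1-2*(yq*yq+zq*zq), 2*(xq*yq-zq*w), 2*(xq*zq+yq*w)],
            [2*(xq*yq+zq*w), 1-2*(xq*xq+zq*zq), 2*(yq*zq-xq*w)],
            [2*(xq*zq-yq*w), 2*(yq*zq+xq*w), 1-2*(xq*xq+yq*yq)]])
        shift = np.array([3.0, -1.0, 0.5])
        v1 = rg.evaluate(g, random_dimers)
        v2 = rg.evaluate(g, random_dimers @ R.T + shift)
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_missing_coordinates_rejected(self):
        g = rg.water_dimer_graph(4)
        with pytest.raises(ValueError, match="atoms"):
            rg.evaluate(g, np.zeros((3, 3)))


class TestCenterOfMass:
    def test_midpoint_symmetry_and_identity(self):
        assert np.allclose(rg.center_of_mass([[0, 0, 0], [2, 0, 0]], [1, 1]),
                           [1, 0, 0])
        assert np.allclose(
            rg.center_of_mass([[0, 0, 0], [1, 0, 0], [-1, 0, 0]], [16, 1, 1]),
            [0, 0, 0])
        assert np.allclose(rg.center_of_mass([[3, 2, 1]], [7.0]), [3, 2, 1])

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            rg.center_of_mass([[0, 0, 0]], [0.0])


# ---------------------------------------------------------------------------
# force propagation
# ---------------------------------------------------------------------------

class TestForces:
    def test_distance_rc_pulls_endpoints_oppositely(self):
        g = rg.water_dimer_graph(1)
        x = np.zeros((6, 3)); x[3, 0] = 3.0
        F = rg.propagate_forces(g, x, [2.0])
        np.testing.assert_allclose(F[0], [2.0, 0, 0])      # -g * (-r̂)
        np.testing.assert_allclose(F[3], [-2.0, 0, 0])
        assert np.allclose(F[[1, 2]], 0.0)                 # hydrogens untouched

    def test_null_gradient_gives_zero_forces(self, random_dimers):
        g = rg.water_dimer_graph(4)
        F = rg.propagate_forces(g, random_dimers, np.zeros((64, 4)))
        assert np.all(F == 0.0)

    @pytest.mark.parametrize("ndim", [1, 2, 4])
    def test_jacobian_matches_finite_differences(self, ndim, rng):
        g = rg.water_dimer_graph(ndim)
        worst = 0.0
        for x in make_random_dimer(rng, 100):
            J = rg.jacobian(g, x[:g.n_atoms] if g.n_atoms < 6 else x)
            Jfd = fd_jacobian(g, x)
            scale = np.abs(J).max(axis=(1, 2), keepdims=True)
            worst = max(worst, float(np.max(np.abs(J - Jfd) / scale)))
        assert worst < 1e-6

    def test_newtons_third_law_and_zero_torque(self, random_dimers):
        g = rg.water_dimer_graph(4)
        dW = np.ones((64, 4))
        F = rg.propagate_forces(g, random_dimers, dW)
        np.testing.assert_allclose(F.sum(axis=-2), 0.0, atol=1e-10)
        torque = np.cross(random_dimers, F).sum(axis=-2)
        np.testing.assert_allclose(torque, 0.0, atol=1e-9)

    def test_com_weights_sum_to_one(self):
        g = rg.water_dimer_graph(2)
        com = next(n for n in g.nodes if n.kind == "center_of_mass")
        assert com.weights.sum() == pytest.approx(1.0)
        assert com.weights[0] == pytest.approx(MASS_O / (MASS_O + 2 * MASS_H))

    def test_degenerate_distance_zeroes_force(self, caplog):
        g = rg.water_dimer_graph(1)
        x = np.zeros((6, 3))                   # both oxygens coincide
        with caplog.at_level("WARNING"):
            F = rg.propagate_forces(g, x, [1.0])
        assert np.all(F == 0.0)

    def test_non_finite_gradient_rejected(self, random_dimers):
        g = rg.water_dimer_graph(1)
        with pytest.raises(ValueError, match="finite"):
            rg.propagate_forces(g, random_dimers[0], [np.nan])


# ---------------------------------------------------------------------------
# derivative matrix
# ---------------------------------------------------------------------------

class TestDerivativeMatrix:
    def test_sparsity_follows_adjacency(self, rng):
        g = rg.water_dimer_graph(4)
        x = make_random_dimer(rng, 1)[0]
        D = rg.derivative_matrix(g, x)
        for i in range(len(g.nodes)):
            for j in range(len(g.nodes)):
                assert (D[i, j] is not None) == bool(g.adjacency[i, j])

    def test_path_products_equal_jacobian(self, rng):
        g = rg.water_dimer_graph(4)
        for x in make_random_dimer(rng, 10):
            J = rg.jacobian(g, x)
            Jp = rg.path_product_jacobian(g, x)
            np.testing.assert_allclose(J, Jp, atol=1e-9)

    def test_shared_atom_accumulates_both_rc_gradients(self):
        # two distance RCs sharing a central atom (proton-exchange style):
        # F on the shared atom is the sum of both chain-rule terms
        g = rg.build_graph({
            "nodes": {"N1": {"kind": "atom_point", "atom": 0},
                      "H": {"kind": "atom_point", "atom": 1},
                      "N2": {"kind": "atom_point", "atom": 2},
                      "xi1": {"kind": "distance", "parents": ["N1", "H"]},
                      "xi2": {"kind": "distance", "parents": ["N2", "H"]}},
            "rcs": ["xi1", "xi2"]})
        x = np.array([[0, 0, 0], [1.1, 0.2, 0], [2.6, 0, 0]], float)
        g1, g2 = 1.3, -0.7
        F = rg.propagate_forces(g, x, [g1, g2])
        J = rg.jacobian(g, x)
        expected_H = -(g1 * J[0, 1] + g2 * J[1, 1])
        np.testing.assert_allclose(F[1], expected_H, atol=1e-12)


class TestDihedralConventions:
    def test_signed_covers_full_circle_arccos_folds(self, rng):
        g_signed = rg.water_dimer_graph(4)
        spec = {
            "nodes": {nm: dict(kind=n.kind,
                               parents=[g_signed.nodes[p].name for p in n.parents],
                               **({"atom": n.atom_index} if n.kind == "atom_point" else {}),
                               **({"masses": [15.9994, 1.008, 1.008]}
                                  if n.kind == "center_of_mass" else {}))
                      for nm, n in ((n.name, n) for n in g_signed.nodes)},
            "rcs": ["r", "theta1", "theta2", "phi"]}
        spec["nodes"]["phi"]["convention"] = "arccos"
        g_arccos = rg.build_graph(spec)
        xs = make_random_dimer(rng, 200)
        phi_s = rg.evaluate(g_signed, xs)[:, 3]
        phi_a = rg.evaluate(g_arccos, xs)[:, 3]
        assert phi_s.max() > 185.0             # signed range extends past 180
        assert phi_a.max() <= 180.0
        folded = np.where(phi_s > 180.0, 360.0 - phi_s, phi_s)
        np.testing.assert_allclose(folded, phi_a, atol=1e-9)
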