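"""Dirichlet normal energy: hand oracle, invariances, exclusion rules."""

import numpy as np
import pytest

from dentaltopo import (
    DNEOptions, RigidTransform, TriangleMesh,
    compute_dne, make_icosphere, make_plane, polygon_energy, rotate_mesh,
)

# hand-computed 2x2 oracle: unit right triangle with normals tilted 45
# degrees along each leg gives G = I, H diagonal entries 0.5 + (1/sqrt2 - 1)^2,
# off-diagonal (1/sqrt2 - 1)^2, so e = tr(H) = 4 - 2*sqrt(2)
COORDS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
NORMALS = np.array([
    [0, 0, 1],
    [1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
    [0, 1 / np.sqrt(2), 1 / np.sqrt(2)],
])
E_EXPECTED = 4 - 2 * np.sqrt(2)  # = 1.1715728752538097


class TestPolygonEnergy:
    def test_hand_computed_example(self):
        e, cond = polygon_energy(COORDS, NORMALS)
        assert e == pytest.approx(E_EXPECTED, rel=1e-12)
        assert cond == pytest.approx(1.0)

    def test_identical_normals_zero_energy(self, rng):
        coords = rng.normal(size=(3, 3))
        n = np.tile([0.0, 0.0, 1.0], (3, 1))
        e, _ = polygon_energy(coords, n)
        assert e == pytest.approx(0.0, abs=1e-15)

    def test_invariant_under_cyclic_vertex_permutation(self, rng):
        for _ in range(20):
            coords = rng.normal(size=(3, 3))
            n = rng.normal(size=(3, 3))
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            e0, _ = polygon_energy(coords, n)
            e1, _ = polygon_energy(coords[[1, 2, 0]], n[[1, 2, 0]])
            e2, _ = polygon_energy(coords[[2, 0, 1]], n[[2, 0, 1]])
            assert e1 == pytest.approx(e0, rel=1e-9)
            assert e2 == pytest.approx(e0, rel=1e-9)

    def test_invariant_under_edge_basis_change(self, rng):
        # e(p) = tr(G^-1 H) is invariant to any affine reparametrization
        # of the edge basis; check with edges taken from vertex 1
        for _ in range(100):
            coords = rng.normal(size=(3, 3))
            n = rng.normal(size=(3, 3))
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            e0, _ = polygon_energy(coords, n)
            u, v = coords[2] - coords[1], coords[0] - coords[1]
            nu, nv = n[2] - n[1], n[0] - n[1]
            G = np.array([[u @ u, u @ v], [u @ v, v @ v]])
            H = np.array([[nu @ nu, nu @ nv], [nu @ nv, nv @ nv]])
            e1 = np.trace(np.linalg.solve(G, H))
            assert e1 == pytest.approx(e0, rel=1e-9)

    def test_collinear_triangle_flagged_singular(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        e, cond = polygon_energy(coords, NORMALS)
        assert np.isinf(cond)
        assert np.isnan(e)


class TestComputeDNE:
    def test_flat_plane_zero(self, flat_plane):
        res = compute_dne(flat_plane, DNEOptions(outlier_discard=False))
        assert res.total_dne == pytest.approx(0.0, abs=1e-12)

    def test_sphere_converges_to_8pi(self):
        opts = DNEOptions(outlier_discard=False)
        errs = [abs(compute_dne(make_icosphere(k), opts).total_dne - 8 * np.pi)
                for k in (2, 3, 4)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] / (8 * np.pi) < 0.02

    def test_scaling_invariance(self, icosphere3):
        opts = DNEOptions(outlier_discard=False)
        base = compute_dne(icosphere3, opts).total_dne
        for s in (0.1, 2.0, 10.0):
            scaled = TriangleMesh(icosphere3.vertices * s, icosphere3.faces)
            assert compute_dne(scaled, opts).total_dne == pytest.approx(
                base, rel=1e-9)

    def test_rotation_invariance(self, icosphere3, rng):
        opts = DNEOptions(outlier_discard=False)
        base = compute_dne(icosphere3, opts).total_dne
        t = RigidTransform(*rng.uniform(0, 360, 3))
        rot = compute_dne(rotate_mesh(icosphere3, t), opts).total_dne
        assert rot == pytest.approx(base, rel=1e-6)

    def test_total_is_sum_of_included_energies(self, hemisphere3):
        res = compute_dne(hemisphere3, DNEOptions())
        inc = res.included
        assert res.total_dne == pytest.approx(
            float((res.energy_density[inc] * res.face_area[inc]).sum()),
            rel=1e-9)
        assert (res.energy_density >= 0).all()

    def test_boundary_faces_excluded_on_open_mesh(self, hemisphere3):
        res = compute_dne(hemisphere3, DNEOptions(outlier_discard=False))
        assert (res.exclusion_reason == "boundary").sum() > 0
        no_discard = compute_dne(
            hemisphere3, DNEOptions(boundary_discard=False,
                                    outlier_discard=False))
        assert (no_discard.exclusion_reason == "boundary").sum() == 0

    def test_outlier_discard_never_increases_total(self, rng):
        sphere = make_icosphere(3)
        radial = sphere.vertices / np.linalg.norm(sphere.vertices, axis=1,
                                                  keepdims=True)
        noisy = TriangleMesh(
            sphere.vertices + radial * rng.normal(0, 0.01, (sphere.vertex_count, 1)),
            sphere.faces)
        with_out = compute_dne(noisy, DNEOptions(outlier_discard=True)).total_dne
        without = compute_dne(noisy, DNEOptions(outlier_discard=False)).total_dne
        assert with_out <= without

    @pytest.mark.parametrize("basis", ["energy", "energy_density"])
    def test_outlier_basis_modes_run(self, basis, icosphere3):
        res = compute_dne(icosphere3, DNEOptions(outlier_basis=basis))
        assert res.total_dne > 0

    def test_raising_condition_threshold_never_drops_faces(self, rng):
        sphere = make_icosphere(2)
        noisy = TriangleMesh(
            sphere.vertices + rng.normal(0, 0.01, sphere.vertices.shape),
            sphere.faces)
        counts = []
        for thr in (1e1, 1e3, 1e5):
            res = compute_dne(noisy, DNEOptions(condition_threshold=thr,
                                                outlier_discard=False))
            counts.append(int(res.included.sum()))
        assert counts[0] <= counts[1] <= counts[2]

    def test_all_excluded_raises(self):
        # single triangle: every face is a boundary face
        mesh = TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
                            np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="no faces survive"):
            compute_dne(mesh, DNEOptions())

    def test_resolution_dependence_on_noisy_spheres(self, rng):
        # noisier claim: for noisy scans, more polygons -> more DNE
        opts = DNEOptions(outlier_discard=False)
        totals = []
        for k in (2, 3):
            sphere = make_icosphere(k)
            radial = sphere.vertices / np.linalg.norm(
                sphere.vertices, axis=1, keepdims=True)
            noisy = TriangleMesh(
                sphere.vertices + radial * rng.normal(
                    0, 0.02, (sphere.vertex_count, 1)),
                sphere.faces)
            totals.append(compute_dne(noisy, opts).total_dne)
        assert totals[1] > totals[0]
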