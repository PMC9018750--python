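import numpy as np
import pytest

from omtcube.density import DensityField
from omtcube.mesh import TetMesh, build_tet_mesh, normalize_complex
from omtcube.surface import PLMap
from omtcube.volume import (
    boundary_cost,
    distortion_diagnostics,
    homotopy_boundary,
    mass_laplacian,
    transport_cost,
    volume_omt,
)


def regular_tet_mesh():
    """Single regular unit-edge tetrahedron wrapped as a TetMesh."""
    verts = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
        ]
    )
    return TetMesh(
        vertices=verts,
        tets=np.array([[0, 1, 2, 3]]),
        spacing=np.ones(3),
        grid_shape=(1, 1, 1),
        voxel_of_vertex=np.zeros((4, 3), dtype=np.int64),
    )


def mass_laplacian_entry_oracle(verts, i, j, rho_tau, vol):
    """Independent scalar evaluation of the off-diagonal weight on one tet:
    -(1/9) |f([v_i,v_l,v_m])| |f([v_j,v_m,v_l])| cos(theta) / (rho |tau|),
    with theta the dihedral angle between the two faces along edge (l, m)."""
    l, m = [k for k in range(4) if k not in (i, j)]
    tri_i = verts[[i, l, m]]
    tri_j = verts[[j, m, l]]

    def area(t):
        return 0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0]))

    # dihedral angle along the shared edge (l, m)
    e = verts[m] - verts[l]
    e /= np.linalg.norm(e)
    u = verts[i] - verts[l]
    v = verts[j] - verts[l]
    u -= np.dot(u, e) * e
    v -= np.dot(v, e) * e
    cos_theta = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return -(1.0 / 9.0) * area(tri_i) * area(tri_j) * cos_theta / (rho_tau * vol)


class TestHomotopyBoundary:
    def test_endpoints_and_midpoint(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((10, 3))
        g = rng.standard_normal((10, 3))
        np.testing.assert_array_equal(homotopy_boundary(g, v, 0.0), v)
        np.testing.assert_array_equal(homotopy_boundary(g, v, 1.0), g)
        np.testing.assert_allclose(
            homotopy_boundary(g, v, 0.5), (v + g) / 2, atol=1e-16
        )

    def test_zeta_out_of_range(self):
        v = np.zeros((2, 3))
        with pytest.raises(ValueError):
            homotopy_boundary(v, v, 1.5)


class TestMassLaplacian:
    def test_regular_tet_matches_hand_evaluation(self):
        mesh = regular_tet_mesh()
        rho = DensityField.uniform(mesh)
        L = mass_laplacian(mesh.vertices, mesh, rho).toarray()
        vol = mesh.tet_volumes()[0]
        for i in range(4):
            for j in range(i + 1, 4):
                expected = mass_laplacian_entry_oracle(mesh.vertices, i, j, 1.0, vol)
                assert L[i, j] == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_zero_rowsums(self):
        mesh = build_tet_mesh(np.ones((3, 3, 2), dtype=bool))
        rng = np.random.default_rng(0)
        rho = DensityField(rng.uniform(0.5, 2.0, mesh.n_vertices))
        f = mesh.vertices + 0.1 * rng.standard_normal(mesh.vertices.shape)
        L = mass_laplacian(f, mesh, rho)
        assert abs(L - L.T).max() < 1e-12
        assert np.abs(L.sum(axis=1)).max() < 1e-12

    def test_distorted_image_matches_oracle(self):
        mesh = regular_tet_mesh()
        rng = np.random.default_rng(3)
        f = mesh.vertices + 0.2 * rng.standard_normal((4, 3))
        rho = DensityField(np.full(4, 1.7))
        L = mass_laplacian(f, mesh, rho).toarray()
        vol = mesh.tet_volumes()[0]
        for i in range(4):
            for j in range(i + 1, 4):
                expected = mass_laplacian_entry_oracle(f, i, j, 1.7, vol)
                assert L[i, j] == pytest.approx(expected, rel=1e-10)


class TestTransportCost:
    def test_identity_zero(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        assert transport_cost(mesh.vertices, mesh, rho) == 0.0

    def test_translation_cost_is_norm_squared(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        t = np.array([0.3, -0.2, 0.7])
        cost = transport_cost(mesh.vertices + t, mesh, rho)
        assert cost == pytest.approx(np.dot(t, t), rel=1e-12)

    def test_boundary_translation(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        B = mesh.boundary_vertex_ids
        t = np.array([0.1, 0.2, -0.3])
        from omtcube.density import simplex_measures

        total_area_mass = simplex_measures(mesh, rho).local_area.sum()
        cost = boundary_cost(mesh.vertices[B] + t, mesh, rho)
        assert cost == pytest.approx(np.dot(t, t) * total_area_mass, rel=1e-12)


class TestDistortionDiagnostics:
    def test_uniform_scaling_ratio(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        s = 1.3
        rep = distortion_diagnostics(mesh.vertices * s, mesh, rho)
        assert rep.local_ratio_mean == pytest.approx(s**-3, rel=1e-10)
        assert rep.folding_count == 0

    def test_reflection_counts_all_folds(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        f = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        rep = distortion_diagnostics(f, mesh, rho)
        assert rep.folding_count == mesh.n_tets

    def test_exact_preservation_zero_distortion(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        rep = distortion_diagnostics(mesh.vertices, mesh, rho)
        # identity image: |f(tau)| = |tau| but rho(tau)|tau| uses the
        # vertex-averaged density, exactly 1 here
        assert rep.total_mass_distortion == pytest.approx(0.0, abs=1e-12)
        assert rep.local_ratio_median == pytest.approx(1.0, rel=1e-12)


class TestVolumeOmt:
    def test_selfmap_quality(self, cube_selfmap):
        rep = cube_selfmap["report"]
        assert rep.transport_cost <= 1e-3
        assert rep.folding_count == 0
        assert 0.98 <= rep.local_ratio_median <= 1.02

    def test_boundary_pinned_exactly(self, cube_selfmap, phantom_subject):
        mesh = cube_selfmap["mesh"]
        fmap = cube_selfmap["fmap"]
        rho = cube_selfmap["rho"]
        from omtcube.surface import cube_boundary_aomt

        gstar = cube_boundary_aomt(mesh, rho)
        np.testing.assert_array_equal(
            fmap.coords[mesh.boundary_vertex_ids], gstar.coords
        )

    def test_interior_residual_small(self, cube_selfmap):
        mesh, rho, fmap = (
            cube_selfmap["mesh"],
            cube_selfmap["rho"],
            cube_selfmap["fmap"],
        )
        L = mass_laplacian(fmap.coords, mesh, rho)
        I = mesh.interior_vertex_ids
        B = mesh.boundary_vertex_ids
        res = L[I][:, I] @ fmap.coords[I] + L[I][:, B] @ fmap.coords[B]
        # f solves the system assembled at the previous iterate; at
        # convergence of the homotopy the self-residual stays small
        rhs = np.linalg.norm(L[I][:, B] @ fmap.coords[B])
        assert np.linalg.norm(res) / rhs < 1e-2

    def test_homotopy_trace_recorded(self, cube_selfmap):
        rep = cube_selfmap["report"]
        assert len(rep.homotopy_trace) == 11
        assert rep.homotopy_trace[-1]["zeta"] == 1.0

    def test_image_volume_near_one(self, uniform_map_products):
        rep = uniform_map_products["report"]
        assert rep.image_volume == pytest.approx(1.0, rel=0.02)

    def test_invalid_p(self, cube_selfmap):
        mesh, rho = cube_selfmap["mesh"], cube_selfmap["rho"]
        with pytest.raises(ValueError):
            volume_omt(mesh, rho, PLMap(coords=np.zeros((1, 3))), p=0)
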