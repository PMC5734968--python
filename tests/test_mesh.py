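"""Mesh stage: grid construction, energy minimization, per-cell homographies,
lambda selection and coarse warping."""

import warnings

import numpy as np
import pytest

from meshffd.errors import ValidationError
from meshffd.homography import (apply_homography, similarity_homography,
                                translation_homography)
from meshffd.image import compute_metrics
from meshffd.mesh import (MeshEnergyConfig, bilinear_weights, build_mesh,
                          cell_homography, coarse_warp, compose_final,
                          energy_terms, lambda_grid, select_lambda, solve_mesh)
from meshffd.synthetic import (CorrespondenceSet, homography_warp,
                               make_correspondences, make_texture,
                               random_homography)


class TestLambdaGrid:
    def test_default_grid_is_ten_steps_of_point_three(self):
        g = lambda_grid()
        assert len(g) == 10
        assert np.allclose(g, 0.3 + 0.3 * np.arange(10))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValidationError):
            lambda_grid(0.0, 3.0, 10)


class TestBuildMesh:
    def test_square_image_regular_grid(self):
        mesh = build_mesh(64, 64, 16)
        assert (mesh.n_cols, mesh.n_rows) == (4, 4)
        assert mesh.vertices.shape == (5, 5, 2)
        assert np.allclose(mesh.xs, [0, 16, 32, 48, 64])

    def test_single_cell_image(self):
        mesh = build_mesh(16, 16, 16)
        assert (mesh.n_cols, mesh.n_rows) == (1, 1)

    def test_partial_boundary_cells(self):
        mesh = build_mesh(70, 64, 16)
        assert mesh.n_cols == 5
        assert mesh.xs[-1] - mesh.xs[-2] == 6.0

    def test_small_beta_rejected(self):
        with pytest.raises(ValidationError):
            build_mesh(64, 64, 3)


class TestBilinearWeights:
    @pytest.mark.parametrize("p,expected", [
        ((0.0, 0.0), (1, 0, 0, 0)),           # top-left corner
        ((8.0, 8.0), (0.25, 0.25, 0.25, 0.25)),  # center
        ((8.0, 0.0), (0.5, 0.5, 0, 0)),       # top-edge midpoint
    ])
    def test_reference_points(self, p, expected):
        w = bilinear_weights(p, (0, 16, 0, 16))
        assert np.allclose(w, expected)

    def test_weights_sum_to_one_and_reproduce_point(self, rng):
        mesh = build_mesh(64, 64, 16)
        for _ in range(50):
            p = rng.uniform(0, 63.99, 2)
            j, k = mesh.cell_of(*p)
            w = bilinear_weights(p, mesh.cell_bounds(j, k))
            assert abs(w.sum() - 1.0) < 1e-12
            corners = [mesh.vertices[ix, iy] for ix, iy in mesh.corner_indices(j, k)]
            assert np.allclose(sum(wi * c for wi, c in zip(w, corners)), p)

    def test_outside_cell_rejected(self):
        with pytest.raises(ValidationError):
            bilinear_weights((20.0, 0.0), (0, 16, 0, 16))


class TestSolveMesh:
    def test_no_correspondences_returns_reference(self):
        mesh = build_mesh(64, 64, 16)
        cs = CorrespondenceSet(np.zeros((0, 2)), np.zeros((0, 2)))
        warped = solve_mesh(cs, np.eye(3), mesh, 1.0)
        assert np.allclose(warped, mesh.vertices, atol=1e-6)

    def test_exact_translation_moves_every_vertex(self):
        mesh = build_mesh(64, 64, 16)
        w = homography_warp(translation_homography(5, -3), (64, 64))
        cs = make_correspondences(w, 60, 0.0, 0, seed=1, size=(64, 64))
        warped = solve_mesh(cs, np.eye(3), mesh, 1.0)
        assert np.allclose(warped, mesh.vertices + [5.0, -3.0], atol=1e-3)
        ed, ec = energy_terms(mesh, warped, cs, np.eye(3))
        assert ed + ec < 1e-8

    def test_similarity_transform_nulls_both_terms(self):
        # rotation + isotropic scale leaves the shape constraint at zero
        mesh = build_mesh(64, 64, 16)
        S = similarity_homography(10.0, 1.05, 2.0, -1.0)
        cs = make_correspondences(homography_warp(S, (64, 64)), 60, 0.0, 0,
                                  seed=2, size=(64, 64))
        truth = apply_homography(S, mesh.vertices.reshape(-1, 2)).reshape(
            mesh.vertices.shape)
        for lam in lambda_grid():
            warped = solve_mesh(cs, np.eye(3), mesh, lam)
            ed, ec = energy_terms(mesh, warped, cs, np.eye(3))
            assert ed + lam * ec < 1e-6
            assert np.abs(warped - truth).max() < 1e-3

    def test_constraint_energy_monotone_in_lambda(self):
        mesh = build_mesh(96, 96, 16)
        H = random_homography(5, 10.0, (96, 96))
        cs = make_correspondences(homography_warp(H, (96, 96)), 80, 1.0, 0,
                                  seed=3, size=(96, 96))
        ecs = []
        for lam in lambda_grid():
            warped = solve_mesh(cs, np.eye(3), mesh, lam)
            ecs.append(energy_terms(mesh, warped, cs, np.eye(3))[1])
        assert all(b <= a + 1e-9 for a, b in zip(ecs, ecs[1:]))


class TestCellHomography:
    square = np.array([[0, 0], [16, 0], [16, 16], [0, 16]], float)

    def test_identity(self):
        H = cell_homography(self.square, self.square)
        assert np.allclose(H, np.eye(3), atol=1e-10)

    def test_translation(self):
        H = cell_homography(self.square, self.square + [5.0, 0.0])
        assert np.allclose(H, translation_homography(5, 0), atol=1e-9)

    def test_projective_round_trip(self):
        Ht = random_homography(8, 3.0, (16, 16))
        warped = apply_homography(Ht, self.square)
        H = cell_homography(self.square, warped)
        assert np.allclose(apply_homography(H, self.square), warped, atol=1e-9)


class TestComposeFinal:
    def test_identity_cases(self):
        H = random_homography(2, 5.0, (64, 64))
        assert np.allclose(compose_final(np.eye(3), H), H / H[2, 2])
        assert np.allclose(compose_final(H, np.eye(3)), H / H[2, 2])

    def test_composed_map_reproduces_matched_corners(self):
        # end-to-end: exact synthetic data, the composed per-cell map must
        # send each reference corner to its true float position
        size = (64, 64)
        Hg = random_homography(3, 4.0, size)
        mesh = build_mesh(*size, 16)
        cs = make_correspondences(homography_warp(Hg, size), 80, 0.0, 0,
                                  seed=4, size=size)
        warped = solve_mesh(cs, Hg, mesh, 0.3)
        for (j, k) in [(0, 0), (2, 1), (3, 3)]:
            ids = mesh.corner_indices(j, k)
            ref_c = np.array([mesh.vertices[ix, iy] for ix, iy in ids])
            war_c = np.array([warped[ix, iy] for ix, iy in ids])
            Hjk = compose_final(cell_homography(ref_c, war_c), Hg)
            expect = apply_homography(Hg, ref_c)
            assert np.allclose(apply_homography(Hjk, ref_c), expect, atol=1e-4)


class TestSelectLambda:
    def test_identity_truth_wins_everywhere(self, texture64):
        mesh = build_mesh(64, 64, 16)
        sols = [(lam, mesh.vertices.copy()) for lam in (0.3, 1.0)]
        lm = select_lambda(sols, texture64, texture64, np.eye(3), mesh)
        assert np.all(lm.score > 1 - 1e-6)
        assert np.allclose(lm.maps, np.eye(3), atol=1e-8)

    def test_single_lambda_is_passthrough(self, texture64):
        mesh = build_mesh(64, 64, 16)
        sols = [(0.9, mesh.vertices.copy())]
        lm = select_lambda(sols, texture64, texture64, np.eye(3), mesh)
        assert np.all(lm.chosen_lambda == 0.9)

    def test_global_mode_selects_one_lambda(self, texture64):
        mesh = build_mesh(64, 64, 16)
        sols = [(lam, mesh.vertices.copy()) for lam in (0.3, 1.0)]
        lm = select_lambda(sols, texture64, texture64, np.eye(3), mesh,
                           mode="global")
        assert len(np.unique(lm.chosen_lambda)) == 1

    def test_shared_vertices_give_consistent_adjacent_maps(self, texture64):
        # within one solution, adjacent cells' composed maps agree at their
        # shared corners
        size = (64, 64)
        Hg = random_homography(3, 4.0, size)
        mesh = build_mesh(*size, 16)
        cs = make_correspondences(homography_warp(Hg, size), 80, 0.0, 0,
                                  seed=4, size=size)
        sols = [(0.3, solve_mesh(cs, Hg, mesh, 0.3))]
        flt, _ = coarse_warp(texture64, select_lambda(
            sols, texture64, texture64, Hg, mesh), size)
        lm = select_lambda(sols, texture64, texture64, Hg, mesh)
        for j in range(mesh.n_cols - 1):
            for k in range(mesh.n_rows):
                shared = np.array([mesh.vertices[j + 1, k],
                                   mesh.vertices[j + 1, k + 1]])
                a = apply_homography(lm.maps[j, k], shared)
                b = apply_homography(lm.maps[j + 1, k], shared)
                assert np.allclose(a, b, atol=1e-6)


class TestCoarseWarp:
    def _identity_maps(self, mesh):
        sols = [(0.3, mesh.vertices.copy())]
        tex = make_texture(30, mesh.width, mesh.height)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return select_lambda(sols, tex, tex, np.eye(3), mesh)

    def test_identity_maps_are_bit_exact(self, texture64):
        mesh = build_mesh(64, 64, 16)
        out, valid = coarse_warp(texture64, self._identity_maps(mesh), (64, 64))
        assert np.array_equal(out, texture64)
        assert valid.all()

    def test_global_homography_truth_recovers_reference(self):
        size = (128, 128)
        tex = make_texture(31, *size)
        Hg = random_homography(6, 5.0, size)
        warp = homography_warp(Hg, size)
        from meshffd.image import warp_backward
        ref, _ = warp_backward(tex, warp.mapping)
        cs = make_correspondences(warp, 200, 0.0, 0, seed=5, size=size)
        mesh = build_mesh(*size, 16)
        sols = [(0.3, solve_mesh(cs, Hg, mesh, 0.3))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lm = select_lambda(sols, ref, tex, Hg, mesh)
        out, valid = coarse_warp(tex, lm, size)
        interior = np.zeros_like(valid)
        interior[16:-16, 16:-16] = True
        sel = valid & interior
        assert ((out[sel] - ref[sel]) ** 2).mean() < 1e-3
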