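"""Fine stage: B-spline basis, FFD transform, bending energy, localized NMI
and the descent optimizer."""

import numpy as np
import pytest

from meshffd.errors import ValidationError
from meshffd.ffd import (ControlLattice, FFDConfig, bending_energy,
                         bspline_basis, cost, ffd_transform, fine_warp,
                         local_nmi, optimize)
from meshffd.image import compute_metrics, warp_backward
from meshffd.synthetic import make_texture


def displaced_lattice(width, height, delta, displacements):
    """Identity lattice with selected controls displaced; displacements is
    a dict (a, b) -> (dx, dy) in array indices."""
    lat = ControlLattice.identity(width, height, delta)
    lat.points = lat.points.copy()
    for (a, b), d in displacements.items():
        lat.points[a, b] += np.asarray(d, dtype=float)
    return lat


class TestBasis:
    def test_closed_form_values(self):
        assert np.allclose(bspline_basis(0.0), [1 / 6, 2 / 3, 1 / 6, 0.0])
        assert np.allclose(bspline_basis(0.5), [1 / 48, 23 / 48, 23 / 48, 1 / 48])

    def test_partition_of_unity_on_dense_grid(self):
        for u in np.arange(0.0, 1.0, 0.01):
            assert abs(bspline_basis(u).sum() - 1.0) < 1e-14

    def test_domain_validation(self):
        with pytest.raises(ValidationError):
            bspline_basis(1.0)


class TestTransform:
    def test_identity_lattice_maps_points_to_themselves(self, rng):
        lat = ControlLattice.identity(64, 64, 4)
        pts = np.column_stack([rng.uniform(0, 63, 50), rng.uniform(0, 63, 50)])
        assert np.abs(ffd_transform(lat, pts) - pts).max() < 1e-9

    def test_uniform_shift_translates(self, rng):
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points + [2.0, -1.0]
        pts = np.column_stack([rng.uniform(0, 63, 20), rng.uniform(0, 63, 20)])
        assert np.allclose(ffd_transform(lat, pts), pts + [2.0, -1.0], atol=1e-9)

    def test_affine_precision(self, rng):
        A = np.array([[1.04, 0.03], [-0.02, 0.97]])
        t = np.array([1.5, -2.0])
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points @ A.T + t
        pts = np.column_stack([rng.uniform(0, 63, 40), rng.uniform(0, 63, 40)])
        assert np.abs(ffd_transform(lat, pts) - (pts @ A.T + t)).max() < 1e-9

    def test_out_of_domain_rejected(self):
        lat = ControlLattice.identity(64, 64, 4)
        with pytest.raises(ValidationError):
            ffd_transform(lat, [[70.0, 3.0]])

    def test_locality_of_one_control(self, rng):
        # perturbing control (i, j) only moves points inside its 4*delta support
        delta = 4
        lat = ControlLattice.identity(48, 48, delta)
        a, b = 6, 5
        i, j = a - 1, b - 1
        lat2 = lat.copy()
        lat2.points[a, b] += [1.0, 0.5]
        ys, xs = np.mgrid[0:48, 0:48]
        pts = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
        moved = np.abs(ffd_transform(lat2, pts) - ffd_transform(lat, pts)).max(axis=1)
        inside = ((pts[:, 0] >= (i - 2) * delta) & (pts[:, 0] < (i + 2) * delta)
                  & (pts[:, 1] >= (j - 2) * delta) & (pts[:, 1] < (j + 2) * delta))
        assert np.all(moved[~inside] == 0.0)
        assert moved[inside].max() > 0.0

    def test_lattice_csv_round_trip(self, tmp_path):
        lat = ControlLattice.identity(32, 24, 4)
        lat.points = lat.points + np.random.default_rng(0).normal(0, 1, lat.points.shape)
        p = tmp_path / "lattice.csv"
        lat.to_csv(p)
        back = ControlLattice.from_csv(p)
        assert back.delta == lat.delta
        assert np.allclose(back.points, lat.points)


class TestBendingEnergy:
    def test_identity_is_flat(self):
        assert bending_energy(ControlLattice.identity(64, 64, 4)) < 1e-12

    def test_affine_lattices_are_flat(self):
        lat = ControlLattice.identity(64, 64, 4)
        A = np.array([[1.1, 0.05], [-0.03, 0.9]])
        lat.points = lat.points @ A.T + [3.0, -1.0]
        assert bending_energy(lat) < 1e-10

    def test_matches_finite_difference_quadrature(self):
        # oracle: second differences of the realized dense field
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points.copy()
        lat.points[8, 8] += [1.0, 0.0]
        ys, xs = np.mgrid[1:63, 1:63]
        pts = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
        # knot discontinuities of T''' make the difference converge only
        # linearly in h, so h must be small
        h = 0.025

        def T(q):
            return ffd_transform(lat, q)

        txx = (T(pts + [h, 0]) - 2 * T(pts) + T(pts - [h, 0])) / h ** 2
        tyy = (T(pts + [0, h]) - 2 * T(pts) + T(pts - [0, h])) / h ** 2
        txy = (T(pts + [h, h]) - T(pts + [h, -h]) - T(pts + [-h, h])
               + T(pts + [-h, -h])) / (4 * h ** 2)
        oracle = (txx ** 2 + 2 * txy ** 2 + tyy ** 2).sum() / (64 * 64)
        # the displaced control sits far from the 1-px border the oracle skips
        assert bending_energy(lat) == pytest.approx(oracle, rel=0.01)


class TestLocalNMI:
    def test_identical_images_at_identity_pvi_is_perfect(self, texture64):
        lat = ControlLattice.identity(64, 64, 4)
        v = local_nmi(texture64, texture64, lat, (8, 8), FFDConfig(), method="pvi")
        assert v == pytest.approx(2.0)

    def test_soft_binning_orders_dependence(self, texture64, rng):
        # identical > monotone remap > spatially shuffled
        lat = ControlLattice.identity(64, 64, 4)
        cfg = FFDConfig()
        same = local_nmi(texture64, texture64, lat, (8, 8), cfg)
        remap = local_nmi(texture64, np.sqrt(texture64), lat, (8, 8), cfg)
        shuffled = texture64.copy().ravel()
        rng.shuffle(shuffled)
        shuf = local_nmi(texture64, shuffled.reshape(64, 64), lat, (8, 8), cfg)
        assert same >= remap >= shuf

    def test_shuffled_images_near_independence(self, texture64, rng):
        lat = ControlLattice.identity(64, 64, 4)
        shuffled = texture64.copy().ravel()
        rng.shuffle(shuffled)
        v = local_nmi(texture64, shuffled.reshape(64, 64), lat, (8, 8),
                      FFDConfig(), method="pvi")
        # 256 sites over 1024 cells bias the estimate upward
        assert abs(v - 1.0) < 0.2

    def test_off_image_neighborhood_skipped(self, texture64):
        lat = ControlLattice.identity(64, 64, 4)
        assert local_nmi(texture64, texture64, lat, (40, 40), FFDConfig()) is None


class TestCost:
    def test_consistency_with_local_nmi_mean(self, texture64, texture64b):
        from meshffd.ffd import _CostEvaluator
        cfg = FFDConfig(delta=4)
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points + np.random.default_rng(2).uniform(
            -0.8, 0.8, lat.points.shape)
        c = cost(texture64, texture64b, lat, cfg)
        ev = _CostEvaluator(texture64, texture64b, cfg)
        vals = [local_nmi(texture64, texture64b, lat, (a - 1, b - 1), cfg)
                for (a, b) in ev.nmi_controls]
        expect = -np.mean(vals) + cfg.mu * bending_energy(lat)
        assert c == pytest.approx(expect, abs=1e-12)

    def test_zero_mu_is_pure_similarity(self, texture64):
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points.copy()
        lat.points[8, 8] += [1.0, 0.0]
        c0 = cost(texture64, texture64, lat, FFDConfig(mu=0.0))
        c1 = cost(texture64, texture64, lat, FFDConfig(mu=0.5))
        assert c1 > c0  # bending penalty only adds

    def test_perturbation_increases_cost_on_identical_images(self, texture64):
        cfg = FFDConfig(delta=4)
        idl = ControlLattice.identity(64, 64, 4)
        c_id = cost(texture64, texture64, idl, cfg)
        pert = idl.copy()
        pert.points = pert.points + np.random.default_rng(5).uniform(
            -0.3, 0.3, pert.points.shape)
        assert cost(texture64, texture64, pert, cfg) > c_id


@pytest.fixture(scope="module")
def recovery_run():
    """One optimize() run on a single-control displacement, reused below."""
    moving = make_texture(6, 64, 64)
    true_lat = displaced_lattice(64, 64, 4, {(9, 8): (1.5, 0.8)})
    ref, _ = warp_backward(moving, lambda p: ffd_transform(true_lat, p))
    res = optimize(ref, moving, FFDConfig(delta=4, max_iters=40))
    return moving, true_lat, ref, res


class TestOptimize:
    def test_already_registered_stays_near_identity(self, texture64):
        res = optimize(texture64, texture64, FFDConfig(delta=4, max_iters=8))
        dev = np.abs(res.lattice.points
                     - ControlLattice.identity(64, 64, 4).points).max()
        assert dev < 0.2
        tr = np.array(res.cost_trace)
        assert np.all(np.diff(tr) <= 1e-12)

    def test_single_control_recovery(self, recovery_run):
        _, true_lat, _, res = recovery_run
        tr = np.array(res.cost_trace)
        assert tr[-1] < tr[0]                      # cost decreased
        assert np.all(np.diff(tr) <= 1e-12)        # monotone with backtracking
        mean_err = np.linalg.norm(res.lattice.points - true_lat.points,
                                  axis=-1).mean()
        assert mean_err < 0.5

    def test_first_step_decreases_cost_without_backtracking(self, recovery_run):
        moving, _, ref, _ = recovery_run
        res = optimize(ref, moving,
                       FFDConfig(delta=4, max_iters=1, backtracking=False,
                                 rho=0.25))
        assert res.cost_trace[-1] < res.cost_trace[0]


class TestFineWarp:
    def test_identity_lattice_is_bit_exact(self, texture64):
        lat = ControlLattice.identity(64, 64, 4)
        out, valid = fine_warp(texture64, lat)
        assert np.array_equal(out, texture64)
        assert valid.all()

    def test_integer_shift_matches_rolled_interior(self, texture64):
        lat = ControlLattice.identity(64, 64, 4)
        lat.points = lat.points + [3.0, 0.0]
        out, valid = fine_warp(texture64, lat)
        assert np.array_equal(out[:, :-3], texture64[:, 3:])
        assert not valid[:, -3:].any()

    def test_recovery_fixture_halves_ssd(self, recovery_run):
        moving, _, ref, res = recovery_run
        out, valid = fine_warp(moving, res.lattice)
        before = compute_metrics(ref, moving, mask=valid).ssd
        after = compute_metrics(ref, out, mask=valid).ssd
        assert after <= 0.5 * before
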