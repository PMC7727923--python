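"""Constrained QP solve: exactness, feasibility invariants, oracle agreement."""

import numpy as np
import pytest

from ctvent.estimators import SubregionEstimate, hu_to_density
from ctvent.grid import Grid, ImageVolume
from ctvent.mls import LinearSystem, build_weight_matrix
from ctvent.sampling import PointSet, Subregion
from ctvent.solver import (
    SolveConfig,
    SolverError,
    _active_set_qp,
    global_constraint_constant,
    solve_ventilation,
    ventilation_signal,
)

from test_mls import _random_instance


def _enumeration_oracle(G, c, a, h, eps):
    """Brute-force QP oracle: try every active set of the bound constraints.

    For each subset S of bounds fixed at eps, solve the equality-constrained
    stationarity system and keep the best primal-dual feasible candidate.
    Independent of the active-set iteration it checks.
    """
    L = len(c)
    best, best_obj = None, np.inf
    for bits in range(2 ** L):
        S = np.array([(bits >> i) & 1 for i in range(L)], dtype=bool)
        F = ~S
        nf = int(F.sum())
        if nf == 0:
            q = np.full(L, eps)
            if abs(a @ q - h) > 1e-9:
                continue
            lam = G @ q - c  # mu unconstrained: pick best-case mu = 0
            obj = 0.5 * q @ G @ q - c @ q
        else:
            KKT = np.zeros((nf + 1, nf + 1))
            KKT[:nf, :nf] = G[np.ix_(F, F)]
            KKT[:nf, nf] = a[F]
            KKT[nf, :nf] = a[F]
            rhs = np.concatenate([c[F] - G[np.ix_(F, S)] @ np.full(int(S.sum()), eps),
                                  [h - a[S] @ np.full(int(S.sum()), eps)]])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError:
                continue
            q = np.full(L, eps)
            q[F] = sol[:nf]
            mu = sol[nf]
            if (q[F] < eps - 1e-9).any():
                continue
            lam = (G @ q - c + mu * a)
            if (lam[S] < -1e-9).any():
                continue
            obj = 0.5 * q @ G @ q - c @ q
        if obj < best_obj:
            best, best_obj = q.copy(), obj
    return best


def _system_from(model, regions_and_b, h):
    row_of = model.row_index()
    A = np.zeros((len(regions_and_b), model.n_knots))
    b = np.empty(len(regions_and_b))
    sizes = np.empty(len(regions_and_b))
    Cd = model.C.toarray()
    for k, (flat, bk) in enumerate(regions_and_b):
        A[k] = Cd[row_of[flat]].sum(axis=0)
        b[k] = bk
        sizes[k] = len(flat)
    return LinearSystem(A_hat=A, b=b, region_sizes=sizes, N=model.n_voxels, h=h)


class TestGlobalConstraint:
    def _masks(self, nT=1000, nR=1000):
        grid = Grid((12, 12, 12), (2.0, 2.0, 2.0))
        mR = np.zeros(grid.shape, bool); mR.ravel()[:nR] = True
        mT = np.zeros(grid.shape, bool); mT.ravel()[:nT] = True
        return grid, ImageVolume(mR, grid), ImageVolume(mT, grid)

    def test_ijf_constant_is_target_volume(self):
        _, mR, mT = self._masks(nT=1000)
        assert global_constraint_constant("IJF", mR, mT) == 1000.0

    def test_mcvc_constant_is_density_ratio_times_volume(self):
        grid, mR, mT = self._masks()
        dR = hu_to_density(ImageVolume(np.full(grid.shape, 0.3 * 1000 - 1000), grid))
        dT = hu_to_density(ImageVolume(np.full(grid.shape, 0.25 * 1000 - 1000), grid),
                           "target")
        h = global_constraint_constant("MCVC", mR, mT, dR, dT)
        assert np.isclose(h, 1200.0)

    def test_identical_images_give_reference_volume(self):
        grid, mR, mT = self._masks()
        d = hu_to_density(ImageVolume(np.full(grid.shape, -700.0), grid))
        h = global_constraint_constant("MCVC", mR, mT, d, d)
        assert np.isclose(h, 1000.0)

    def test_empty_mask_rejected(self):
        grid, mR, _ = self._masks()
        empty = ImageVolume(np.zeros(grid.shape, bool), grid)
        with pytest.raises(ValueError):
            global_constraint_constant("IJF", mR, empty)


class TestSolveVentilation:
    def test_consistent_constant_data_recovered_exactly(self):
        """b_k = c|Omega_k| and h = cN must give q = c to solver precision."""
        mask, knots = _random_instance(seed=11)
        model = build_weight_matrix(mask, knots)
        rng = np.random.default_rng(11)
        c = 1.25
        regions = []
        flat_all = model.voxel_order
        for _ in range(12):
            flat = np.sort(rng.choice(flat_all, size=rng.integers(5, 50),
                                      replace=False))
            regions.append((flat, c * len(flat)))
        system = _system_from(model, regions, h=c * model.n_voxels)
        result = solve_ventilation(system, model, SolveConfig(epsilon=0.05))
        assert np.max(np.abs(result.q - c)) < 1e-8
        assert np.max(np.abs(result.v_values - c)) < 1e-8
        assert result.residual_norm < 1e-8

    def test_matches_active_set_enumeration_oracle(self):
        """Random small QPs: iterative active set vs exhaustive enumeration."""
        rng = np.random.default_rng(0)
        for trial in range(25):
            L = 4
            A = rng.normal(size=(10, L))
            b = rng.normal(size=10)
            lam = 10.0 ** rng.uniform(-2, 1)
            a = rng.uniform(0.5, 2.0, size=L)
            eps = 0.05
            h = float(eps * a.sum() * rng.uniform(1.05, 3.0))
            G = 2.0 * (A.T @ A + lam * np.eye(L))
            c = 2.0 * (A.T @ b + lam * (h / a.sum()) * np.ones(L))
            q, _, _ = _active_set_qp(G, c, a, h, eps, 200)
            q_oracle = _enumeration_oracle(G, c, a, h, eps)
            assert q_oracle is not None
            assert np.max(np.abs(q - q_oracle)) < 1e-6
            assert abs(a @ q - h) < 1e-8 and (q >= eps - 1e-10).all()

    def test_floor_pinned_solution(self):
        """epsilon * N == h leaves q == epsilon as the only feasible point."""
        mask, knots = _random_instance(seed=12)
        model = build_weight_matrix(mask, knots)
        N = model.n_voxels
        eps = 0.05
        regions = [(model.voxel_order[:50], 100.0)] * 6
        system = _system_from(model, regions, h=eps * N)
        result = solve_ventilation(system, model, SolveConfig(epsilon=eps))
        assert np.allclose(result.q, eps)
        assert np.allclose(result.v_values, eps)

    def test_infeasible_configuration_raises(self):
        mask, knots = _random_instance(seed=13)
        model = build_weight_matrix(mask, knots)
        regions = [(model.voxel_order[:30], 40.0)] * 6
        system = _system_from(model, regions, h=0.01 * model.n_voxels)
        with pytest.raises(SolverError, match="epsilon"):
            solve_ventilation(system, model, SolveConfig(epsilon=0.05))

    def test_invariants_on_random_solves(self):
        """Positivity and global-volume consistency hold on every solve."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            mask, knots = _random_instance(seed=20 + trial)
            model = build_weight_matrix(mask, knots)
            regions = []
            for _ in range(15):
                flat = np.sort(rng.choice(model.voxel_order,
                                          size=rng.integers(3, 60), replace=False))
                regions.append((flat, len(flat) * rng.uniform(0.2, 3.0)))
            h = model.n_voxels * rng.uniform(0.8, 1.5)
            system = _system_from(model, regions, h=h)
            result = solve_ventilation(system, model, SolveConfig(epsilon=0.05))
            assert (result.q >= 0.05 - 1e-10).all()
            assert (result.v_values > 0).all()
            assert abs(result.v_values.sum() - h) <= 1e-6 * h

    def test_weaker_regularization_fits_no_worse(self):
        """The data-fit term of the optimum is monotone in lambda."""
        mask, knots = _random_instance(seed=30)
        model = build_weight_matrix(mask, knots)
        rng = np.random.default_rng(30)
        regions = []
        for _ in range(12):
            flat = np.sort(rng.choice(model.voxel_order, size=rng.integers(5, 40),
                                      replace=False))
            regions.append((flat, len(flat) * rng.uniform(0.5, 2.0)))
        system = _system_from(model, regions, h=float(model.n_voxels))
        fits = []
        for lam in (4.0, 1.0, 0.25):
            res = solve_ventilation(system, model,
                                    SolveConfig(epsilon=0.05, lambda_reg=lam))
            fits.append(res.residual_norm)
        assert fits[0] >= fits[1] >= fits[2] - 1e-12


class TestVentilationSignal:
    def test_unit_jacobian_gives_zero_signal(self):
        grid = Grid((4, 4, 4), (1, 1, 1))
        V = ImageVolume(np.ones(grid.shape), grid)
        assert np.allclose(ventilation_signal(V).data, 0.0)

    def test_direction_conventions(self):
        grid = Grid((4, 4, 4), (1, 1, 1))
        V = ImageVolume(np.full(grid.shape, 1.2), grid)
        assert np.allclose(ventilation_signal(V, "reference_is_exhale").data, 0.2)
        assert np.allclose(ventilation_signal(V, "reference_is_inhale").data, -0.2)
        with pytest.raises(ValueError):
            ventilation_signal(V, "sideways")

    def test_signal_is_rank_preserving(self):
        grid = Grid((4, 4, 4), (1, 1, 1))
        rng = np.random.default_rng(1)
        V = ImageVolume(rng.uniform(0.5, 2.0, grid.shape), grid)
        sig = ventilation_signal(V, "reference_is_exhale")
        assert (np.argsort(sig.data.ravel()) == np.argsort(V.data.ravel())).all()
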