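"""Constrained, variance-regularized least-squares recovery of knot values.

Solves, for the MLS knot values q (L unknowns),

    min_q  || A_hat q - b ||^2  +  lambda * sum_k (q_k - h/N)^2
    s.t.   sum_i v_i = h        (global volume consistency, v = C q)
           q_k >= epsilon       (strictly positive Jacobian estimates)

The equality constraint is expressed in knot space as (1^T C) q = h, which
is identical to sum(v) = h and keeps the problem L-dimensional.  Because C
is row-stochastic with nonnegative entries, q >= epsilon > 0 already forces
v = C q >= epsilon > 0 — positivity of the ventilation image is inherited
from the bound constraints.  The regularizer penalizes the variance of the
knot values about the mean volume change h/N enforced by the equality
constraint (large Jacobian spread being a practical error indicator).

The quadratic program is strictly convex (for lambda > 0) and small, and is
solved with a primal active-set method on the bound constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ImageVolume
from .estimators import DensityVolume
from .mls import LinearSystem, MLSModel, evaluate_field

__all__ = ["SolveConfig", "VentilationResult", "SolverError",
           "global_constraint_constant", "solve_ventilation", "ventilation_signal"]


class SolverError(RuntimeError):
    pass


@dataclass
class SolveConfig:
    epsilon: float = 0.05          # lower bound on q (Jacobian floor)
    lambda_reg: float = 1.0        # variance-regularizer weight
    equality_tolerance: float = 1e-6
    solver_max_iter: int = 500
    kkt_tolerance: float = 1e-6


@dataclass
class VentilationResult:
    q: np.ndarray                  # L knot values >= epsilon
    V: ImageVolume                 # det J estimates on the reference grid
    signal: ImageVolume            # ventilation signal (direction-converted)
    v_values: np.ndarray           # per-voxel values in mask order
    h: float
    residual_norm: float           # ||A_hat q - b||
    constraint_gap: float          # |sum v - h|
    kkt_residual: float
    tau: float | None = None
    method: str | None = None
    n_active_bounds: int = 0
    iterations: int = 0


def global_constraint_constant(method: str, mask_R: ImageVolume,
                               mask_T: ImageVolume,
                               density_R: DensityVolume | None = None,
                               density_T: DensityVolume | None = None) -> float:
    """Method-specific global volume-change constant h (voxel-volume units).

    IJF: h = |Omega(T)| — the target lung volume is the integral of det J
    over the reference lung.  MCVC: h = mean(rho_R over Omega(R)) /
    mean(rho_T over Omega(T)) * |Omega(R)| — the whole-lung density ratio.
    """
    mR = np.asarray(mask_R.data, dtype=bool)
    mT = np.asarray(mask_T.data, dtype=bool)
    if not mR.any() or not mT.any():
        raise ValueError("lung masks must be non-empty")
    method = method.upper()
    if method == "IJF":
        return float(mT.sum())
    if method == "MCVC":
        if density_R is None or density_T is None:
            raise ValueError("MCVC requires reference and target densities")
        mean_r = float(np.asarray(density_R.values.data)[mR].mean())
        mean_t = float(np.asarray(density_T.values.data)[mT].mean())
        if mean_t <= 0:
            raise ValueError("zero mean target density")
        return mean_r / mean_t * float(mR.sum())
    raise ValueError(f"unknown method {method!r}")


def _active_set_qp(G: np.ndarray, c: np.ndarray, a: np.ndarray, h: float,
                   eps: float, max_iter: int):
    """min 1/2 q^T G q - c^T q  s.t.  a^T q = h,  q >= eps  (G SPD).

    Returns (q, mu, n_iter).  Primal active-set with a strictly feasible
    start; for SPD G each working set is visited at most once, so the loop
    terminates.
    """
    L = len(c)
    n_tot = float(a.sum())
    q = np.full(L, h / n_tot)
    W = np.zeros(L, dtype=bool)
    tol = 1e-10 * max(1.0, np.abs(c).max())

    mu = 0.0
    for it in range(1, max_iter + 1):
        F = ~W
        nf = int(F.sum())
        if nf == 0:
            # all bounds active; mu from least squares on the eq constraint
            mu = 0.0
            grad = G @ q - c
            lam = grad + mu * a
            if (lam >= -tol).all():
                return q, mu, it
            W[np.argmin(lam)] = False
            continue
        # KKT system for free variables
        KKT = np.zeros((nf + 1, nf + 1))
        KKT[:nf, :nf] = G[np.ix_(F, F)]
        KKT[:nf, nf] = a[F]
        KKT[nf, :nf] = a[F]
        rhs = np.empty(nf + 1)
        rhs[:nf] = c[F] - G[np.ix_(F, W)] @ q[W]
        rhs[nf] = h - a[W] @ q[W]
        sol = np.linalg.solve(KKT, rhs)
        q_target = q.copy()
        q_target[F] = sol[:nf]
        mu = sol[nf]

        p = q_target - q
        if np.abs(p).max() <= 1e-12 * max(1.0, np.abs(q).max()):
            grad = G @ q - c
            lam = grad + mu * a          # multipliers of active bounds
            lam_active = np.where(W, lam, np.inf)
            if (lam_active >= -tol).all():
                return q, mu, it
            W[np.argmin(lam_active)] = False
            continue

        # step length limited by inactive bounds heading to eps
        dec = F & (p < 0)
        alpha = 1.0
        block = -1
        if dec.any():
            ratios = (eps - q[dec]) / p[dec]
            k = int(np.argmin(ratios))
            if ratios[k] < alpha:
                alpha = float(ratios[k])
                block = np.flatnonzero(dec)[k]
        q = q + alpha * p
        if block >= 0:
            q[block] = eps
            W[block] = True

    raise SolverError(f"active-set QP did not converge in {max_iter} iterations")


def solve_ventilation(system: LinearSystem, model: MLSModel,
                      cfg: SolveConfig | None = None,
                      tau: float | None = None,
                      method: str | None = None,
                      signal_direction: str = "reference_is_exhale") -> VentilationResult:
    """Solve the constrained fit and evaluate the ventilation image.

    Raises :class:`SolverError` when the configuration is infeasible
    (epsilon * N > h) or the QP fails to converge.  When epsilon * N == h the
    equality constraint pins every knot to the floor and q == epsilon is
    returned directly (the unique feasible point).
    """
    if cfg is None:
        cfg = SolveConfig()
    A, b, h, N = system.A_hat, system.b, system.h, system.N
    L = A.shape[1]
    a = np.asarray(model.C.sum(axis=0)).ravel()  # (1^T C); sums to N

    if cfg.epsilon * N > h * (1 + 1e-12):
        raise SolverError(
            f"infeasible configuration: epsilon*N = {cfg.epsilon * N:.6g} exceeds "
            f"h = {h:.6g}; the bound q >= epsilon and the equality sum(v) = h "
            "cannot both hold"
        )

    if abs(cfg.epsilon * N - h) <= 1e-12 * max(1.0, h):
        q = np.full(L, cfg.epsilon)
        mu = 0.0
        iterations = 0
    else:
        G = 2.0 * (A.T @ A + cfg.lambda_reg * np.eye(L))
        c = 2.0 * (A.T @ b + cfg.lambda_reg * (h / N) * np.ones(L))
        q, mu, iterations = _active_set_qp(G, c, a, h, cfg.epsilon, cfg.solver_max_iter)

        # KKT residual (relative stationarity over the free set)
        grad = G @ q - c + mu * a
        free = q > cfg.epsilon + 1e-12
        scale = max(1.0, float(np.abs(c).max()))
        kkt = float(np.abs(grad[free]).max() / scale) if free.any() else 0.0
        if kkt > cfg.kkt_tolerance:
            raise SolverError(f"KKT residual {kkt:.3e} exceeds tolerance")

    v = evaluate_field(model, q)
    constraint_gap = float(abs(v.sum() - h))
    if constraint_gap > cfg.equality_tolerance * max(1.0, abs(h)):
        raise SolverError(
            f"global volume constraint violated: |sum v - h| = {constraint_gap:.3e}"
        )
    if np.any(v <= 0):
        raise SolverError("non-positive ventilation value produced")

    grad = (2.0 * (A.T @ (A @ q - b) + cfg.lambda_reg * (q - h / N))) + mu * a \
        if cfg.epsilon * N < h else np.zeros(L)
    free = q > cfg.epsilon + 1e-12
    kkt_res = float(np.abs(grad[free]).max()) if free.any() else 0.0

    V = model.field_volume(v, fill=0.0)
    sig_values = ventilation_signal(V, signal_direction)

    return VentilationResult(
        q=q, V=V, signal=sig_values, v_values=v, h=float(h),
        residual_norm=float(np.linalg.norm(A @ q - b)),
        constraint_gap=constraint_gap,
        kkt_residual=kkt_res, tau=tau, method=method,
        n_active_bounds=int((q <= cfg.epsilon + 1e-12).sum()),
        iterations=iterations,
    )


def ventilation_signal(V: ImageVolume, direction: str = "reference_is_exhale") -> ImageVolume:
    """Convert a Jacobian image to an absolute-volume-difference signal.

    With the exhale phase as reference, expansion (det J > 1) is positive
    ventilation: signal = V - 1.  With an inhale reference the sign flips:
    signal = 1 - V.  Either way the map is monotone in V, so rank-based
    comparisons are unaffected by the direction convention.
    """
    if direction == "reference_is_exhale":
        return V.like(np.asarray(V.data, dtype=float) - 1.0)
    if direction == "reference_is_inhale":
        return V.like(1.0 - np.asarray(V.data, dtype=float))
    raise ValueError(f"unknown signal direction {direction!r}")
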