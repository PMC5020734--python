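"""Inverse estimation of the stage-transition matrix (Wood's method).

Given a sequence of annual stage vectors n(0)...n(T), the transition
matrix M that best explains n(t+1) ~ M n(t) is found by constrained least
squares: entries live only on the arcs of a life-cycle graph, all entries
are nonnegative, and in each column the survival entries (stasis + growth
+ shrinkage) sum to at most one. Fertility entries are unconstrained
above zero. The problem is a convex quadratic program in the vector of
free arc parameters; an unconstrained least-squares solution is accepted
directly whenever it is feasible, otherwise the QP is solved to high
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .structure import (LifeCycleStructure, TransitionMatrix,
                        UnidentifiableError)

__all__ = [
    "SolveReport",
    "check_identifiability",
    "build_design",
    "solve_wood",
    "decompose",
]


@dataclass(frozen=True)
class SolveReport:
    """Result and diagnostics of one inverse fit."""

    matrix: TransitionMatrix
    rss: float
    residuals: np.ndarray  # (transitions, k): n(t+1) - M n(t)
    equations: int
    unknowns: int
    identifiable: bool
    ridge: float = 0.0

    @property
    def objective(self) -> float:
        """Sum of squared residuals minimized by the fit."""
        return self.rss


def check_identifiability(series_length: int,
                          structure: LifeCycleStructure) -> dict:
    """Count equations vs. free parameters for a planned fit.

    Each observed transition contributes k equations; the system is
    identifiable when k (series_length - 1) >= number of arcs.
    """
    if series_length < 2:
        raise ValueError("need at least 2 vectors")
    equations = structure.n_classes * (series_length - 1)
    unknowns = structure.n_parameters
    return {"equations": equations, "unknowns": unknowns,
            "identifiable": equations >= unknowns}


def build_design(vectors: np.ndarray,
                 structure: LifeCycleStructure) -> tuple[np.ndarray, np.ndarray]:
    """Stack the transitions into a linear system A theta = y.

    theta holds one coefficient per arc in :meth:`LifeCycleStructure.sorted_arcs`
    order; row (t, i) of the system reads
    sum_{arcs (i <- j)} theta_arc n_j(t) = n_i(t + 1).
    """
    vectors = np.asarray(vectors, dtype=float)
    T, k = vectors.shape[0] - 1, vectors.shape[1]
    arcs = structure.sorted_arcs()
    A = np.zeros((T * k, len(arcs)))
    y = vectors[1:].reshape(-1)
    for p, arc in enumerate(arcs):
        rows = np.arange(T) * k + arc.target
        A[rows, p] = vectors[:-1, arc.source]
    return A, y


def _survival_constraint(structure: LifeCycleStructure) -> tuple[np.ndarray, list[int]]:
    """Rows of C theta <= 1, one per column holding survival arcs.

    Survival arcs of different columns never share a parameter, so the
    constraint rows have disjoint support (this makes exact projection
    possible for oracle solvers).
    """
    arcs = structure.sorted_arcs()
    cols = sorted({a.source for a in arcs if a.role != "fertility"})
    C = np.zeros((len(cols), len(arcs)))
    for r, j in enumerate(cols):
        for p, arc in enumerate(arcs):
            if arc.source == j and arc.role != "fertility":
                C[r, p] = 1.0
    return C, cols


def _theta_to_matrix(theta: np.ndarray,
                     structure: LifeCycleStructure) -> np.ndarray:
    M = np.zeros((structure.n_classes, structure.n_classes))
    for p, arc in enumerate(structure.sorted_arcs()):
        M[arc.target, arc.source] = theta[p]
    return M


def solve_wood(vectors, structure: LifeCycleStructure,
               ridge: float = 0.0,
               constraint_tol: float = 1e-8,
               scheme=None) -> SolveReport:
    """Estimate M minimizing sum_t ||n(t+1) - M n(t)||^2 under structure.

    The fit is ordinary (unweighted) least squares over the free arc
    parameters with entries >= 0 and column survival sums <= 1. An
    unidentifiable system (fewer equations than parameters) is an error
    unless a positive ``ridge`` penalty lambda ||theta||^2 is supplied, in
    which case the minimum-norm solution is returned. Deterministic for a
    fixed configuration.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need a 2-D array of at least 2 stage vectors")
    if np.any(vectors < 0):
        raise ValueError("stage vectors must be nonnegative")
    if not np.any(vectors[:-1].sum(axis=1) > 0):
        raise ValueError("degenerate input: all source vectors are zero")
    if vectors.shape[1] != structure.n_classes:
        raise ValueError("vector length does not match structure")

    ident = check_identifiability(vectors.shape[0], structure)
    if not ident["identifiable"] and ridge <= 0:
        raise UnidentifiableError(
            f"{ident['equations']} equations < {ident['unknowns']} parameters; "
            "enable ridge regularization to obtain a minimum-norm solution")

    A, y = build_design(vectors, structure)
    C, _ = _survival_constraint(structure)
    theta = _solve_qp(A, y, C, ridge, constraint_tol)

    M = _theta_to_matrix(theta, structure)
    matrix = TransitionMatrix(values=M, structure=structure, scheme=scheme)
    pred = vectors[:-1] @ M.T
    residuals = vectors[1:] - pred
    rss = float(np.sum(residuals ** 2))
    return SolveReport(matrix=matrix, rss=rss, residuals=residuals,
                       equations=ident["equations"], unknowns=ident["unknowns"],
                       identifiable=ident["identifiable"], ridge=ridge)


def _solve_qp(A: np.ndarray, y: np.ndarray, C: np.ndarray,
              ridge: float, constraint_tol: float) -> np.ndarray:
    """Minimize ||A theta - y||^2 + ridge ||theta||^2 s.t. theta >= 0, C theta <= 1.

    The system is first normalized by the Frobenius norm of A so that the
    result is equivariant under rescaling of the input vectors. Fast path:
    the (ridge-)unconstrained least-squares solution is returned when it
    already satisfies the constraints. Otherwise the convex QP is solved
    with a trust-region interior method and the exact optimum is recovered
    by re-solving the equality-constrained problem on the identified
    active set (KKT polish).
    """
    p = A.shape[1]
    scale = np.linalg.norm(A)
    if scale == 0:
        return np.zeros(p)
    A = A / scale
    y = y / scale
    if ridge > 0:
        A_aug = np.vstack([A, np.sqrt(ridge) / scale * np.eye(p)])
        y_aug = np.concatenate([y, np.zeros(p)])
    else:
        A_aug, y_aug = A, y
    theta0, *_ = np.linalg.lstsq(A_aug, y_aug, rcond=None)
    if (theta0 >= -constraint_tol).all() and (C @ theta0 <= 1 + constraint_tol).all():
        return _snap_feasible(theta0, C)

    H = A_aug.T @ A_aug
    g = A_aug.T @ y_aug

    def fun(th):
        return 0.5 * th @ H @ th - g @ th

    def jac(th):
        return H @ th - g

    x0 = np.clip(theta0, 0.0, None)
    # start strictly feasible for the interior method
    excess = C @ x0
    for r in range(C.shape[0]):
        if excess[r] > 1.0:
            sup = C[r] > 0
            x0[sup] *= 1.0 / excess[r]
    res = minimize(fun, x0, jac=jac, hess=lambda th: H,
                   method="trust-constr",
                   bounds=[(0.0, None)] * p,
                   constraints=[LinearConstraint(C, -np.inf, 1.0)],
                   options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000})
    theta = _polish_active_set(A_aug, y_aug, C, res.x)
    return _snap_feasible(theta, C)


def _polish_active_set(A: np.ndarray, y: np.ndarray, C: np.ndarray,
                       theta: np.ndarray) -> np.ndarray:
    """Exact KKT re-solve on the active set identified by the QP solver.

    An interior-point iterate approaches active bounds and tight
    survival-sum rows without ever reaching them, so the activity
    tolerance is swept over several levels; for each guessed active set
    the equality-constrained least-squares problem is solved in closed
    form (KKT system) and the best feasible candidate is kept. At the
    correct active set this recovers the exact constrained optimum.
    """
    p = theta.size
    ref = max(float(np.max(theta)), 1.0)
    slack = C @ theta

    def candidate(tol: float) -> np.ndarray | None:
        free = theta > tol * ref
        if not free.any():
            return None
        active_rows = np.where(slack >= 1.0 - tol)[0]
        Af = A[:, free]
        nf = Af.shape[1]
        if active_rows.size:
            E = C[np.ix_(active_rows, np.where(free)[0])]
            K = np.block([[Af.T @ Af, E.T],
                          [E, np.zeros((E.shape[0], E.shape[0]))]])
            rhs = np.concatenate([Af.T @ y, np.ones(E.shape[0])])
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            x = sol[:nf]
        else:
            x, *_ = np.linalg.lstsq(Af, y, rcond=None)
        cand = np.zeros(p)
        cand[free] = x
        if (cand >= -1e-12).all() and (C @ cand <= 1.0 + 1e-9).all():
            return cand
        return None

    best = theta
    best_obj = float(np.sum((A @ theta - y) ** 2))
    for tol in (1e-8, 1e-6, 1e-4, 1e-3, 1e-2):
        cand = candidate(tol)
        if cand is not None:
            obj = float(np.sum((A @ cand - y) ** 2))
            if obj < best_obj:
                best, best_obj = cand, obj
    return best


def _snap_feasible(theta: np.ndarray, C: np.ndarray,
                   tol: float = 1e-12) -> np.ndarray:
    """Clip tiny negatives and rescale marginal constraint overshoots so the
    returned matrix satisfies its invariants exactly."""
    theta = np.clip(theta, 0.0, None)
    s = C @ theta
    for r in range(C.shape[0]):
        if s[r] > 1.0:
            sup = C[r] > 0
            theta[sup] /= s[r]
    return theta


def decompose(M: TransitionMatrix) -> "MatrixDecomposition":
    """Split M into survival S (stasis/growth/shrinkage) and fecundity R.

    The split follows the roles of the matrix's own structure, so
    S + R = M holds bit for bit with disjoint supports.
    """
    from .structure import MatrixDecomposition

    surv = M.structure.survival_mask()
    fert = M.structure.role_mask(("fertility",))
    S = np.where(surv, M.values, 0.0)
    R = np.where(fert, M.values, 0.0)
    leftover = M.values - S - R
    if np.any(leftover != 0):
        raise ValueError("matrix has entries on arcs with no role")
    return MatrixDecomposition(S=S, R=R, structure=M.structure)
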