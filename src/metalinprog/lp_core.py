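"""Linear-program assembly and solving for the sparse SVM formulations.

Two convex problems are posed as linear programs over nonnegative
variables:

* **Binary L1 SVM.**  Minimize ``sum_i xi_i + lam * ||beta||_1`` subject to
  ``y_i (beta . x_i + beta0) + xi_i >= 1``.  The free coefficients are
  split into nonnegative parts, ``beta_j = u_j - v_j`` and
  ``beta0 = b+ - b-`` (the intercept is not penalized), which turns the
  absolute values in the objective into the linear cost
  ``lam * sum_j (u_j + v_j)``.

* **Multiclass joint L-infinity,1 SVM.**  For a c-class problem encoded
  one-against-rest into K = c - 1 sign matrices, minimize
  ``sum_{i,k} xi_ik + lam * sum_j t_j`` subject to the K hinge systems and
  the box constraints ``-t_j <= beta_jk <= t_j``.  At the optimum
  ``t_j = max_k |beta_jk|``, so the penalty is the L-infinity,1 mixed norm:
  features are switched on or off jointly across all K subproblems, which
  forces the one-against-rest classifiers to share a feature set.

Both programs are solved by an off-the-shelf solver (SciPy's HiGHS
interface); the global optimum is certified by an independent feasibility
re-check of the returned point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: Accepted solver backends (all HiGHS variants exposed by SciPy).
BACKENDS = ("highs", "highs-ds", "highs-ipm")
DEFAULT_BACKEND = "highs-ipm"

FEASIBILITY_TOL = 1e-6
OBJECTIVE_REL_TOL = 1e-8

Status = Literal["optimal", "infeasible", "unbounded", "numerical_failure"]

_LINPROG_STATUS: dict[int, Status] = {
    0: "optimal",
    1: "numerical_failure",  # iteration limit
    2: "infeasible",
    3: "unbounded",
    4: "numerical_failure",
}


class ConfigurationError(ValueError):
    """Unknown or unavailable solver backend."""


@dataclass
class LinearProgram:
    """min c.z  s.t.  A z >= b,  lower <= z <= upper, with named blocks.

    ``var_map`` locates each semantic block of the stacked variable vector:
    ``u``/``v`` (positive/negative coefficient parts), ``intercept_pos``/
    ``intercept_neg``, ``slack`` (hinge slacks xi) and ``rowmax`` (the per-
    feature bound t; empty for the binary program).
    """

    objective: np.ndarray
    ineq_matrix: sparse.csr_matrix
    ineq_rhs: np.ndarray
    var_lower: np.ndarray
    var_upper: np.ndarray
    var_map: dict[str, slice]

    def __post_init__(self) -> None:
        nv = self.objective.size
        if self.ineq_matrix.shape[1] != nv:
            raise ValueError("constraint matrix width != variable count")
        if self.ineq_matrix.shape[0] != self.ineq_rhs.size:
            raise ValueError("constraint count != rhs length")
        if self.var_lower.size != nv or self.var_upper.size != nv:
            raise ValueError("bounds length != variable count")
        if np.any(self.objective < 0):
            raise ValueError("objective coefficients must be nonnegative")
        covered = np.zeros(nv, dtype=int)
        for sl in self.var_map.values():
            covered[sl] += 1
        if np.any(covered != 1):
            raise ValueError("var_map slices must be disjoint and cover z")

    @property
    def n_variables(self) -> int:
        return self.objective.size

    @property
    def n_constraints(self) -> int:
        return self.ineq_rhs.size


@dataclass
class LPSolution:
    variables: np.ndarray
    objective_value: float
    status: Status


def _check_binary_inputs(Xt: np.ndarray, y: np.ndarray, lam: float):
    Xt = np.asarray(Xt, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xt.ndim != 2:
        raise ValueError("Xt must be a 2-D matrix")
    n, _ = Xt.shape
    if y.shape != (n,):
        raise ValueError(f"y must have length {n}")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("y entries must be -1 or +1")
    if np.all(y == y[0]):
        raise ValueError("both classes must be present in y")
    if lam < 0:
        raise ValueError("regularization weight lam must be >= 0")
    return Xt, y


def assemble_binary_lp(Xt: np.ndarray, y: np.ndarray, lam: float) -> LinearProgram:
    """LP for the binary L1-penalized soft-margin SVM.

    Variable order: u (m), v (m), b+, b-, xi (n); 2m + 2 + n variables and
    n hinge constraints ``y_i((u - v).x_i + b+ - b-) + xi_i >= 1``.
    """
    Xt, y = _check_binary_inputs(Xt, y, lam)
    n, m = Xt.shape
    Yx = y[:, None] * Xt
    ycol = sparse.csr_matrix(y[:, None])
    A = sparse.hstack(
        [sparse.csr_matrix(Yx), sparse.csr_matrix(-Yx), ycol, -ycol,
         sparse.eye(n, format="csr")],
        format="csr",
    )
    nv = 2 * m + 2 + n
    objective = np.concatenate(
        [np.full(2 * m, lam), np.zeros(2), np.ones(n)]
    )
    var_map = {
        "u": slice(0, m),
        "v": slice(m, 2 * m),
        "intercept_pos": slice(2 * m, 2 * m + 1),
        "intercept_neg": slice(2 * m + 1, 2 * m + 2),
        "slack": slice(2 * m + 2, nv),
        "rowmax": slice(nv, nv),
    }
    return LinearProgram(
        objective=objective,
        ineq_matrix=A,
        ineq_rhs=np.ones(n),
        var_lower=np.zeros(nv),
        var_upper=np.full(nv, np.inf),
        var_map=var_map,
    )


def assemble_multiclass_lp(
    Xt: np.ndarray, Y: np.ndarray, lam: float
) -> LinearProgram:
    """LP for the joint L-infinity,1 multiclass SVM.

    ``Y`` is the n x K one-against-rest sign matrix (K = c - 1; the
    reference class's subproblem is dropped).  Variable order: u (mK),
    v (mK), b+ (K), b- (K), xi (nK), t (m); the k-th m-block of u/v holds
    subproblem k's coefficients.  Constraints: nK hinge rows plus 2mK box
    rows ``t_j - beta_jk >= 0`` and ``t_j + beta_jk >= 0``.
    """
    Xt = np.asarray(Xt, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != Xt.shape[0]:
        raise ValueError("Y must be n x (c-1)")
    if not np.all(np.isin(Y, (-1.0, 1.0))):
        raise ValueError("Y entries must be -1 or +1")
    if lam < 0:
        raise ValueError("regularization weight lam must be >= 0")
    n, m = Xt.shape
    K = Y.shape[1]
    for k in range(K):
        if np.all(Y[:, k] == Y[0, k]):
            raise ValueError(f"subproblem {k} has only one sign present")

    nv = 2 * m * K + 2 * K + n * K + m
    off_v = m * K
    off_bp = 2 * m * K
    off_bn = off_bp + K
    off_xi = off_bn + K
    off_t = off_xi + n * K

    blocks = []
    Zn = lambda cols: sparse.csr_matrix((n, cols))  # noqa: E731
    for k in range(K):
        Yx = sparse.csr_matrix(Y[:, k][:, None] * Xt)
        ycol = sparse.csr_matrix(Y[:, k][:, None])
        bp = sparse.hstack(
            [Zn(k), ycol, Zn(K - 1 - k), Zn(k), -ycol, Zn(K - 1 - k)],
            format="csr",
        )
        xi = sparse.hstack(
            [Zn(k * n), sparse.eye(n, format="csr"), Zn((K - 1 - k) * n)],
            format="csr",
        )
        blocks.append(
            sparse.hstack(
                [Zn(k * m), Yx, Zn((K - 1 - k) * m),
                 Zn(k * m), -Yx, Zn((K - 1 - k) * m),
                 bp, xi, Zn(m)],
                format="csr",
            )
        )
    I = sparse.eye(m, format="csr")
    Zm = lambda cols: sparse.csr_matrix((m, cols))  # noqa: E731
    for k in range(K):
        for sign in (-1, 1):  # t_j - sign * beta_jk >= 0
            blocks.append(
                sparse.hstack(
                    [Zm(k * m), -sign * I, Zm((K - 1 - k) * m),
                     Zm(k * m), sign * I, Zm((K - 1 - k) * m),
                     Zm(2 * K + n * K), I],
                    format="csr",
                )
            )
    A = sparse.vstack(blocks, format="csr")
    rhs = np.concatenate([np.ones(n * K), np.zeros(2 * m * K)])
    objective = np.concatenate(
        [np.zeros(2 * m * K + 2 * K), np.ones(n * K), np.full(m, lam)]
    )
    var_map = {
        "u": slice(0, off_v),
        "v": slice(off_v, off_bp),
        "intercept_pos": slice(off_bp, off_bn),
        "intercept_neg": slice(off_bn, off_xi),
        "slack": slice(off_xi, off_t),
        "rowmax": slice(off_t, nv),
    }
    return LinearProgram(
        objective=objective,
        ineq_matrix=A,
        ineq_rhs=rhs,
        var_lower=np.zeros(nv),
        var_upper=np.full(nv, np.inf),
        var_map=var_map,
    )


def solve_lp(lp: LinearProgram, backend: str = DEFAULT_BACKEND) -> LPSolution:
    """Solve ``lp`` and certify the answer.

    An optimal point is re-checked against the constraints and bounds at
    tolerance 1e-6, and the reported objective is re-evaluated from the
    cost vector (relative tolerance 1e-8); any discrepancy downgrades the
    status to ``numerical_failure`` rather than returning a silent wrong
    answer.
    """
    if backend not in BACKENDS:
        raise ConfigurationError(
            f"unknown backend {backend!r}; available: {BACKENDS}"
        )
    bounds = np.column_stack([lp.var_lower, lp.var_upper])
    result = linprog(
        lp.objective,
        A_ub=-lp.ineq_matrix,
        b_ub=-lp.ineq_rhs,
        bounds=bounds,
        method=backend,
    )
    status = _LINPROG_STATUS.get(result.status, "numerical_failure")
    if status != "optimal":
        return LPSolution(
            variables=np.array([]), objective_value=np.nan, status=status
        )
    z = np.asarray(result.x, dtype=float)
    residual = lp.ineq_matrix @ z - lp.ineq_rhs
    scale = max(1.0, float(np.abs(lp.ineq_rhs).max(initial=0.0)))
    feasible = (
        residual.min(initial=0.0) >= -FEASIBILITY_TOL * scale
        and np.all(z >= lp.var_lower - FEASIBILITY_TOL)
        and np.all(z <= lp.var_upper + FEASIBILITY_TOL)
    )
    objective_value = float(lp.objective @ z)
    reported = float(result.fun)
    consistent = abs(objective_value - reported) <= OBJECTIVE_REL_TOL * max(
        1.0, abs(objective_value)
    )
    if not (feasible and consistent):
        return LPSolution(
            variables=z, objective_value=objective_value,
            status="numerical_failure",
        )
    return LPSolution(
        variables=z, objective_value=objective_value, status="optimal"
    )
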