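"""Thin deterministic wrappers around scipy's HiGHS LP/MILP interfaces.

All constraint-based computations in the package go through these two entry
points so the solver backend can be swapped in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp

FEASIBILITY_TOL = 1e-9

__all__ = ["LpSolution", "solve_lp", "solve_milp_min_count", "FEASIBILITY_TOL"]


@dataclass
class LpSolution:
    status: str  # optimal | infeasible | unbounded
    objective: Optional[float]
    x: Optional[np.ndarray]


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    a_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    maximize: bool = False,
    a_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
) -> LpSolution:
    """Solve min (or max) c.x s.t. a_eq.x = b_eq, a_ub.x <= b_ub,
    lb <= x <= ub."""
    if np.any(lb > ub):
        raise ValueError("lower bound exceeds upper bound")
    sign = -1.0 if maximize else 1.0
    if a_ub is not None and a_ub.shape[0] == 0:
        a_ub, b_ub = None, None
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_eq=a_eq,
        b_eq=b_eq,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return LpSolution(status, None, None)
    return LpSolution("optimal", sign * res.fun, res.x)


def solve_milp_min_count(
    n_cont: int,
    candidate_idx: Sequence[int],
    a_eq: sparse.spmatrix,
    b_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    extra_lb_row: Optional[np.ndarray] = None,
    extra_lb_value: float = 0.0,
    forced_on: Sequence[int] = (),
    forced_off: Sequence[int] = (),
    cardinality: Optional[int] = None,
) -> Optional[np.ndarray]:
    """Minimize the number of switched-on candidate variables.

    Continuous variables x (n_cont of them) satisfy ``a_eq.x = b_eq`` and
    bounds; each candidate j in ``candidate_idx`` gets a binary indicator y_j
    coupling its bounds: lb_j*y_j <= x_j <= ub_j*y_j.  Optionally one extra
    inequality ``extra_lb_row.x >= extra_lb_value`` (e.g. growth above a
    threshold).  Returns the indicator vector over ``candidate_idx`` (order
    preserved) for an optimal solution, or None if infeasible.

    ``forced_on`` / ``forced_off`` fix individual indicators (positions into
    ``candidate_idx``); ``cardinality`` fixes the indicator sum, turning the
    solve into a feasibility check used for lexicographic tie-breaking.
    """
    candidate_idx = list(candidate_idx)
    m = len(candidate_idx)
    n = n_cont + m
    lb_full = np.concatenate([lb, np.zeros(m)])
    ub_full = np.concatenate([ub, np.ones(m)])
    for pos in forced_on:
        lb_full[n_cont + pos] = 1.0
    for pos in forced_off:
        ub_full[n_cont + pos] = 0.0

    a_eq = sparse.csr_matrix(a_eq)
    eq_block = sparse.hstack(
        [a_eq, sparse.csr_matrix((a_eq.shape[0], m))], format="csr"
    )
    constraints = [LinearConstraint(eq_block, b_eq, b_eq)]

    # indicator coupling: x_j - ub_j*y_j <= 0  and  x_j - lb_j*y_j >= 0.
    # Rows are scaled up so that a sub-tolerance flux leak through a
    # switched-off reaction (which could fake a tiny growth threshold)
    # becomes a genuine violation for the MIP feasibility check.
    kappa = 1e4
    rows, cols, vals = [], [], []
    lower, upper = [], []
    r = 0
    for pos, j in enumerate(candidate_idx):
        rows += [r, r]
        cols += [j, n_cont + pos]
        vals += [kappa, -kappa * ub[j]]
        lower.append(-np.inf)
        upper.append(0.0)
        r += 1
        rows += [r, r]
        cols += [j, n_cont + pos]
        vals += [kappa, -kappa * lb[j]]
        lower.append(0.0)
        upper.append(np.inf)
        r += 1
    coupling = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n))
    constraints.append(LinearConstraint(coupling, lower, upper))

    if extra_lb_row is not None:
        # rescale so the RHS is O(1): tiny thresholds (e.g. a 1e-6 growth
        # floor) would otherwise vanish inside the MIP feasibility tolerance
        scale = 1.0 / abs(extra_lb_value) if extra_lb_value != 0 else 1.0
        row = sparse.csr_matrix(
            np.concatenate([scale * extra_lb_row, np.zeros(m)])[None, :]
        )
        constraints.append(
            LinearConstraint(row, scale * extra_lb_value, np.inf)
        )

    if cardinality is not None:
        card_row = sparse.csr_matrix(
            np.concatenate([np.zeros(n_cont), np.ones(m)])[None, :]
        )
        constraints.append(LinearConstraint(card_row, cardinality, cardinality))

    c = np.concatenate([np.zeros(n_cont), np.ones(m)])
    integrality = np.concatenate([np.zeros(n_cont), np.ones(m)])
    import warnings

    from scipy.optimize import Bounds

    with warnings.catch_warnings():
        # tolerance options are forwarded verbatim to HiGHS; scipy flags
        # them as unrecognized
        warnings.simplefilter("ignore", RuntimeWarning)
        res = milp(
            c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lb_full, ub_full),
            options={
                "mip_rel_gap": 0.0,
                "mip_feasibility_tolerance": 1e-9,
                "primal_feasibility_tolerance": 1e-9,
            },
        )
    if not res.success:
        return None
    return np.round(res.x[n_cont:]).astype(int)
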