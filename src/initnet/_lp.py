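"""Thin wrappers around scipy's HiGHS LP interface used across modules."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

#: Default numeric bound standing in for "unbounded" flux.
DEFAULT_BOUND = 1000.0

#: Primal/dual feasibility tolerance requested from the solver.
LP_TOL = 1e-7


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[sparse.spmatrix],
    b_eq: Optional[np.ndarray],
    bounds: Sequence[Tuple[float, float]],
    A_ub: Optional[sparse.spmatrix] = None,
    b_ub: Optional[np.ndarray] = None,
    maximize: bool = False,
):
    """Solve an LP; returns the scipy result with ``.fun`` sign-corrected.

    ``res.status`` follows scipy: 0 optimal, 2 infeasible, 3 unbounded.
    """
    sign = -1.0 if maximize else 1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(bounds),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status == 0:
        res.fun = sign * res.fun
    return res


def flux_bounds(reversible: bool, big_m: float = DEFAULT_BOUND) -> Tuple[float, float]:
    return (-big_m if reversible else 0.0, big_m)
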