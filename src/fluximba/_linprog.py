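"""Thin adapter over scipy's HiGHS linear-programming backend.

All LPs in the package are stated here as minimizations; callers handle
sense.  The adapter exposes equality-constraint marginals with scipy's
convention (d(min objective)/d(rhs)); sign normalization to the package's
shadow-price convention happens in the calling modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 1: "iteration_limit", 2: INFEASIBLE, 3: UNBOUNDED, 4: "numerical"}


@dataclass
class LpResult:
    status: str
    x: Optional[np.ndarray]
    objective: Optional[float]
    eq_marginals: Optional[np.ndarray]
    ub_marginals: Optional[np.ndarray] = None

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL


def solve_lp(
    c,
    A_eq=None,
    b_eq=None,
    bounds=None,
    A_ub=None,
    b_ub=None,
) -> LpResult:
    """Minimize ``c @ x`` subject to equality/inequality constraints and bounds."""
    res = linprog(
        c=c,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, f"solver_status_{res.status}")
    if status != OPTIMAL:
        return LpResult(status=status, x=None, objective=None, eq_marginals=None)
    eq_marg = np.asarray(res.eqlin.marginals) if A_eq is not None else None
    ub_marg = np.asarray(res.ineqlin.marginals) if A_ub is not None else None
    return LpResult(
        status=OPTIMAL,
        x=np.asarray(res.x),
        objective=float(res.fun),
        eq_marginals=eq_marg,
        ub_marginals=ub_marg,
    )
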