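"""The FBA primal LP, its explicit dual, and shadow-price extraction.

Primal (maximization)::

    max  c' v
    s.t. S v = b
         v_LB <= v <= v_UB

Dual, with multipliers lambda (free, one per metabolite), mu_LB >= 0 and
mu_UB >= 0 (one pair per reaction)::

    min  b' lambda - v_LB' mu_LB + v_UB' mu_UB
    s.t. S' lambda - mu_LB + mu_UB = c

Shadow prices follow the sensitivity convention lambda_i = dZ*/db_i for the
maximization primal: a *negative* shadow price means that permitting extra
outflow from the metabolite (b_i < 0) raises the optimum, i.e. the
metabolite is growth-limiting under a growth objective.

Each shadow price is only valid over a range [G-, G+] of right-hand-side
perturbations, determined by the geometry of the feasible polytope.  The
ranging here is solver-independent: G+ (resp. G-) is found by a single
auxiliary LP that maximizes (minimizes) the perturbation delta subject to
the original constraints plus the requirement that the objective stays on
the linear piece Z(delta) = Z(0) + lambda_i * delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._linprog import INFEASIBLE, OPTIMAL, LpResult, solve_lp
from .exceptions import SolverError
from .model import MetabolicModel

#: default numerical tolerance used throughout the package
DEFAULT_TOL = 1e-6

#: perturbations beyond this magnitude are reported as an unbounded range
RANGE_CAP = 1e9


@dataclass
class PrimalSolution:
    fluxes: Optional[np.ndarray]
    objective_value: Optional[float]
    status: str
    lethal: bool = False

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class DualSolution:
    shadow_prices: np.ndarray
    reduced_costs_lower: np.ndarray
    reduced_costs_upper: np.ndarray
    dual_objective: float


@dataclass
class ShadowPriceRecord:
    metabolite_id: str
    compartment: str
    lam: float
    range_low: float
    range_high: float
    valid: bool


@dataclass
class DualProgram:
    """Explicit dual LP over (lambda, mu_LB, mu_UB), stated as a minimization."""

    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: List[Tuple[Optional[float], Optional[float]]]
    variable_names: List[str] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return len(self.c)

    def solve(self) -> LpResult:
        return solve_lp(self.c, A_eq=self.A_eq, b_eq=self.b_eq, bounds=self.bounds)


def _finite_bounds(model: MetabolicModel):
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


def solve_fba(
    model: MetabolicModel, b: Optional[np.ndarray] = None
) -> Tuple[PrimalSolution, Optional[DualSolution]]:
    """Solve the FBA primal and return primal and dual solutions.

    ``b`` overrides the model's right-hand side (used for flux-imbalance
    perturbations).  On infeasible or unbounded problems the primal carries
    the status and the dual is ``None``; infeasibility is additionally
    flagged as potentially lethal when the model contains knocked-out
    reactions (both bounds zero) — the typical signature of an in-silico
    gene deletion that cannot sustain a demanded flux.
    """
    c = model.objective_vector()
    S = model.stoichiometric_matrix()
    rhs = model.b if b is None else np.asarray(b, dtype=float)
    res = solve_lp(-c, A_eq=S, b_eq=rhs, bounds=model.bounds())
    if not res.is_optimal:
        lethal = res.status == INFEASIBLE and any(
            r.lower_bound == 0.0 and r.upper_bound == 0.0 for r in model.reactions
        )
        return PrimalSolution(None, None, res.status, lethal=lethal), None
    z = -res.objective
    lam = -res.eq_marginals  # scipy reports d(min -c'v)/db; flip to dZ/db
    # reduced costs reconstructed from stationarity S'lam - mu_LB + mu_UB = c
    r = c - S.T @ lam
    mu_ub = np.maximum(r, 0.0)
    mu_lb = np.maximum(-r, 0.0)
    lb, ub = _finite_bounds(model)
    # multipliers of vacuous (infinite) bounds are identically zero
    mu_lb[np.isneginf(lb)] = 0.0
    mu_ub[np.isposinf(ub)] = 0.0
    dual_obj = (
        float(lam @ rhs)
        - float(np.sum(mu_lb[mu_lb > 0] * lb[mu_lb > 0]))
        + float(np.sum(mu_ub[mu_ub > 0] * ub[mu_ub > 0]))
    )
    primal = PrimalSolution(res.x, z, OPTIMAL)
    dual = DualSolution(lam, mu_lb, mu_ub, dual_obj)
    return primal, dual


def build_dual(model: MetabolicModel) -> DualProgram:
    """Construct the explicit dual LP of the FBA primal.

    Variables are ordered [lambda (m), mu_LB (n), mu_UB (n)].  Multipliers
    of infinite (vacuous) primal bounds are fixed to zero so the dual
    objective stays finite.
    """
    m, n = model.n_metabolites, model.n_reactions
    S = model.stoichiometric_matrix().toarray()
    c_primal = model.objective_vector()
    lb, ub = _finite_bounds(model)

    obj = np.zeros(m + 2 * n)
    obj[:m] = model.b
    obj[m : m + n] = np.where(np.isneginf(lb), 0.0, -lb)
    obj[m + n :] = np.where(np.isposinf(ub), 0.0, ub)

    A_eq = np.zeros((n, m + 2 * n))
    A_eq[:, :m] = S.T
    A_eq[:, m : m + n] = -np.eye(n)
    A_eq[:, m + n :] = np.eye(n)

    bounds: List[Tuple[Optional[float], Optional[float]]] = []
    bounds += [(None, None)] * m
    bounds += [(0.0, 0.0) if np.isneginf(lb[j]) else (0.0, None) for j in range(n)]
    bounds += [(0.0, 0.0) if np.isposinf(ub[j]) else (0.0, None) for j in range(n)]

    names = (
        [f"lambda[{mid}]" for mid in model.metabolite_ids]
        + [f"mu_LB[{rid}]" for rid in model.reaction_ids]
        + [f"mu_UB[{rid}]" for rid in model.reaction_ids]
    )
    return DualProgram(obj, A_eq, c_primal, bounds, names)


def shadow_price_range(
    model: MetabolicModel,
    metabolite_id: str,
    lam: float,
    z0: float,
    tol: float = DEFAULT_TOL,
    cap: float = RANGE_CAP,
) -> Tuple[float, float]:
    """Validity range [G-, G+] of a shadow price.

    Solves, for each direction, an LP over (v, delta) that pushes delta as
    far as possible while keeping ``c'v >= Z0 + lam*delta - tol``; because
    Z(delta) is concave with supergradient lam at 0, feasibility of that
    constraint characterizes the linear piece on which lam is valid.
    Endpoints at the numerical cap are reported as +/- infinity.
    """
    i = model.metabolite_index(metabolite_id)
    m, n = model.n_metabolites, model.n_reactions
    S = model.stoichiometric_matrix().toarray()
    c = model.objective_vector()

    A_eq = np.hstack([S, np.zeros((m, 1))])
    A_eq[i, n] = -1.0
    b_eq = model.b
    # -c'v + lam*delta <= -Z0 + tol
    A_ub = np.concatenate([-c, [lam]])[None, :]
    b_ub = np.array([-z0 + tol])
    base_bounds = model.bounds()

    out = []
    for sense, dbounds in ((+1.0, (0.0, cap)), (-1.0, (-cap, 0.0))):
        obj = np.zeros(n + 1)
        obj[n] = -sense  # maximize sense*delta
        res = solve_lp(
            obj, A_eq=A_eq, b_eq=b_eq, bounds=base_bounds + [dbounds], A_ub=A_ub, b_ub=b_ub
        )
        if not res.is_optimal:
            raise SolverError(
                f"ranging LP for {metabolite_id!r} returned {res.status}"
            )
        val = float(res.x[n])
        if abs(val) >= 0.99 * cap:
            val = float(np.inf) * sense
        out.append(val)
    g_plus, g_minus = out
    return g_minus, g_plus


def shadow_price_table(
    model: MetabolicModel,
    dual: Optional[DualSolution] = None,
    eps_range: float = DEFAULT_TOL,
    tol: float = DEFAULT_TOL,
) -> List[ShadowPriceRecord]:
    """One shadow-price record per metabolite, with validity ranges.

    Records whose range width ``G+ - G-`` falls below ``eps_range`` are
    marked invalid and should be discarded from downstream comparisons.
    """
    primal, solved_dual = solve_fba(model)
    if not primal.is_optimal:
        raise SolverError(f"base FBA solve is {primal.status}; cannot build table")
    if dual is None:
        dual = solved_dual
    z0 = primal.objective_value
    records = []
    for met, lam in zip(model.metabolites, dual.shadow_prices):
        g_minus, g_plus = shadow_price_range(model, met.id, float(lam), z0, tol=tol)
        width = g_plus - g_minus
        records.append(
            ShadowPriceRecord(
                metabolite_id=met.id,
                compartment=met.compartment,
                lam=float(lam),
                range_low=g_minus,
                range_high=g_plus,
                valid=bool(width >= eps_range),
            )
        )
    return records
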