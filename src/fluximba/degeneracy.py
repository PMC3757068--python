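"""Brute-force validation of shadow prices against alternate optima.

At a degenerate optimum the dual solution is not unique: the sensitivity of
the objective to a flux imbalance can differ depending on whether the
metabolite accumulates (b_i > 0) or depletes (b_i < 0).  The solver's
shadow price is then ambiguous.  The check here re-derives the sensitivity
by brute force: re-solve the primal with b_i displaced into the validity
range by a fraction ``p`` and form the finite difference

    lambda+ = (Z(+delta) - Z(0)) / +delta      (incremental)
    lambda- = (Z(-delta) - Z(0)) / -delta      (decremental)

and flag any metabolite whose recomputed sensitivities disagree with the
solver's dual value beyond tolerance.  When the validity range is one-sided
(G+ = 0 or G- = 0), the valid direction reproduces the solver value by
construction, so the probe into the zero-width direction is what actually
reveals the second supergradient; the checker probes it with a small trial
displacement, shrinking on infeasibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .duality import DEFAULT_TOL, shadow_price_range, solve_fba
from .exceptions import FluximbaError, SolverError
from .model import MetabolicModel

#: default perturbation fraction of the validity range
DEFAULT_P = 0.2

#: default mismatch tolerance, ten times the solver feasibility tolerance
DEFAULT_DEGENERACY_TOL = 10 * DEFAULT_TOL


@dataclass
class DegeneracyRecord:
    metabolite_id: str
    lam_solver: float
    lam_plus: Optional[float]
    lam_minus: Optional[float]
    perturbation_fraction: float
    degenerate: bool


def perturbed_objective(model: MetabolicModel, metabolite_id: str, delta: float):
    """Optimal objective with metabolite's RHS displaced by delta; None if infeasible."""
    b = model.b.copy()
    b[model.metabolite_index(metabolite_id)] += delta
    primal, _ = solve_fba(model, b=b)
    if not primal.is_optimal:
        return None
    return primal.objective_value


def _finite_difference(model, metabolite_id, delta, z0) -> float:
    z = perturbed_objective(model, metabolite_id, delta)
    if z is None:
        raise SolverError(
            f"perturbed LP infeasible for {metabolite_id!r} at delta={delta}"
        )
    return (z - z0) / delta


def incremental_shadow_price(
    model: MetabolicModel, metabolite_id: str, p: float = DEFAULT_P
) -> float:
    """lambda+ from re-solving with b_i = p * G+ (accumulation)."""
    if not 0 < p < 1:
        raise ValueError(f"perturbation fraction p must be in (0,1), got {p}")
    primal, dual = solve_fba(model)
    if not primal.is_optimal:
        raise SolverError(f"base FBA solve is {primal.status}")
    i = model.metabolite_index(metabolite_id)
    lam = float(dual.shadow_prices[i])
    g_minus, g_plus = shadow_price_range(
        model, metabolite_id, lam, primal.objective_value
    )
    if g_plus <= 0:
        raise FluximbaError(
            f"cannot perturb up: G+ = {g_plus} for metabolite {metabolite_id!r}"
        )
    delta = p * min(g_plus, 1e6)
    return _finite_difference(model, metabolite_id, delta, primal.objective_value)


def decremental_shadow_price(
    model: MetabolicModel, metabolite_id: str, p: float = DEFAULT_P
) -> float:
    """lambda- from re-solving with b_i = p * G- (depletion)."""
    if not 0 < p < 1:
        raise ValueError(f"perturbation fraction p must be in (0,1), got {p}")
    primal, dual = solve_fba(model)
    if not primal.is_optimal:
        raise SolverError(f"base FBA solve is {primal.status}")
    i = model.metabolite_index(metabolite_id)
    lam = float(dual.shadow_prices[i])
    g_minus, g_plus = shadow_price_range(
        model, metabolite_id, lam, primal.objective_value
    )
    if g_minus >= 0:
        raise FluximbaError(
            f"cannot perturb down: G- = {g_minus} for metabolite {metabolite_id!r}"
        )
    delta = p * max(g_minus, -1e6)
    return _finite_difference(model, metabolite_id, delta, primal.objective_value)


def _probe(model, metabolite_id, delta, z0, max_shrink: int = 40):
    """Finite difference at delta, geometrically shrinking while infeasible."""
    for _ in range(max_shrink):
        z = perturbed_objective(model, metabolite_id, delta)
        if z is not None:
            return (z - z0) / delta
        delta *= 0.5
        if abs(delta) < 1e-12:
            break
    return None


def check_degeneracy(
    model: MetabolicModel,
    metabolite_ids: Optional[Iterable[str]] = None,
    p: float = DEFAULT_P,
    tolerance: float = DEFAULT_DEGENERACY_TOL,
) -> List[DegeneracyRecord]:
    """Compare solver shadow prices against brute-force recomputation.

    For each metabolite, lambda+ is recomputed when the validity range
    extends upward and lambda- when it extends downward; a zero-width
    direction is probed with a small trial displacement so that a kink in
    Z(b_i) at the optimum (a degenerate dual) is still detected.  A record
    is flagged degenerate when any recomputed value deviates from the
    solver's by more than ``tolerance``.  Input model is never mutated.
    """
    if not 0 < p < 1:
        raise ValueError(f"perturbation fraction p must be in (0,1), got {p}")
    primal, dual = solve_fba(model)
    if not primal.is_optimal:
        raise SolverError(f"base FBA solve is {primal.status}")
    z0 = primal.objective_value
    ids = list(metabolite_ids) if metabolite_ids is not None else model.metabolite_ids
    records = []
    for met_id in ids:
        i = model.metabolite_index(met_id)
        lam = float(dual.shadow_prices[i])
        g_minus, g_plus = shadow_price_range(model, met_id, lam, z0)
        probe_scale = max(
            abs(g_minus) if np.isfinite(g_minus) else 0.0,
            abs(g_plus) if np.isfinite(g_plus) else 0.0,
            1.0,
        )
        # a validity range whose width is on the order of the solver
        # tolerance is treated as zero-width: perturbing inside it would
        # divide solver noise by a near-zero delta
        width_floor = 1e-4 * probe_scale
        lam_plus = lam_minus = None
        if g_plus > width_floor:
            delta = p * (g_plus if np.isfinite(g_plus) else probe_scale)
            lam_plus = _probe(model, met_id, delta, z0)
        else:
            lam_plus = _probe(model, met_id, p * min(probe_scale, 1e6), z0)
        if g_minus < -width_floor:
            delta = p * (g_minus if np.isfinite(g_minus) else -probe_scale)
            lam_minus = _probe(model, met_id, delta, z0)
        else:
            lam_minus = _probe(model, met_id, -p * min(probe_scale, 1e6), z0)
        degenerate = any(
            v is not None and abs(v - lam) > tolerance for v in (lam_plus, lam_minus)
        )
        records.append(
            DegeneracyRecord(met_id, lam, lam_plus, lam_minus, p, degenerate)
        )
    return records


def classify_growth_limiting(
    records, eps: float = DEFAULT_TOL
) -> Dict[str, str]:
    """Classify metabolites by shadow-price sign under growth maximization.

    ``lambda < -eps`` -> ``"limiting"`` (extra outflow raises growth);
    ``|lambda| <= eps`` -> ``"non_limiting"``.  Positive shadow prices of
    intracellular metabolites fall outside the growth-limitation dichotomy
    and are reported as ``"positive"`` without further interpretation.
    """
    out = {}
    for rec in records:
        if rec.lam < -eps:
            out[rec.metabolite_id] = "limiting"
        elif rec.lam <= eps:
            out[rec.metabolite_id] = "non_limiting"
        else:
            out[rec.metabolite_id] = "positive"
    return out


def differential_shadow_prices(
    wild_type: MetabolicModel, knockout: MetabolicModel
) -> pd.DataFrame:
    """Per-metabolite shadow-price change (knockout minus wild type).

    Both models must share the same metabolite ordering (knockouts zero
    bounds rather than delete columns precisely so this alignment holds).
    """
    if wild_type.metabolite_ids != knockout.metabolite_ids:
        raise FluximbaError("models have different metabolite orderings")
    _, dual_wt = solve_fba(wild_type)
    _, dual_ko = solve_fba(knockout)
    if dual_wt is None or dual_ko is None:
        raise SolverError("both models must solve to optimality")
    return pd.DataFrame(
        {
            "metabolite_id": wild_type.metabolite_ids,
            "lambda_wt": dual_wt.shadow_prices,
            "lambda_ko": dual_ko.shadow_prices,
            "delta_lambda": dual_ko.shadow_prices - dual_wt.shadow_prices,
        }
    )


def degeneracy_report(records: List[DegeneracyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in records],
            "lambda_solver": [r.lam_solver for r in records],
            "lambda_plus": [r.lam_plus for r in records],
            "lambda_minus": [r.lam_minus for r in records],
            "p": [r.perturbation_fraction for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )
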