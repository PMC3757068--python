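"""Expression-data integration in the GIMME/TEAM style.

Instead of maximizing growth, the LP here minimizes an *inconsistency
score* (IS) between predicted fluxes and measured gene expression::

    min  sum_j c_j |v_j|
    s.t. S v = b
         v_LB <= v <= v_UB
         v_RMF >= v_RMF,min

where ``c_j >= 0`` penalizes flux through reactions whose genes are lowly
expressed, and the *required metabolic functionality* (RMF) constraint —
e.g. acetate secretion at 30% of its FBA maximum — excludes the trivial
all-zero flux solution.

Gene penalties are threshold-based and gene-specific: the threshold x_g is
the theta-quantile of gene g's own expression distribution across samples,
and p_g = max(0, x_g - EXP_g).  Penalties propagate to reactions through
the GPR rules (OR -> min, AND -> max).

Shadow prices of the TEAM LP follow lambda_i = d(IS*)/db_i with IS
*minimized*, so a positive shadow price means that letting the metabolite
deplete (b_i < 0) lowers the inconsistency: its abundance is predicted to
*decrease*.  Negative shadow prices predict accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from ._linprog import solve_lp
from .duality import DEFAULT_TOL
from .exceptions import (
    InfeasibleProblemError,
    RmfUnreachableError,
    ValidationError,
)
from .model import MetabolicModel

#: default penalty-threshold percentile
DEFAULT_THETA = 0.88

#: default RMF fraction of the FBA maximum
DEFAULT_RMF_FRACTION = 0.3


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix."""

    genes: List[str]
    samples: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionDataset":
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in table.index],
            samples=[str(s) for s in table.columns],
            values=table.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.samples).to_csv(
            path, sep="\t", index_label="gene"
        )

    def sample_values(self, sample: str) -> Dict[str, float]:
        j = self.samples.index(sample)
        return {g: float(self.values[i, j]) for i, g in enumerate(self.genes)}


@dataclass
class PenaltyModel:
    theta: float
    thresholds: Dict[str, float]
    gene_penalties: Dict[str, float]
    reaction_penalties: np.ndarray


@dataclass
class TEAMSolution:
    fluxes: np.ndarray
    inconsistency_score: float
    shadow_prices: np.ndarray
    rmf_reaction_id: str
    rmf_min: float
    metabolite_ids: List[str] = field(default_factory=list)
    directions: Dict[str, str] = field(default_factory=dict)


def gene_thresholds(expr: ExpressionDataset, theta: float = DEFAULT_THETA) -> Dict[str, float]:
    """Per-gene penalty threshold x_g: the theta-quantile of the gene's own
    expression distribution across all samples (linear interpolation between
    order statistics, so thresholds vary continuously in theta)."""
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0,1), got {theta}")
    thresholds = {}
    for i, gene in enumerate(expr.genes):
        row = expr.values[i]
        if row.size == 1:
            warnings.warn(
                f"gene {gene!r} has a single measurement; threshold set to it",
                stacklevel=2,
            )
            thresholds[gene] = float(row[0])
        else:
            thresholds[gene] = float(np.quantile(row, theta))
    return thresholds


def gene_penalties(
    expr_sample: Dict[str, float], thresholds: Dict[str, float]
) -> Dict[str, float]:
    """p_g = max(0, x_g - EXP_g): only below-threshold expression is penalized."""
    missing = set(expr_sample) - set(thresholds)
    if missing:
        raise ValidationError(f"no thresholds for genes {sorted(missing)}")
    return {
        g: max(0.0, thresholds[g] - exp_g) for g, exp_g in expr_sample.items()
    }


def reaction_penalties(
    model: MetabolicModel, penalties: Dict[str, float]
) -> np.ndarray:
    """Map gene penalties to reaction penalties through the GPR rules.

    OR -> minimum (any isozyme suffices), AND -> maximum (a complex is
    limited by its least-expressed member).  Empty GPR or genes without
    data contribute penalty 0.
    """
    c = np.zeros(model.n_reactions)
    for j, rxn in enumerate(model.reactions):
        tree = rxn.gpr_tree
        if tree is not None:
            c[j] = tree.penalty(penalties)
    return c


def penalty_model(
    model: MetabolicModel,
    expr: ExpressionDataset,
    sample: str,
    theta: float = DEFAULT_THETA,
) -> PenaltyModel:
    """Thresholds -> gene penalties -> reaction penalty vector in one step."""
    thresholds = gene_thresholds(expr, theta)
    p_g = gene_penalties(expr.sample_values(sample), thresholds)
    c = reaction_penalties(model, p_g)
    return PenaltyModel(theta, thresholds, p_g, c)


def rmf_bound(
    model: MetabolicModel,
    rmf_reaction_id: str,
    fraction: float = DEFAULT_RMF_FRACTION,
    tol: float = DEFAULT_TOL,
) -> float:
    """Minimum RMF flux: ``fraction`` times the FBA maximum of the RMF flux."""
    if not 0 < fraction <= 1:
        raise ValueError(f"RMF fraction must be in (0,1], got {fraction}")
    j = model.reaction_index(rmf_reaction_id)
    obj = np.zeros(model.n_reactions)
    obj[j] = -1.0  # maximize v_RMF
    res = solve_lp(
        obj,
        A_eq=model.stoichiometric_matrix(),
        b_eq=model.b,
        bounds=model.bounds(),
    )
    if not res.is_optimal:
        raise InfeasibleProblemError(
            f"FBA maximization of RMF {rmf_reaction_id!r} is {res.status}"
        )
    v_max = -res.objective
    if v_max <= tol:
        raise RmfUnreachableError(
            f"RMF {rmf_reaction_id!r} has zero maximum flux; the constraint "
            "would admit the trivial all-zero solution"
        )
    return fraction * v_max


def solve_team(
    model: MetabolicModel,
    c: np.ndarray,
    rmf_reaction_id: str,
    rmf_min: float,
    b: Optional[np.ndarray] = None,
    tol: float = DEFAULT_TOL,
) -> TEAMSolution:
    """Minimize the inconsistency score subject to the RMF constraint.

    The objective sum_j c_j |v_j| penalizes flux *magnitude* so that
    reversible reactions cannot earn negative penalty by running backward;
    the absolute values are linearized with auxiliary variables
    t_j >= |v_j| (equivalent to splitting each reaction into two
    nonnegative half-reactions that share the penalty c_j).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (model.n_reactions,):
        raise ValidationError(
            f"penalty vector has shape {c.shape}, expected ({model.n_reactions},)"
        )
    if np.any(c < 0):
        raise ValidationError("reaction penalties must be nonnegative")
    n, m = model.n_reactions, model.n_metabolites
    j_rmf = model.reaction_index(rmf_reaction_id)
    S = model.stoichiometric_matrix().toarray()
    rhs = model.b if b is None else np.asarray(b, dtype=float)

    # variables: [v (n), t (n)], minimize c @ t
    obj = np.concatenate([np.zeros(n), c])
    A_eq = np.hstack([S, np.zeros((m, n))])
    # t_j >= v_j  and  t_j >= -v_j
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),
            np.hstack([-np.eye(n), -np.eye(n)]),
        ]
    )
    b_ub = np.zeros(2 * n)
    bounds = model.bounds()
    lb_rmf, ub_rmf = bounds[j_rmf]
    if rmf_min > ub_rmf + tol:
        raise InfeasibleProblemError(
            f"rmf_min {rmf_min} exceeds the upper bound of {rmf_reaction_id!r}"
        )
    bounds[j_rmf] = (max(lb_rmf, rmf_min), ub_rmf)
    bounds += [(0.0, None)] * n

    res = solve_lp(obj, A_eq=A_eq, b_eq=rhs, bounds=bounds, A_ub=A_ub, b_ub=b_ub)
    if not res.is_optimal:
        raise InfeasibleProblemError(
            f"TEAM LP is {res.status} (rmf_min={rmf_min} may be too high)"
        )
    fluxes = res.x[:n]
    # minimization problem: scipy's equality marginals are d(IS*)/db directly
    lam = res.eq_marginals.copy()
    solution = TEAMSolution(
        fluxes=fluxes,
        inconsistency_score=float(res.objective),
        shadow_prices=lam,
        rmf_reaction_id=rmf_reaction_id,
        rmf_min=float(rmf_min),
        metabolite_ids=model.metabolite_ids,
    )
    solution.directions = predict_direction(solution, tol=tol)
    return solution


def predict_direction(solution: TEAMSolution, tol: float = DEFAULT_TOL) -> Dict[str, str]:
    """Predicted abundance change per metabolite from TEAM shadow prices.

    lambda > tol -> "decrease" (letting the metabolite deplete lowers IS);
    lambda < -tol -> "increase"; otherwise "none".
    """
    out = {}
    for met_id, lam in zip(solution.metabolite_ids, solution.shadow_prices):
        if lam > tol:
            out[met_id] = "decrease"
        elif lam < -tol:
            out[met_id] = "increase"
        else:
            out[met_id] = "none"
    return out


def theta_scan(
    model: MetabolicModel,
    expr: ExpressionDataset,
    sample: str,
    rmf_reaction_id: str,
    theta_grid: Iterable[float],
    score: Callable[[float, TEAMSolution], float],
    rmf_fraction: float = DEFAULT_RMF_FRACTION,
) -> pd.DataFrame:
    """Re-run thresholds -> penalties -> TEAM per theta and score each solve.

    ``score(theta, solution)`` is caller-supplied (e.g. a correlation with
    observed abundance changes).  Returns a table theta -> score, IS.
    """
    rmf_min = rmf_bound(model, rmf_reaction_id, rmf_fraction)
    rows = []
    for theta in theta_grid:
        pm = penalty_model(model, expr, sample, theta)
        sol = solve_team(model, pm.reaction_penalties, rmf_reaction_id, rmf_min)
        rows.append(
            {
                "theta": theta,
                "score": float(score(theta, sol)),
                "inconsistency_score": sol.inconsistency_score,
            }
        )
    return pd.DataFrame(rows)


def team_report(solution: TEAMSolution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite_id": solution.metabolite_ids,
            "shadow_price": solution.shadow_prices,
            "predicted_direction": [
                solution.directions[m] for m in solution.metabolite_ids
            ],
        }
    )
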