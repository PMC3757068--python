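"""End-to-end flux-imbalance report: solve, shadow prices, degeneracy
check, growth-limitation classification, with optional expression and
time-course joins.  All outputs are TSV/JSON; the full configuration is
echoed into a run-metadata file so runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import io as model_io
from .degeneracy import (
    DEFAULT_DEGENERACY_TOL,
    DEFAULT_P,
    check_degeneracy,
    classify_growth_limiting,
    degeneracy_report,
)
from .duality import DEFAULT_TOL, shadow_price_table, solve_fba
from .exceptions import InfeasibleProblemError
from .model import MetabolicModel, knockout_genes, apply_medium
from .stats import permutation_test, read_timecourses, variation_table
from .team import (
    DEFAULT_RMF_FRACTION,
    DEFAULT_THETA,
    ExpressionDataset,
    penalty_model,
    rmf_bound,
    solve_team,
    team_report,
)

logger = logging.getLogger("fluximba")


@dataclass
class RunConfig:
    model_path: str
    model_format: Optional[str] = None
    medium_path: Optional[str] = None
    knockouts: List[str] = field(default_factory=list)
    tolerance: float = DEFAULT_TOL
    eps_range: float = DEFAULT_TOL
    p: float = DEFAULT_P
    degeneracy_tolerance: float = DEFAULT_DEGENERACY_TOL
    # optional expression join
    expression_path: Optional[str] = None
    expression_sample: Optional[str] = None
    theta: float = DEFAULT_THETA
    rmf_reaction: Optional[str] = None
    rmf_fraction: float = DEFAULT_RMF_FRACTION
    # optional time-course join
    timecourse_path: Optional[str] = None
    window_minutes: float = 30.0
    n_perm: int = 100_000
    center: str = "mean"
    seed: int = 0
    output_dir: str = "fluximba_report"


def _load_model(config: RunConfig) -> MetabolicModel:
    model = model_io.read_model(config.model_path, format=config.model_format)
    if config.medium_path:
        model = apply_medium(model, model_io.read_medium(config.medium_path))
    if config.knockouts:
        model = knockout_genes(model, config.knockouts)
    return model


def run_report(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline and write a report bundle to disk.

    Returns a summary dictionary (also written as ``summary.json``).
    Raises :class:`InfeasibleProblemError` if the (possibly knocked-out)
    model does not solve to optimality.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = _load_model(config)
    logger.info("loaded model %s", model)

    primal, dual = solve_fba(model)
    if not primal.is_optimal:
        raise InfeasibleProblemError(
            f"model_core/lp_duality: FBA is {primal.status}"
            + (" (possible lethal knockout)" if primal.lethal else ""),
            lethal=primal.lethal,
        )
    records = shadow_price_table(
        model, dual, eps_range=config.eps_range, tol=config.tolerance
    )
    sp_table = pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in records],
            "compartment": [r.compartment for r in records],
            "lambda": [r.lam for r in records],
            "range_low": [r.range_low for r in records],
            "range_high": [r.range_high for r in records],
            "valid": [r.valid for r in records],
        }
    )
    sp_table.to_csv(outdir / "shadow_prices.tsv", sep="\t", index=False)

    degen = check_degeneracy(
        model, p=config.p, tolerance=config.degeneracy_tolerance
    )
    degeneracy_report(degen).to_csv(outdir / "degeneracy.tsv", sep="\t", index=False)

    classes = classify_growth_limiting(records, eps=config.tolerance)
    pd.DataFrame(
        {"metabolite_id": list(classes), "class": list(classes.values())}
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)

    summary: Dict[str, object] = {
        "objective_value": primal.objective_value,
        "n_metabolites": model.n_metabolites,
        "n_reactions": model.n_reactions,
        "n_limiting": sum(1 for v in classes.values() if v == "limiting"),
        "n_degenerate": sum(1 for r in degen if r.degenerate),
        "config": dataclasses.asdict(config),
    }

    if config.expression_path and config.rmf_reaction:
        expr = ExpressionDataset.from_tsv(config.expression_path)
        sample = config.expression_sample or expr.samples[-1]
        pm = penalty_model(model, expr, sample, config.theta)
        rmf_min = rmf_bound(model, config.rmf_reaction, config.rmf_fraction)
        team_sol = solve_team(model, pm.reaction_penalties, config.rmf_reaction, rmf_min)
        team_report(team_sol).to_csv(outdir / "team.tsv", sep="\t", index=False)
        summary["team"] = {
            "theta": config.theta,
            "rmf_reaction": config.rmf_reaction,
            "rmf_fraction": config.rmf_fraction,
            "rmf_min": team_sol.rmf_min,
            "inconsistency_score": team_sol.inconsistency_score,
        }

    if config.timecourse_path:
        tcs = read_timecourses(config.timecourse_path)
        shadow = {r.metabolite_id: r.lam for r in records if r.valid}
        var_records = variation_table(tcs, shadow, config.window_minutes)
        joint = pd.DataFrame(
            {
                "metabolite_id": [r.metabolite_id for r in var_records],
                "shadow_price": [r.lam for r in var_records],
                "cv": [r.cv for r in var_records],
            }
        )
        joint.to_csv(outdir / "dynamics.tsv", sep="\t", index=False)
        if len(var_records) >= 3:
            perm = permutation_test(
                var_records,
                n_perm=config.n_perm,
                center=config.center,
                seed=config.seed,
            )
            summary["dynamics"] = {
                "m_s": perm.m_s,
                "m_t": perm.m_t,
                "p_original": perm.p_original,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value,
                "center": perm.center,
            }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
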