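"""Deterministic toy networks and seeded synthetic-data generators.

Every fixture carries a ground-truth record derived analytically (by hand
LP solution, annotated below), never from the solvers under test, so the
fixtures double as independent oracles.

Fixture kinds
-------------
``figure1``
    One metabolite M, a source (0 <= v1 <= 10) and an objective sink
    (0 <= v2 <= 1000).  Hand LP: the optimum saturates the source, Z = 10.
    Accumulation b = delta removes delta of sink flux, Z = 10 - delta;
    depletion adds sink flux until the sink cap at delta = -990.  So
    lambda_M = -1, valid over [-990, 10], lambda+ = lambda- = -1.
``degenerate``
    M fed by a source (cap 5) and drained by two sinks: A (cap 5, weight 1)
    and B (cap 1000, weight 0.5).  Hand LP: Z = 5 via sink A.  Tightening
    (b > 0) removes weight-1 flux, slope -1; relaxing (b < 0) routes the
    surplus through the weight-0.5 sink, slope -0.5.  Z(b) has a kink at 0:
    lambda+ = -1 differs from lambda- = -0.5 (a degenerate dual).
``branched``
    Linear chain A -> B through an uptake cap of 10; Z = 10 and
    lambda_A = lambda_B = -1 (hand LP as in figure1).
``two_pathway_team``
    M producible by a high-expression pathway (gene g_hi) or a
    low-expression one (g_lo), drained by an RMF sink.  With penalties
    c_hi = 0, c_lo = 1 all flux routes through the free pathway: IS = 0.
``nitrogen_assimilation``
    Ammonium N assimilated into G by two redundant pathways, GDH-like
    (gene gdhA) and GOGAT-like (complex gltB and gltD), with a growth
    demand on G.  Single knockouts reroute (Z = 10 either way, identical
    shadow prices); the double knockout cuts both pathways and the growth
    demand makes the model infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .model import Metabolite, MetabolicModel, Reaction
from .stats import TimeCourse
from .team import ExpressionDataset

FIXTURE_KINDS = (
    "figure1",
    "degenerate",
    "branched",
    "two_pathway_team",
    "nitrogen_assimilation",
)


@dataclass
class FixtureSpec:
    kind: str
    parameters: Dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec) -> Tuple[MetabolicModel, Dict]:
    """Build a named toy model and its analytically derived ground truth."""
    if isinstance(spec, str):
        spec = FixtureSpec(kind=spec)
    builder = {
        "figure1": _figure1,
        "degenerate": _degenerate,
        "branched": _branched,
        "two_pathway_team": _two_pathway_team,
        "nitrogen_assimilation": _nitrogen_assimilation,
    }.get(spec.kind)
    if builder is None:
        raise ValueError(
            f"unknown fixture kind {spec.kind!r}; expected one of {FIXTURE_KINDS}"
        )
    return builder(spec.parameters)


def _figure1(params) -> Tuple[MetabolicModel, Dict]:
    source_cap = params.get("source_cap", 10.0)
    sink_cap = params.get("sink_cap", 1000.0)
    model = MetabolicModel(
        metabolites=[Metabolite("M[c]", "M", "c")],
        reactions=[
            Reaction("R1", {"M[c]": 1.0}, 0.0, source_cap),
            Reaction("R2", {"M[c]": -1.0}, 0.0, sink_cap),
        ],
        objective={"R2": 1.0},
        name="figure1",
    )
    truth = {
        "Z": source_cap,
        "fluxes": {"R1": source_cap, "R2": source_cap},
        "lambda": {"M[c]": -1.0},
        "range": {"M[c]": (-(sink_cap - source_cap), source_cap)},
        "lambda_plus": {"M[c]": -1.0},
        "lambda_minus": {"M[c]": -1.0},
        "degenerate": [],
    }
    return model, truth


def _degenerate(params) -> Tuple[MetabolicModel, Dict]:
    source_cap = params.get("source_cap", 5.0)
    model = MetabolicModel(
        metabolites=[Metabolite("M[c]", "M", "c")],
        reactions=[
            Reaction("SRC", {"M[c]": 1.0}, 0.0, source_cap),
            Reaction("SINK_A", {"M[c]": -1.0}, 0.0, source_cap),
            Reaction("SINK_B", {"M[c]": -1.0}, 0.0, 1000.0),
        ],
        objective={"SINK_A": 1.0, "SINK_B": 0.5},
        name="degenerate",
    )
    truth = {
        "Z": source_cap,
        "lambda_plus": {"M[c]": -1.0},
        "lambda_minus": {"M[c]": -0.5},
        "degenerate": ["M[c]"],
    }
    return model, truth


def _branched(params) -> Tuple[MetabolicModel, Dict]:
    uptake_cap = params.get("uptake_cap", 10.0)
    model = MetabolicModel(
        metabolites=[Metabolite("A[c]", "A", "c"), Metabolite("B[c]", "B", "c")],
        reactions=[
            Reaction("UP", {"A[c]": 1.0}, 0.0, uptake_cap),
            Reaction("CONV", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 100.0),
            Reaction("OUT", {"B[c]": -1.0}, 0.0, 100.0),
        ],
        objective={"OUT": 1.0},
        name="branched",
    )
    truth = {
        "Z": uptake_cap,
        "lambda": {"A[c]": -1.0, "B[c]": -1.0},
    }
    return model, truth


def _two_pathway_team(params) -> Tuple[MetabolicModel, Dict]:
    cap = params.get("cap", 10.0)
    model = MetabolicModel(
        metabolites=[Metabolite("M[c]", "M", "c")],
        reactions=[
            Reaction("R_HI", {"M[c]": 1.0}, 0.0, cap, gpr="g_hi"),
            Reaction("R_LO", {"M[c]": 1.0}, 0.0, cap, gpr="g_lo"),
            Reaction("RMF", {"M[c]": -1.0}, 0.0, cap),
        ],
        name="two_pathway_team",
    )
    truth = {
        "rmf_reaction": "RMF",
        "rmf_max": cap,
        "IS": 0.0,  # all flux routes through the zero-penalty pathway
        "active_reactions": ["R_HI", "RMF"],
        "inactive_reactions": ["R_LO"],
    }
    return model, truth


def _nitrogen_assimilation(params) -> Tuple[MetabolicModel, Dict]:
    uptake = params.get("uptake", 10.0)
    growth_demand = params.get("growth_demand", 0.1)
    model = MetabolicModel(
        metabolites=[Metabolite("N[c]", "ammonium", "c"), Metabolite("G[c]", "glutamate", "c")],
        reactions=[
            Reaction("EX_N", {"N[c]": -1.0}, -uptake, 1000.0),
            Reaction("GDH", {"N[c]": -1.0, "G[c]": 1.0}, 0.0, 100.0, gpr="gdhA"),
            Reaction("GOGAT", {"N[c]": -1.0, "G[c]": 1.0}, 0.0, 100.0, gpr="gltB and gltD"),
            Reaction("GROWTH", {"G[c]": -1.0}, growth_demand, 1000.0),
        ],
        objective={"GROWTH": 1.0},
        name="nitrogen_assimilation",
    )
    truth = {
        "Z": uptake,
        "gdh_genes": {"gdhA"},
        "gogat_genes": {"gltB", "gltD"},
        # either single knockout reroutes through the redundant pathway
        "Z_single_knockout": uptake,
        "double_knockout_infeasible": True,
    }
    return model, truth


# -- team toys ---------------------------------------------------------------


def team_toy(polarity: str = "producer") -> Tuple[MetabolicModel, np.ndarray, str, float, Dict]:
    """Minimal TEAM fixtures with hand-derived shadow prices.

    ``producer``: M is produced only by a penalized reaction (c = 2) and
    drained by the RMF sink with rmf_min = 1, so IS = 2.  Accumulation
    b = delta forces extra penalized flux: IS(delta) = 2(1 + delta), hence
    lambda_M = +2 and the metabolite is predicted to *decrease*.

    ``consumer``: the RMF produces M and the only drain is penalized; now
    accumulation spares penalized flux, IS(delta) = 2(1 - delta), hence
    lambda_M = -2 and the metabolite is predicted to *increase*.
    """
    if polarity == "producer":
        model = MetabolicModel(
            metabolites=[Metabolite("M[c]", "M", "c")],
            reactions=[
                Reaction("R_P", {"M[c]": 1.0}, 0.0, 10.0, gpr="g_p"),
                Reaction("RMF", {"M[c]": -1.0}, 0.0, 10.0),
            ],
            name="team_toy_producer",
        )
        penalties = np.array([2.0, 0.0])
        truth = {"IS": 2.0, "lambda": {"M[c]": 2.0}, "direction": {"M[c]": "decrease"}}
    elif polarity == "consumer":
        model = MetabolicModel(
            metabolites=[Metabolite("M[c]", "M", "c")],
            reactions=[
                Reaction("RMF", {"M[c]": 1.0}, 0.0, 10.0),
                Reaction("R_C", {"M[c]": -1.0}, 0.0, 10.0, gpr="g_c"),
            ],
            name="team_toy_consumer",
        )
        penalties = np.array([0.0, 2.0])
        truth = {"IS": 2.0, "lambda": {"M[c]": -2.0}, "direction": {"M[c]": "increase"}}
    else:
        raise ValueError(f"polarity must be 'producer' or 'consumer', got {polarity!r}")
    return model, penalties, "RMF", 1.0, truth


# -- random models -----------------------------------------------------------


def make_random_model(
    seed: int,
    n_metabolites: int = 6,
    n_reactions: int = 12,
) -> MetabolicModel:
    """Random feasible, bounded FBA instance.

    Finite bounds guarantee boundedness; the right-hand side is set to
    S @ v0 for a random interior flux vector v0, guaranteeing feasibility.
    Continuous random coefficients make accidental degeneracy a
    measure-zero event.
    """
    rng = np.random.default_rng(seed)
    metabolites = [Metabolite(f"M{i}[c]", f"M{i}", "c") for i in range(n_metabolites)]
    reactions = []
    S = np.zeros((n_metabolites, n_reactions))
    for j in range(n_reactions):
        k = int(rng.integers(1, min(3, n_metabolites) + 1))
        rows = rng.choice(n_metabolites, size=k, replace=False)
        for i in rows:
            coef = float(rng.uniform(0.2, 2.0)) * (1 if rng.random() < 0.5 else -1)
            S[i, j] = coef
        lb = float(rng.uniform(-10.0, 0.0))
        ub = lb + float(rng.uniform(1.0, 10.0))
        reactions.append(
            Reaction(
                f"R{j}",
                {f"M{i}[c]": S[i, j] for i in rows},
                lb,
                ub,
            )
        )
    lbs = np.array([r.lower_bound for r in reactions])
    ubs = np.array([r.upper_bound for r in reactions])
    v0 = rng.uniform(lbs, ubs)
    b = S @ v0
    weights = rng.normal(size=n_reactions)
    weights[rng.random(n_reactions) > 0.7] = 0.0
    objective = {f"R{j}": float(weights[j]) for j in range(n_reactions) if weights[j]}
    if not objective:
        objective = {"R0": 1.0}
    return MetabolicModel(metabolites, reactions, objective, b=b, name=f"random-{seed}")


# -- synthetic expression ----------------------------------------------------


def simulate_expression(
    model: MetabolicModel,
    active_reactions: Iterable[str],
    n_samples: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ExpressionDataset:
    """Synthetic expression matrix with a designated ``condition`` sample.

    Genes of active reactions are drawn high in the condition sample
    (above any theta-quantile of their own distribution for theta < 1);
    genes of inactive reactions are drawn low (below the 0.88 quantile, so
    their reactions pick up positive penalties).  Background samples carry
    a deterministic within-gene spread plus Gaussian noise; the whole
    matrix is a pure function of the seed.
    """
    active_reactions = set(active_reactions)
    unknown = active_reactions - set(model.reaction_ids)
    if unknown:
        raise ValueError(f"unknown reactions {sorted(unknown)}")
    active_genes = set()
    for rid in active_reactions:
        active_genes |= model.get_reaction(rid).genes
    genes = sorted(model.genes)
    rng = np.random.default_rng(seed)
    n_bg = max(2, n_samples - 1)
    ramp = np.linspace(-1.0, 1.0, n_bg)
    rows = []
    for gene in genes:
        base = float(rng.uniform(8.0, 12.0))
        spread = float(rng.uniform(0.5, 1.5))
        background = base + spread * ramp + rng.normal(0.0, noise_sd, n_bg)
        shift = 3.0 * spread if gene in active_genes else -3.0 * spread
        condition = base + shift + float(rng.normal(0.0, noise_sd))
        rows.append(np.concatenate([background, [condition]]))
    samples = [f"s{k}" for k in range(1, n_bg + 1)] + ["condition"]
    return ExpressionDataset(genes=genes, samples=samples, values=np.array(rows))


# -- synthetic time courses --------------------------------------------------


def simulate_timecourses(
    shadow_prices: Dict[str, float],
    mode: str = "signal",
    n_points: int = 8,
    seed: int = 0,
    window_minutes: float = 30.0,
    cv_limiting: Tuple[float, float] = (0.02, 0.15),
    cv_free: Tuple[float, float] = (0.4, 1.0),
) -> List[TimeCourse]:
    """Synthetic post-perturbation trajectories keyed to shadow prices.

    In ``signal`` mode metabolites with negative shadow price get
    low-variability trajectories (target CV drawn from ``cv_limiting``)
    while zero-shadow-price metabolites get a wide CV spread
    (``cv_free``) — the regime in which tightly controlled growth-limiting
    pools respond little to a perturbation.  In ``null`` mode the target
    CV is drawn independently of the shadow price (for calibration of the
    permutation test).  Trajectories are positive lognormal-shaped series
    whose log-scale spread is chosen to land near the target CV.
    """
    if mode not in ("signal", "null"):
        raise ValueError(f"mode must be 'signal' or 'null', got {mode!r}")
    if n_points < 3:
        raise ValueError(f"need n_points >= 3, got {n_points}")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, window_minutes, n_points)
    out = []
    null_range = (cv_limiting[0], cv_free[1])
    for met_id, lam in shadow_prices.items():
        if mode == "null":
            target_cv = float(rng.uniform(*null_range))
        elif lam < 0:
            target_cv = float(rng.uniform(*cv_limiting))
        else:
            target_cv = float(rng.uniform(*cv_free))
        if target_cv == 0:
            values = np.full(n_points, 100.0)
        else:
            z = rng.normal(size=n_points)
            z = (z - z.mean()) / max(z.std(ddof=1), 1e-12)
            sigma = float(np.sqrt(np.log1p(target_cv**2)))
            values = 100.0 * np.exp(sigma * z - sigma**2 / 2.0)
        out.append(TimeCourse(met_id, times, values))
    return out
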