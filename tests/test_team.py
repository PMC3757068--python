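"""Expression-integration LP: thresholds, penalties, RMF, shadow-price signs."""

import itertools

import numpy as np
import pytest

from fluximba.exceptions import RmfUnreachableError, ValidationError
from fluximba.fixtures import make_fixture, simulate_expression, team_toy
from fluximba.gpr import parse_gpr
from fluximba.model import Metabolite, MetabolicModel, Reaction
from fluximba.team import (
    ExpressionDataset,
    gene_penalties,
    gene_thresholds,
    penalty_model,
    predict_direction,
    reaction_penalties,
    rmf_bound,
    solve_team,
    theta_scan,
)

# -- thresholds -------------------------------------------------------------


def test_threshold_is_own_quantile():
    expr = ExpressionDataset(
        genes=["g"], samples=[f"s{i}" for i in range(100)],
        values=np.arange(1.0, 101.0)[None, :],
    )
    # linear-interpolated empirical median of 1..100
    assert gene_thresholds(expr, 0.5)["g"] == pytest.approx(50.5)


def test_threshold_constant_gene():
    expr = ExpressionDataset(["g"], ["a", "b", "c"], np.full((1, 3), 7.0))
    for theta in (0.1, 0.5, 0.88):
        assert gene_thresholds(expr, theta)["g"] == pytest.approx(7.0)


def test_threshold_single_measurement_warns():
    expr = ExpressionDataset(["g"], ["only"], np.array([[3.0]]))
    with pytest.warns(UserWarning, match="single measurement"):
        assert gene_thresholds(expr, 0.88)["g"] == pytest.approx(3.0)


def test_thresholds_monotone_in_theta():
    rng = np.random.default_rng(7)
    expr = ExpressionDataset(
        genes=[f"g{i}" for i in range(5)],
        samples=[f"s{j}" for j in range(30)],
        values=rng.lognormal(2.0, 0.8, size=(5, 30)),
    )
    grid = [0.1, 0.3, 0.5, 0.7, 0.88, 0.95]
    tables = [gene_thresholds(expr, t) for t in grid]
    for lo, hi in zip(tables, tables[1:]):
        for g in expr.genes:
            assert hi[g] >= lo[g] - 1e-12


@pytest.mark.parametrize("theta", [0.0, 1.0, -0.2, 1.3])
def test_invalid_theta_rejected(theta):
    expr = ExpressionDataset(["g"], ["a", "b"], np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError):
        gene_thresholds(expr, theta)


# -- gene penalties ---------------------------------------------------------


@pytest.mark.parametrize(
    "x, exp, expected",
    [(10.0, 12.0, 0.0), (10.0, 7.0, 3.0), (10.0, 10.0, 0.0), (0.0, -1.0, 1.0)],
)
def test_gene_penalty_formula(x, exp, expected):
    """p_g = max(0, x_g - EXP_g): only below-threshold expression is penalized."""
    assert gene_penalties({"g": exp}, {"g": x})["g"] == pytest.approx(expected)


def test_gene_penalty_missing_threshold_raises():
    with pytest.raises(ValidationError):
        gene_penalties({"g": 1.0}, {})


# -- reaction penalties via GPR ---------------------------------------------


def _one_reaction_model(gpr):
    return MetabolicModel(
        [Metabolite("M", compartment="c")],
        [Reaction("R", {"M": 1.0}, 0.0, 10.0, gpr=gpr)],
    )


def _brute_force_penalty(gpr_text, penalties):
    """Independent oracle: minimum over satisfying gene-activity patterns of
    the maximum penalty among active genes.

    A reaction needs some satisfying assignment of its GPR; using a gene
    with penalty p costs p, a complex costs its worst member, and the cell
    picks the cheapest way to satisfy the rule.
    """
    tree = parse_gpr(gpr_text)
    genes = sorted(tree.genes)
    best = None
    for pattern in itertools.product([False, True], repeat=len(genes)):
        active = {g for g, on in zip(genes, pattern) if on}
        if tree.evaluate(set(genes) - active):
            cost = max((penalties.get(g, 0.0) for g in active), default=0.0)
            best = cost if best is None else min(best, cost)
    return best


@pytest.mark.parametrize(
    "gpr, penalties, expected",
    [
        ("g1 or g2", {"g1": 5.0, "g2": 0.0}, 0.0),
        ("g1 and g2", {"g1": 5.0, "g2": 0.0}, 5.0),
        ("", {"g1": 5.0}, 0.0),
        ("g1 and g2", {}, 0.0),  # no expression evidence, no penalty
    ],
)
def test_reaction_penalty_examples(gpr, penalties, expected):
    model = _one_reaction_model(gpr)
    assert reaction_penalties(model, penalties)[0] == pytest.approx(expected)


@pytest.mark.parametrize("op", ["and", "or"])
@pytest.mark.parametrize(
    "p1, p2", list(itertools.product([0.0, 1.0, 2.5], repeat=2))
)
def test_two_gene_rules_match_truth_table_oracle(op, p1, p2):
    """OR -> min / AND -> max agrees with brute-force enumeration of
    satisfying gene patterns on every 2-gene rule."""
    gpr = f"g1 {op} g2"
    penalties = {"g1": p1, "g2": p2}
    got = reaction_penalties(_one_reaction_model(gpr), penalties)[0]
    assert got == pytest.approx(_brute_force_penalty(gpr, penalties))


def test_nested_rule_matches_truth_table_oracle():
    gpr = "(g1 and g2) or (g3 and g4)"
    penalties = {"g1": 4.0, "g2": 1.0, "g3": 2.0, "g4": 3.0}
    got = reaction_penalties(_one_reaction_model(gpr), penalties)[0]
    assert got == pytest.approx(_brute_force_penalty(gpr, penalties)) == 3.0


# -- RMF bound --------------------------------------------------------------


def test_rmf_bound_is_fraction_of_fba_maximum():
    model, truth = make_fixture("two_pathway_team")
    assert rmf_bound(model, "RMF", 0.3) == pytest.approx(0.3 * truth["rmf_max"])
    assert rmf_bound(model, "RMF", 1.0) == pytest.approx(truth["rmf_max"])


def test_rmf_unreachable_raises():
    model, _ = make_fixture("two_pathway_team")
    for rxn in model.reactions:
        if rxn.id != "RMF":
            rxn.upper_bound = 0.0  # no production; secretion maximum is 0
    with pytest.raises(RmfUnreachableError):
        rmf_bound(model, "RMF", 0.3)


@pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
def test_rmf_fraction_validated(fraction):
    model, _ = make_fixture("two_pathway_team")
    with pytest.raises(ValueError):
        rmf_bound(model, "RMF", fraction)


# -- TEAM solve and shadow-price signs --------------------------------------


def test_producer_penalized_toy():
    """M made only by a penalized reaction (c=2), drained by the RMF:
    IS = 2, lambda_M = +2, abundance predicted to decrease."""
    model, c, rmf, rmf_min, truth = team_toy("producer")
    sol = solve_team(model, c, rmf, rmf_min)
    assert sol.inconsistency_score == pytest.approx(truth["IS"])
    assert sol.shadow_prices[0] == pytest.approx(truth["lambda"]["M[c]"])
    assert sol.directions == truth["direction"]
    # IS equals sum_j c_j |v_j| at the optimum
    assert sol.inconsistency_score == pytest.approx(float(c @ np.abs(sol.fluxes)))
    assert sol.fluxes[model.reaction_index(rmf)] >= rmf_min - 1e-9


def test_consumer_penalized_toy_mirrored_sign():
    model, c, rmf, rmf_min, truth = team_toy("consumer")
    sol = solve_team(model, c, rmf, rmf_min)
    assert sol.shadow_prices[0] == pytest.approx(truth["lambda"]["M[c]"])
    assert sol.directions == truth["direction"]


def test_team_shadow_price_matches_brute_force_resolve():
    """d(IS)/db_i via perturbed re-solves agrees with the LP dual value."""
    model, c, rmf, rmf_min, _ = team_toy("producer")
    sol = solve_team(model, c, rmf, rmf_min)
    for delta in (0.1, -0.1):
        perturbed = solve_team(model, c, rmf, rmf_min, b=np.array([delta]))
        slope = (perturbed.inconsistency_score - sol.inconsistency_score) / delta
        assert slope == pytest.approx(sol.shadow_prices[0], abs=1e-6)


def test_zero_penalties_give_zero_is():
    model, truth = make_fixture("two_pathway_team")
    rmf_min = rmf_bound(model, "RMF", 0.3)
    sol = solve_team(model, np.zeros(model.n_reactions), "RMF", rmf_min)
    assert sol.inconsistency_score == pytest.approx(0.0)


def test_flux_routes_through_unpenalized_pathway():
    """Two parallel producers; penalizing one sends all flux to the free
    one and the inconsistency vanishes."""
    model, truth = make_fixture("two_pathway_team")
    c = reaction_penalties(model, {"g_lo": 1.0, "g_hi": 0.0})
    rmf_min = rmf_bound(model, "RMF", 0.3)
    sol = solve_team(model, c, "RMF", rmf_min)
    assert sol.inconsistency_score == pytest.approx(truth["IS"])
    assert sol.fluxes[model.reaction_index("R_LO")] == pytest.approx(0.0, abs=1e-9)
    assert sol.fluxes[model.reaction_index("R_HI")] >= rmf_min - 1e-9


def test_reversible_reaction_penalized_by_magnitude():
    """A reversible penalized reaction cannot lower IS by running backward."""
    model = MetabolicModel(
        [Metabolite("M", compartment="c")],
        [
            Reaction("R_REV", {"M": 1.0}, -10.0, 10.0, gpr="g"),
            Reaction("RMF", {"M": -1.0}, 0.0, 10.0),
        ],
    )
    c = np.array([2.0, 0.0])
    sol = solve_team(model, c, "RMF", 1.0)
    assert sol.inconsistency_score == pytest.approx(2.0)
    assert sol.fluxes[0] == pytest.approx(1.0)


def test_infeasible_rmf_min_raises():
    model, c, rmf, _, _ = team_toy("producer")
    from fluximba.exceptions import InfeasibleProblemError

    with pytest.raises(InfeasibleProblemError):
        solve_team(model, c, rmf, rmf_min=50.0)


def test_raising_theta_never_lowers_is():
    """Quantile monotonicity: a higher percentile threshold can only raise
    gene penalties, hence the optimal inconsistency score."""
    model, _ = make_fixture("two_pathway_team")
    expr = simulate_expression(model, active_reactions=["R_HI"], seed=3)
    rmf_min = rmf_bound(model, "RMF", 0.3)
    last = -np.inf
    for theta in (0.2, 0.5, 0.7, 0.88, 0.95):
        pm = penalty_model(model, expr, "condition", theta)
        sol = solve_team(model, pm.reaction_penalties, "RMF", rmf_min)
        assert sol.inconsistency_score >= last - 1e-9
        last = sol.inconsistency_score


def test_theta_scan_single_point_and_bimodal_constancy():
    model, _ = make_fixture("two_pathway_team")
    expr = simulate_expression(model, active_reactions=["R_HI"], seed=5)
    scores = theta_scan(
        model, expr, "condition", "RMF",
        theta_grid=[0.88],
        score=lambda theta, sol: sol.inconsistency_score,
    )
    pm = penalty_model(model, expr, "condition", 0.88)
    rmf_min = rmf_bound(model, "RMF", 0.3)
    single = solve_team(model, pm.reaction_penalties, "RMF", rmf_min)
    assert scores["score"][0] == pytest.approx(single.inconsistency_score)

    # bimodal expression: condition values sit far outside the background
    # band, so which side of the threshold each gene falls on is theta-free
    bimodal = ExpressionDataset(
        genes=["g_hi", "g_lo"],
        samples=["s1", "s2", "s3", "condition"],
        values=np.array([[10.0, 10.1, 9.9, 100.0], [10.0, 10.1, 9.9, 0.0]]),
    )
    table = theta_scan(
        model, bimodal, "condition", "RMF",
        theta_grid=[0.3, 0.5, 0.7],
        score=lambda theta, sol: sol.directions["M[c]"] == "none",
    )
    assert table["score"].nunique() == 1
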