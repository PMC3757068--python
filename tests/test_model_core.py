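"""Model data structures, I/O dialects, GPR rules, medium and knockouts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluximba.exceptions import FormatError, GprParseError, ValidationError
from fluximba.gpr import parse_gpr
from fluximba.io import read_medium, read_model, write_medium, write_model
from fluximba.model import (
    Medium,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_medium,
    knockout_genes,
)
from fluximba.duality import solve_fba
from fluximba.fixtures import make_fixture


# -- GPR grammar ------------------------------------------------------------


@pytest.mark.parametrize(
    "rule, genes",
    [
        ("g1", {"g1"}),
        ("(g1 and g2) or g3", {"g1", "g2", "g3"}),
        ("g1 AND g2 Or g3", {"g1", "g2", "g3"}),  # keywords case-insensitive
        ("", set()),
        ("  ", set()),
    ],
)
def test_gpr_gene_extraction(rule, genes):
    tree = parse_gpr(rule)
    assert (set(tree.genes) if tree else set()) == genes


@pytest.mark.parametrize(
    "rule, knocked, alive",
    [
        ("g1 and g2", {"g1"}, False),
        ("g1 or g2", {"g1"}, True),
        ("g1 or g2", {"g1", "g2"}, False),
        # AND binds tighter than OR: g1 or (g2 and g3)
        ("g1 or g2 and g3", {"g2"}, True),
        ("g1 or g2 and g3", {"g1", "g3"}, False),
        ("(g1 or g2) and g3", {"g3"}, False),
    ],
)
def test_gpr_boolean_evaluation(rule, knocked, alive):
    assert parse_gpr(rule).evaluate(knocked) is alive


@pytest.mark.parametrize("bad", ["g1 and", "and g1", "(g1 or g2", "g1 g2", "()"])
def test_malformed_gpr_raises(bad):
    with pytest.raises(GprParseError):
        parse_gpr(bad)


def test_gpr_roundtrip_through_string():
    tree = parse_gpr("(g1 and g2) or g3")
    again = parse_gpr(tree.to_string())
    assert again.genes == tree.genes
    assert again.evaluate({"g1"}) == tree.evaluate({"g1"})
    assert again.evaluate({"g3", "g2"}) == tree.evaluate({"g3", "g2"})


# -- structural validation --------------------------------------------------


def test_reaction_invariants():
    with pytest.raises(ValidationError):
        Reaction("R", {})
    with pytest.raises(ValidationError):
        Reaction("R", {"M": 1.0}, lower_bound=5.0, upper_bound=1.0)
    assert Reaction("EX", {"M": -1.0}).is_exchange
    assert not Reaction("R", {"A": -1.0, "B": 1.0}).is_exchange


def test_duplicate_ids_rejected():
    mets = [Metabolite("M", compartment="c"), Metabolite("M", compartment="c")]
    with pytest.raises(ValidationError):
        MetabolicModel(mets, [Reaction("R", {"M": 1.0})])


def test_model_gene_set_from_gprs():
    model = MetabolicModel(
        [Metabolite("M", compartment="c")],
        [Reaction("R", {"M": 1.0}, gpr="(g1 and g2) or g3")],
    )
    assert model.genes == {"g1", "g2", "g3"}


# -- I/O dialects -----------------------------------------------------------


def test_tsv_minimal_dimensions(tmp_path):
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "id\tequation\tlower_bound\tupper_bound\tgpr\tobjective\n"
        "R1\t -> M[c]\t0\t10\t\t\n"
        "R2\tM[c] -> \t0\t1000\t\t1\n"
    )
    model = read_model(path)
    assert model.stoichiometric_matrix().shape == (1, 2)
    assert model.objective == {"R2": 1.0}


def test_json_gene_set(tmp_path):
    path = tmp_path / "m.json"
    path.write_text(
        """{"metabolites": [{"id": "M[c]", "compartment": "c"}],
            "reactions": [{"id": "R", "metabolites": {"M[c]": 1.0},
                           "lower_bound": 0, "upper_bound": 10,
                           "gene_reaction_rule": "(g1 and g2) or g3"}],
            "objective": {}}"""
    )
    model = read_model(path)
    assert model.genes == {"g1", "g2", "g3"}


@pytest.mark.parametrize("fmt,ext", [("json", "json"), ("tsv", "tsv"), ("sbml", "xml")])
@pytest.mark.parametrize("kind", ["figure1", "nitrogen_assimilation"])
def test_roundtrip_preserves_model(tmp_path, fmt, ext, kind):
    model, _ = make_fixture(kind)
    path = tmp_path / f"model.{ext}"
    write_model(model, path, format=fmt)
    back = read_model(path, format=fmt)
    assert back.metabolite_ids == model.metabolite_ids
    assert back.reaction_ids == model.reaction_ids
    assert np.allclose(
        back.stoichiometric_matrix().toarray(),
        model.stoichiometric_matrix().toarray(),
    )
    for r1, r2 in zip(model.reactions, back.reactions):
        assert r1.lower_bound == pytest.approx(r2.lower_bound)
        assert r1.upper_bound == pytest.approx(r2.upper_bound)
        t1, t2 = parse_gpr(r1.gpr), parse_gpr(r2.gpr)
        assert (t1 is None) == (t2 is None)
        if t1 is not None:
            assert t1.genes == t2.genes
    assert {k: float(v) for k, v in back.objective.items()} == pytest.approx(
        model.objective
    )


def test_unparseable_file_names_the_problem(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(FormatError, match="line"):
        read_model(bad)
    bad_tsv = tmp_path / "bad.tsv"
    bad_tsv.write_text(
        "id\tequation\tlower_bound\tupper_bound\nR1\tno arrow here\t0\t1\n"
    )
    with pytest.raises(FormatError, match="arrow"):
        read_model(bad_tsv)


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_model(tmp_path / "absent.json")


# -- medium -----------------------------------------------------------------


def _exchange_model():
    return MetabolicModel(
        [Metabolite("G[e]", compartment="e"), Metabolite("G[c]", compartment="c")],
        [
            Reaction("EX_glc", {"G[e]": -1.0}, -5.0, 1000.0),
            Reaction("T", {"G[e]": -1.0, "G[c]": 1.0}, 0.0, 100.0),
            Reaction("SINK", {"G[c]": -1.0}, 0.0, 100.0),
        ],
        {"SINK": 1.0},
    )


def test_empty_medium_closes_uptake():
    model = _exchange_model()
    out = apply_medium(model, Medium({}))
    ex = out.get_reaction("EX_glc")
    assert ex.lower_bound == 0.0
    assert ex.upper_bound == 1000.0  # secretion unchanged


def test_medium_bounds_set_verbatim():
    out = apply_medium(_exchange_model(), Medium({"EX_glc": (-10.0, 1000.0)}))
    ex = out.get_reaction("EX_glc")
    assert (ex.lower_bound, ex.upper_bound) == (-10.0, 1000.0)


def test_medium_never_touches_intracellular_bounds():
    model = _exchange_model()
    out = apply_medium(model, Medium({"EX_glc": (-1.0, 1.0)}))
    for rid in ("T", "SINK"):
        assert out.get_reaction(rid).lower_bound == model.get_reaction(rid).lower_bound
        assert out.get_reaction(rid).upper_bound == model.get_reaction(rid).upper_bound


def test_medium_rejects_non_exchange_and_unknown():
    with pytest.raises(ValidationError):
        apply_medium(_exchange_model(), Medium({"T": (-1.0, 1.0)}))
    with pytest.raises(ValidationError, match="EX_nope"):
        apply_medium(_exchange_model(), Medium({"EX_nope": (-1.0, 1.0)}))


def test_medium_tsv_roundtrip(tmp_path):
    medium = Medium({"EX_glc": (-10.0, 1000.0), "EX_o2": (-math.inf, math.inf)})
    path = tmp_path / "medium.tsv"
    write_medium(medium, path)
    back = read_medium(path)
    assert back.entries == medium.entries


# -- knockouts --------------------------------------------------------------


def test_knockout_boolean_rules():
    model = MetabolicModel(
        [Metabolite("M", compartment="c")],
        [
            Reaction("R_and", {"M": 1.0}, 0.0, 10.0, gpr="g1 and g2"),
            Reaction("R_or", {"M": -1.0}, 0.0, 10.0, gpr="g1 or g2"),
            Reaction("R_none", {"M": -1.0}, 0.0, 10.0),
        ],
    )
    out = knockout_genes(model, {"g1"})
    assert (out.get_reaction("R_and").lower_bound, out.get_reaction("R_and").upper_bound) == (0.0, 0.0)
    assert out.get_reaction("R_or").upper_bound == 10.0  # isozyme survives
    assert out.get_reaction("R_none").upper_bound == 10.0  # empty GPR untouched


def test_knockout_unknown_gene_raises():
    model, _ = make_fixture("nitrogen_assimilation")
    with pytest.raises(ValidationError, match="nonsense"):
        knockout_genes(model, {"nonsense"})


def test_double_nitrogen_knockout_is_lethal(nitrogen):
    model, truth = nitrogen
    ko_one = knockout_genes(model, {"gdhA"})
    primal, _ = solve_fba(ko_one)
    assert primal.is_optimal
    assert primal.objective_value == pytest.approx(truth["Z_single_knockout"])
    ko_both = knockout_genes(model, {"gdhA", "gltB"})
    primal, dual = solve_fba(ko_both)
    assert primal.status == "infeasible"
    assert primal.lethal
    assert dual is None


@settings(deadline=None, max_examples=25)
@given(
    sub=st.sets(st.sampled_from(["gdhA", "gltB", "gltD"]), max_size=2),
    extra=st.sets(st.sampled_from(["gdhA", "gltB", "gltD"]), max_size=3),
)
def test_knockout_idempotent_and_monotone(sub, extra):
    """Re-applying a knockout changes nothing; knocking out more genes
    disables a superset of reactions."""
    model, _ = make_fixture("nitrogen_assimilation")

    def disabled(m):
        return {r.id for r in m.reactions if r.lower_bound == r.upper_bound == 0.0}

    ko = knockout_genes(model, sub)
    assert disabled(knockout_genes(ko, sub)) == disabled(ko)
    bigger = knockout_genes(model, sub | extra)
    assert disabled(ko) <= disabled(bigger)
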