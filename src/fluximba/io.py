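"""Readers and writers for metabolic models and tabular inputs.

Three model dialects are supported:

* **SBML** Level 3 with the FBC package (via cobrapy),
* a **JSON** dialect::

    {"metabolites": [{"id", "name", "compartment"}],
     "reactions": [{"id", "metabolites": {id: coef}, "lower_bound",
                    "upper_bound", "gene_reaction_rule"}],
     "objective": {reaction_id: weight}}

* a **TSV** dialect: one reactions table with columns
  ``id, equation, lower_bound, upper_bound, gpr`` where the equation is a
  string such as ``"2 A[c] + B[e] -> C[c]"`` and the bracket suffix is the
  compartment.

Media are TSV tables with columns ``reaction_id, lower_bound, upper_bound``.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Optional

import pandas as pd

from .exceptions import FormatError
from .model import Medium, Metabolite, MetabolicModel, Reaction

_ARROW_RE = re.compile(r"<->|<=>|-->|->|=>")
_MET_TOKEN_RE = re.compile(r"^(?P<name>.+?)(\[(?P<comp>[^\[\]]+)\])?$")

_FORMATS = ("sbml", "json", "tsv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise FormatError(f"cannot infer model format from {path.name!r}")


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a metabolic model from SBML, JSON or TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown model format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "json":
        return _read_json(path)
    return _read_tsv(path)


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "json":
        _write_json(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    else:
        raise FormatError(f"unknown model format {fmt!r}")


# -- JSON dialect -----------------------------------------------------------


def _read_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON at line {exc.lineno}") from exc
    try:
        metabolites = [
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
            )
            for entry in payload["metabolites"]
        ]
        reactions = [
            Reaction(
                id=entry["id"],
                stoichiometry={k: float(v) for k, v in entry["metabolites"].items()},
                lower_bound=float(entry.get("lower_bound", 0.0)),
                upper_bound=float(entry.get("upper_bound", 1000.0)),
                gpr=entry.get("gene_reaction_rule", ""),
            )
            for entry in payload["reactions"]
        ]
    except KeyError as exc:
        raise FormatError(f"{path.name}: missing required key {exc}") from exc
    objective = {k: float(v) for k, v in payload.get("objective", {}).items()}
    return MetabolicModel(metabolites, reactions, objective, name=path.stem)


def _write_json(model: MetabolicModel, path: Path) -> None:
    payload = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
            }
            for r in model.reactions
        ],
        "objective": model.objective,
    }
    path.write_text(json.dumps(payload, indent=1))


# -- TSV dialect ------------------------------------------------------------


def _parse_met_token(token: str):
    match = _MET_TOKEN_RE.match(token)
    name = match.group("name")
    comp = match.group("comp") or ""
    return token, name, comp


def _parse_side(side: str, sign: float, stoich, mets):
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        parts = term.split()
        if len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise FormatError(f"bad stoichiometric coefficient in {term!r}") from exc
            token = parts[1]
        elif len(parts) == 1:
            coef, token = 1.0, parts[0]
        else:
            raise FormatError(f"cannot parse equation term {term!r}")
        met_id, name, comp = _parse_met_token(token)
        stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef
        mets.setdefault(met_id, (name, comp))


def parse_equation(equation: str):
    """Parse ``"2 A[c] + B[e] -> C[c]"`` into (stoichiometry, metabolite info)."""
    match = _ARROW_RE.search(equation)
    if match is None:
        raise FormatError(f"equation {equation!r} has no reaction arrow")
    left = equation[: match.start()]
    right = equation[match.end() :]
    stoich: dict = {}
    mets: dict = {}
    _parse_side(left, -1.0, stoich, mets)
    _parse_side(right, +1.0, stoich, mets)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise FormatError(f"equation {equation!r} has empty net stoichiometry")
    return stoich, mets


def format_equation(reaction: Reaction) -> str:
    def fmt(items):
        parts = []
        for met_id, coef in items:
            coef = abs(coef)
            parts.append(met_id if coef == 1 else f"{coef:g} {met_id}")
        return " + ".join(parts)

    left = [(k, v) for k, v in reaction.stoichiometry.items() if v < 0]
    right = [(k, v) for k, v in reaction.stoichiometry.items() if v > 0]
    return f"{fmt(left)} -> {fmt(right)}".strip()


def _read_tsv(path: Path) -> MetabolicModel:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path.name}: cannot read TSV: {exc}") from exc
    required = {"id", "equation", "lower_bound", "upper_bound"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    metabolites: dict = {}
    reactions = []
    objective = {}
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        try:
            stoich, mets = parse_equation(row.equation)
        except FormatError as exc:
            raise FormatError(f"{path.name} line {line_no}: {exc}") from exc
        for met_id, (name, comp) in mets.items():
            metabolites.setdefault(met_id, Metabolite(met_id, name, comp))
        reactions.append(
            Reaction(
                id=row.id,
                stoichiometry=stoich,
                lower_bound=float(row.lower_bound),
                upper_bound=float(row.upper_bound),
                gpr=getattr(row, "gpr", ""),
            )
        )
        weight = getattr(row, "objective", "")
        if weight not in ("", "0", "0.0"):
            objective[row.id] = float(weight)
    return MetabolicModel(
        list(metabolites.values()), reactions, objective, name=path.stem
    )


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    rows = []
    for rxn in model.reactions:
        rows.append(
            {
                "id": rxn.id,
                "equation": format_equation(rxn),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "gpr": rxn.gpr,
                "objective": model.objective.get(rxn.id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- SBML via cobrapy -------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.name or "model")
    mets = {}
    for met in model.metabolites:
        cmet = cobra.Metabolite(
            met.id, name=met.name, compartment=met.compartment or "c"
        )
        mets[met.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions:
        crxn = cobra.Reaction(
            rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound
        )
        rxns.append(crxn)
    cm.add_reactions(rxns)
    for rxn, crxn in zip(model.reactions, rxns):
        crxn.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
        if rxn.gpr:
            crxn.gene_reaction_rule = rxn.gpr
    cm.objective = {
        cm.reactions.get_by_id(rid): w for rid, w in model.objective.items()
    }
    return cm


def _from_cobra(cm, name: str = "") -> MetabolicModel:
    metabolites = [
        Metabolite(m.id, name=m.name or "", compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gene_reaction_rule or "",
        )
        for r in cm.reactions
    ]
    objective = {}
    for rxn in cm.reactions:
        coef = rxn.objective_coefficient
        if coef:
            objective[rxn.id] = float(coef)
    return MetabolicModel(metabolites, reactions, objective, name=name or cm.id or "")


def _read_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise FormatError(f"{path.name}: SBML parse failure: {exc}") from exc
    return _from_cobra(cm, name=path.stem)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


# -- tabular inputs ---------------------------------------------------------


def read_medium(path) -> Medium:
    """Medium TSV with columns reaction_id, lower_bound, upper_bound."""
    table = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "lower_bound", "upper_bound"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"medium file missing columns {sorted(missing)}")
    entries = {}
    for row in table.itertuples(index=False):
        lb = -math.inf if pd.isna(row.lower_bound) else float(row.lower_bound)
        ub = math.inf if pd.isna(row.upper_bound) else float(row.upper_bound)
        entries[str(row.reaction_id)] = (lb, ub)
    return Medium(entries)


def write_medium(medium: Medium, path) -> None:
    rows = [
        {"reaction_id": rid, "lower_bound": lb, "upper_bound": ub}
        for rid, (lb, ub) in medium.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
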