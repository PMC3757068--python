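"""Core data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is the stoichiometric matrix ``S`` (metabolites x
reactions), per-reaction flux bounds, a right-hand-side vector ``b`` of
accumulation/depletion rates (zero at steady state), a linear objective and
Boolean gene-protein-reaction rules.  The COBRA sign convention is used for
exchange reactions: negative flux is uptake, positive flux is secretion.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy import sparse

from .exceptions import ValidationError
from .gpr import GprNode, parse_gpr


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction touches exactly one metabolite (source/sink)."""
        return len(self.stoichiometry) == 1

    @property
    def gpr_tree(self) -> Optional[GprNode]:
        return parse_gpr(self.gpr)

    @property
    def genes(self) -> Set[str]:
        tree = self.gpr_tree
        return set(tree.genes) if tree is not None else set()


@dataclass
class Medium:
    """Exchange-bound overrides: reaction id -> (lower_bound, upper_bound)."""

    entries: Dict[str, Tuple[float, float]] = field(default_factory=dict)


class MetabolicModel:
    """Stoichiometric model with bounds, objective, RHS and GPR rules."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective: Optional[Dict[str, float]] = None,
        b: Optional[np.ndarray] = None,
        name: str = "",
    ):
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective: Dict[str, float] = dict(objective or {})
        self.name = name
        self.b = (
            np.zeros(len(self.metabolites))
            if b is None
            else np.asarray(b, dtype=float).copy()
        )
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(missing)}"
                )
        if self.b.shape != (len(self.metabolites),):
            raise ValidationError(
                f"b has shape {self.b.shape}, expected ({len(self.metabolites)},)"
            )
        unknown_obj = set(self.objective) - set(rxn_ids)
        if unknown_obj:
            raise ValidationError(
                f"objective references unknown reactions {sorted(unknown_obj)}"
            )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def get_reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index(reaction_id)]

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    # -- matrices ----------------------------------------------------------

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """Sparse S (m x n) with metabolites as rows, reactions as columns."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(met_pos[met_id])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    @property
    def S(self) -> sparse.csr_matrix:
        return self.stoichiometric_matrix()

    def bounds(self) -> List[Tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.n_reactions)
        for rxn_id, weight in self.objective.items():
            c[self.reaction_index(rxn_id)] = weight
        return c

    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:
        return (
            f"MetabolicModel({self.name or 'unnamed'}: "
            f"{self.n_metabolites} metabolites, {self.n_reactions} reactions)"
        )


# -- operations -------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Replace exchange bounds from a medium definition.

    Exchange reactions absent from the medium get lower bound 0 (no uptake);
    their upper bounds and all intracellular reactions are untouched.
    """
    unknown = [rid for rid in medium.entries if rid not in set(model.reaction_ids)]
    if unknown:
        raise ValidationError(f"medium references unknown reactions {sorted(unknown)}")
    non_exchange = [
        rid for rid in medium.entries if not model.get_reaction(rid).is_exchange
    ]
    if non_exchange:
        raise ValidationError(
            f"medium references non-exchange reactions {sorted(non_exchange)}"
        )
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.entries:
            lb, ub = medium.entries[rxn.id]
            if lb > ub:
                raise ValidationError(
                    f"medium entry {rxn.id!r}: lower bound {lb} exceeds upper bound {ub}"
                )
            rxn.lower_bound = float(lb)
            rxn.upper_bound = float(ub)
        else:
            rxn.lower_bound = max(0.0, rxn.lower_bound)
    return out


def knockout_genes(model: MetabolicModel, gene_ids: Iterable[str]) -> MetabolicModel:
    """Disable reactions whose GPR evaluates false under a gene deletion.

    Disabled reactions get both bounds set to 0 (columns are kept so that
    metabolite/reaction indices stay aligned across strains for differential
    shadow-price comparisons).  Reactions with an empty GPR are untouched.
    """
    gene_ids = set(gene_ids)
    unknown = gene_ids - model.genes
    if unknown:
        raise ValidationError(f"unknown genes {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions:
        tree = rxn.gpr_tree
        if tree is None:
            continue
        if not tree.evaluate(gene_ids):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
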