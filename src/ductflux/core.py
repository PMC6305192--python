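"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is the substrate of every linear-programming
operation in this package: a set of compartmentalized metabolites, a set of
bounded stoichiometric reactions, and a designated biomass pseudo-reaction
whose flux is the modeling objective.  Flux units are mmol·gDW⁻¹·h⁻¹
throughout.

Compartmentalization follows the simplest convention consistent with plant
genome-scale models: the compartment is a property of the metabolite, and a
transport step is an ordinary reaction touching metabolites in two
compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Set

import numpy as np

__all__ = [
    "Compartment",
    "DbSource",
    "SolverStatus",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "Violation",
    "validate_model",
    "stoichiometric_matrix",
    "InvalidModelError",
]


class Compartment(str, Enum):
    """Subcellular compartments of a plant cell model.

    The four intracellular compartments cover the localization calls made
    for plant enzymes; ``extracellular`` exists so that exchange reactions
    have a metabolite to touch.
    """

    CYTOSOL = "cytosol"
    PLASTID = "plastid"
    MITOCHONDRION = "mitochondrion"
    PEROXISOME = "peroxisome"
    EXTRACELLULAR = "extracellular"


class DbSource(str, Enum):
    """Provenance of a reaction: which reference database contributed it."""

    ARABIDOPSIS_CORE = "arabidopsis_core"
    ARACYC = "aracyc"
    METACYC = "metacyc"
    CUSTOM = "custom"


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


# Default bounds: the literature convention of +/-1000 as "effectively
# unbounded" in mmol/gDW/h.
DEFAULT_UB = 1000.0
DEFAULT_LB_REVERSIBLE = -1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.CYTOSOL
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.compartment, Compartment):
            object.__setattr__(self, "compartment", Compartment(self.compartment))


@dataclass
class Reaction:
    """A bounded stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    means consumed.  ``is_exchange`` marks system-boundary reactions, which
    by convention touch exactly one metabolite (negative flux = uptake,
    positive flux = export).
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    subsystem: str = ""
    ec_numbers: List[str] = field(default_factory=list)
    gene_ids: Set[str] = field(default_factory=set)
    is_exchange: bool = False
    db_source: DbSource = DbSource.CUSTOM

    def __post_init__(self) -> None:
        if not isinstance(self.db_source, DbSource):
            self.db_source = DbSource(self.db_source)
        self.gene_ids = set(self.gene_ids)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            ec_numbers=list(self.ec_numbers),
            gene_ids=set(self.gene_ids),
            is_exchange=self.is_exchange,
            db_source=self.db_source,
        )


@dataclass
class MetabolicModel:
    id: str
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str = ""
    annotations: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_lists(
        cls,
        model_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str = "",
        annotations: Optional[Dict[str, str]] = None,
    ) -> "MetabolicModel":
        mets = {}
        for m in metabolites:
            if m.id in mets:
                raise ValueError(f"duplicate metabolite id {m.id!r}")
            mets[m.id] = m
        rxns = {}
        for r in reactions:
            if r.id in rxns:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            rxns[r.id] = r
        return cls(
            id=model_id,
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=biomass_reaction_id,
            annotations=dict(annotations or {}),
        )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            annotations=dict(self.annotations),
        )

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reactions[self.biomass_reaction_id]

    def exchange_ids(self) -> List[str]:
        return sorted(r.id for r in self.reactions.values() if r.is_exchange)

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions.values():
            out |= r.gene_ids
        return out

    def subsystem_reactions(self, subsystem: str) -> List[str]:
        return sorted(
            r.id for r in self.reactions.values() if r.subsystem == subsystem
        )


@dataclass
class FluxDistribution:
    """Result of an LP flux prediction over a model."""

    model_id: str
    fluxes: Dict[str, float]
    objective_value: float
    status: SolverStatus

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_model`."""

    entity: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}"


class InvalidModelError(ValueError):
    pass


def validate_model(model: MetabolicModel) -> List[Violation]:
    """Check every structural invariant of a model.

    Returns an empty list iff the model is well-formed.  Violations are
    data, not exceptions, so callers can report all defects at once.
    """
    out: List[Violation] = []
    for mid, met in model.metabolites.items():
        if met.id != mid:
            out.append(Violation(mid, "metabolite key does not match its id"))
        if not isinstance(met.compartment, Compartment):
            out.append(Violation(mid, f"unknown compartment {met.compartment!r}"))
    for rid, rxn in model.reactions.items():
        if rxn.id != rid:
            out.append(Violation(rid, "reaction key does not match its id"))
        if rxn.lower_bound > rxn.upper_bound:
            out.append(
                Violation(rid, f"lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}")
            )
        if not rxn.stoichiometry:
            out.append(Violation(rid, "empty stoichiometry"))
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff == 0.0:
                out.append(Violation(rid, f"zero coefficient for {met_id}"))
            if met_id not in model.metabolites:
                out.append(Violation(rid, f"references missing metabolite {met_id!r}"))
        if rxn.is_exchange and len(rxn.stoichiometry) != 1:
            out.append(
                Violation(
                    rid,
                    f"exchange reaction touches {len(rxn.stoichiometry)} metabolites (must be 1)",
                )
            )
    if model.biomass_reaction_id and model.biomass_reaction_id not in model.reactions:
        out.append(
            Violation(
                model.biomass_reaction_id,
                "biomass_reaction_id does not name an existing reaction",
            )
        )
    return out


def stoichiometric_matrix(model: MetabolicModel):
    """Build the stoichiometric matrix S of a model.

    Rows are metabolites, columns reactions, both sorted by id so the
    layout is deterministic.  Returns ``(S, metabolite_ids, reaction_ids)``
    with S a dense ``numpy`` array.
    """
    violations = validate_model(model)
    if violations:
        raise InvalidModelError(f"invalid model: {violations[0]}")
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[met_id], j] = coeff
    return S, met_ids, rxn_ids
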