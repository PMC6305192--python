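"""Readers and writers for the tabular model format and SBML Level 3.

The tabular format is two TSV files: ``metabolites.tsv`` (id, name,
compartment, formula, charge) and ``reactions.tsv`` (id, name, equation,
lower_bound, upper_bound, subsystem, ec, genes, is_exchange, db_source).
Equations use ``-->`` for irreversible and ``<=>`` for reversible
reactions, e.g. ``2 A_c + B_c --> C_p``.  Numbers are written with
``repr``-level precision so a write → read round trip is bit-exact.
"""

from __future__ import annotations

import os
from typing import Dict, List, Tuple

import pandas as pd

from .core import (
    Compartment,
    DbSource,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "format_equation",
    "parse_equation",
    "write_model_tabular",
    "read_model_tabular",
    "write_model_sbml",
    "read_model_sbml",
]

_IRREV_ARROW = "-->"
_REV_ARROW = "<=>"


def _fmt_coeff(c: float) -> str:
    # repr round-trips floats exactly; integers print without ".0" clutter
    if c == int(c):
        return str(int(c))
    return repr(c)


def format_equation(reaction: Reaction) -> str:
    """Render a reaction's stoichiometry as an equation string."""
    lhs: List[str] = []
    rhs: List[str] = []
    for met_id in sorted(reaction.stoichiometry):
        coeff = reaction.stoichiometry[met_id]
        mag = abs(coeff)
        term = met_id if mag == 1.0 else f"{_fmt_coeff(mag)} {met_id}"
        (lhs if coeff < 0 else rhs).append(term)
    arrow = _REV_ARROW if reaction.reversible else _IRREV_ARROW
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse an equation string; returns (stoichiometry, reversible)."""
    if _REV_ARROW in equation:
        arrow, reversible = _REV_ARROW, True
    elif _IRREV_ARROW in equation:
        arrow, reversible = _IRREV_ARROW, False
    else:
        raise ValueError(f"no arrow ('{_IRREV_ARROW}' or '{_REV_ARROW}') in {equation!r}")
    lhs_str, rhs_str = equation.split(arrow)
    stoich: Dict[str, float] = {}

    def _add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    _add_side(lhs_str, -1.0)
    _add_side(rhs_str, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}, reversible


def write_model_tabular(model: MetabolicModel, directory: str) -> None:
    """Write a model as ``metabolites.tsv`` + ``reactions.tsv``."""
    os.makedirs(directory, exist_ok=True)
    met_rows = []
    for mid in sorted(model.metabolites):
        m = model.metabolites[mid]
        met_rows.append(
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment.value,
                "formula": m.formula or "",
                "charge": "" if m.charge is None else str(m.charge),
            }
        )
    pd.DataFrame(met_rows).to_csv(
        os.path.join(directory, "metabolites.tsv"), sep="\t", index=False
    )
    rxn_rows = []
    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rxn_rows.append(
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r),
                "lower_bound": repr(r.lower_bound),
                "upper_bound": repr(r.upper_bound),
                "subsystem": r.subsystem,
                "ec": ";".join(r.ec_numbers),
                "genes": ";".join(sorted(r.gene_ids)),
                "is_exchange": str(int(r.is_exchange)),
                "db_source": r.db_source.value,
            }
        )
    pd.DataFrame(rxn_rows).to_csv(
        os.path.join(directory, "reactions.tsv"), sep="\t", index=False
    )
    with open(os.path.join(directory, "model.tsv"), "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"id\t{model.id}\n")
        fh.write(f"biomass_reaction_id\t{model.biomass_reaction_id}\n")
        for k in sorted(model.annotations):
            fh.write(f"annotation:{k}\t{model.annotations[k]}\n")


def read_model_tabular(directory: str) -> MetabolicModel:
    """Read a model written by :func:`write_model_tabular`."""
    mets_df = pd.read_csv(
        os.path.join(directory, "metabolites.tsv"), sep="\t", dtype=str
    ).fillna("")
    rxns_df = pd.read_csv(
        os.path.join(directory, "reactions.tsv"), sep="\t", dtype=str
    ).fillna("")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row["name"],
            compartment=Compartment(row["compartment"]),
            formula=row["formula"] or None,
            charge=int(row["charge"]) if row["charge"] else None,
        )
        for _, row in mets_df.iterrows()
    ]
    reactions = []
    for _, row in rxns_df.iterrows():
        stoich, _ = parse_equation(row["equation"])
        reactions.append(
            Reaction(
                id=row["id"],
                name=row["name"],
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                subsystem=row["subsystem"],
                ec_numbers=[e for e in row["ec"].split(";") if e],
                gene_ids={g for g in row["genes"].split(";") if g},
                is_exchange=bool(int(row["is_exchange"])),
                db_source=DbSource(row["db_source"]),
            )
        )
    model_id = ""
    biomass_id = ""
    annotations: Dict[str, str] = {}
    meta_path = os.path.join(directory, "model.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        for _, row in meta.iterrows():
            key, value = row["key"], row["value"]
            if key == "id":
                model_id = value
            elif key == "biomass_reaction_id":
                biomass_id = value
            elif key.startswith("annotation:"):
                annotations[key[len("annotation:") :]] = value
    return MetabolicModel.from_lists(
        model_id or os.path.basename(os.path.normpath(directory)),
        metabolites,
        reactions,
        biomass_reaction_id=biomass_id,
        annotations=annotations,
    )


# --- SBML Level 3 (fbc flux bounds) ------------------------------------

_COMP_CODES = {
    Compartment.CYTOSOL: "c",
    Compartment.PLASTID: "p",
    Compartment.MITOCHONDRION: "m",
    Compartment.PEROXISOME: "x",
    Compartment.EXTRACELLULAR: "e",
}
_CODE_COMPS = {v: k for k, v in _COMP_CODES.items()}


def write_model_sbml(model: MetabolicModel, path: str) -> None:
    """Export as SBML Level 3 Version 1 with fbc flux bounds."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id or "model")
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for comp in Compartment:
        c = sbml_model.createCompartment()
        c.setId(_COMP_CODES[comp])
        c.setName(comp.value)
        c.setConstant(True)

    for mid in sorted(model.metabolites):
        m = model.metabolites[mid]
        sp = sbml_model.createSpecies()
        sp.setId(f"M_{m.id}")
        sp.setName(m.name or m.id)
        sp.setCompartment(_COMP_CODES[m.compartment])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    bounds_seen: Dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"bnd_{len(bounds_seen)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        rx = sbml_model.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for met_id, coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rx.createReactant()
            else:
                ref = rx.createProduct()
            ref.setSpecies(f"M_{met_id}")
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = rx.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(r.upper_bound))

    libsbml.writeSBMLToFile(doc, path)


def read_model_sbml(path: str) -> MetabolicModel:
    """Import an SBML Level 3 fbc model written by :func:`write_model_sbml`.

    Subsystem, gene and provenance metadata are not part of core SBML and
    are left at their defaults; reaction count, bounds and stoichiometry
    are preserved.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML read error in {path}: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = sp.getId()
        sid = sid[2:] if sid.startswith("M_") else sid
        metabolites.append(
            Metabolite(
                id=sid,
                name=sp.getName(),
                compartment=_CODE_COMPS.get(sp.getCompartment(), Compartment.CYTOSOL),
            )
        )
    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = rx.getId()
        rid = rid[2:] if rid.startswith("R_") else rid
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            met = ref.getSpecies()
            met = met[2:] if met.startswith("M_") else met
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            met = ref.getSpecies()
            met = met[2:] if met.startswith("M_") else met
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb = params.get(rfbc.getLowerFluxBound(), 0.0)
        ub = params.get(rfbc.getUpperFluxBound(), 1000.0)
        reactions.append(
            Reaction(
                id=rid,
                name=rx.getName(),
                stoichiometry={m: c for m, c in stoich.items() if c != 0.0},
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=len(stoich) == 1,
            )
        )
    return MetabolicModel.from_lists(sbml_model.getId(), metabolites, reactions)
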