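"""Biomass objective construction from measured end-product compositions.

A biomass objective is a single lumped pseudo-reaction that drains each
measured end product (oleoresin terpenoid classes, protein, chlorophyll,
starch, lignin, flavonoids) in stoichiometric proportion to its measured
concentration: a component at c mg per g dry weight with molecular weight
M g/mol contributes a drain coefficient of c/M mmol·gDW⁻¹.  Protein mass is
expanded into per-residue amino-acid drains using the mole-fraction
composition of a reference protein — for a secretory cell a highly
expressed soluble enzyme such as a glutathione S-transferase, for a
photosynthetic cell Rubisco.

Oleoresin is measured on bulk needle tissue, but is produced by the
epithelial cells lining the resin ducts, which occupy only a small volume
fraction of the needle.  The geometry helpers convert needle and duct
cross-section measurements into that volume fraction: a needle tapers over
its distal third, so its volume is cylinder-like over the proximal two
thirds (area × 2L/3) plus an elliptical cap (⅔ × area × L/3), totalling
(8/9)·A·L, while each duct is a cylinder running the full length (a·L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional

import pandas as pd

from .core import Reaction

__all__ = [
    "ProductClass",
    "BiomassComponent",
    "BiomassComposition",
    "NeedleGeometry",
    "needle_volume",
    "duct_volume_fraction",
    "aa_composition",
    "build_biomass_reaction",
    "read_composition_tsv",
    "write_composition_tsv",
    "AA_RESIDUE_MASS",
    "DEFAULT_ATP_MAINTENANCE",
]


class ProductClass(str, Enum):
    MONOTERPENE = "monoterpene"
    SESQUITERPENE = "sesquiterpene"
    DITERPENOID = "diterpenoid"
    PROTEIN = "protein"
    CHLOROPHYLL = "chlorophyll"
    STARCH = "starch"
    LIGNIN = "lignin"
    FLAVONOID = "flavonoid"
    OTHER = "other"


# Average residue masses (g/mol, monomer minus water) of the 20 standard
# amino acids.
AA_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

# Non-growth maintenance ATP charged inside the biomass reaction
# (mmol ATP per gDW of biomass formed).
DEFAULT_ATP_MAINTENANCE = 30.0


@dataclass(frozen=True)
class BiomassComponent:
    component_id: str
    product_class: ProductClass
    concentration: float  # mg per g dry weight
    mw: float  # g per mol

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.component_id}: concentration < 0")
        if self.mw <= 0:
            raise ValueError(f"{self.component_id}: molecular weight must be > 0")


@dataclass
class BiomassComposition:
    """Measured end-product composition of one cell type (mg/gDW)."""

    cell_type: str
    components: List[BiomassComponent] = field(default_factory=list)

    def class_total(self, product_class: ProductClass) -> float:
        return sum(
            c.concentration for c in self.components if c.product_class == product_class
        )

    def class_totals(self) -> Dict[ProductClass, float]:
        out: Dict[ProductClass, float] = {}
        for c in self.components:
            out[c.product_class] = out.get(c.product_class, 0.0) + c.concentration
        return out

    def total(self) -> float:
        return sum(c.concentration for c in self.components)


@dataclass(frozen=True)
class NeedleGeometry:
    """Cross-section geometry of a needle and its resin ducts (mm, mm²)."""

    cross_section_area: float
    length: float
    duct_areas: tuple = ()

    def __post_init__(self) -> None:
        if self.cross_section_area <= 0:
            raise ValueError("cross-section area must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        object.__setattr__(self, "duct_areas", tuple(self.duct_areas))
        if any(a < 0 for a in self.duct_areas):
            raise ValueError("duct areas must be >= 0")
        if sum(self.duct_areas) >= self.cross_section_area:
            raise ValueError("total duct area must be smaller than the needle area")


def needle_volume(area: float, length: float) -> float:
    """Volume of a tapering needle from mid-length cross-section area.

    Proximal two thirds as a cylinder (A · 2L/3) plus the distal third as
    an elliptical cap (⅔ · A · L/3); total (8/9)·A·L (mm³ for mm², mm).
    """
    if area <= 0 or length <= 0:
        raise ValueError("area and length must be > 0")
    return area * (2.0 * length / 3.0) + (2.0 / 3.0) * area * (length / 3.0)


def duct_volume_fraction(geom: NeedleGeometry) -> float:
    """Fraction of needle volume occupied by resin ducts.

    Ducts are cylinders spanning the needle, so the fraction reduces to
    (9/8) · (Σ duct areas) / A and is independent of length.
    """
    duct_volume = sum(geom.duct_areas) * geom.length
    return duct_volume / needle_volume(geom.cross_section_area, geom.length)


def aa_composition(protein_sequence: str) -> Dict[str, float]:
    """Mole fraction of each residue in a protein sequence."""
    seq = protein_sequence.strip().upper()
    if not seq:
        raise ValueError("protein sequence is empty")
    counts: Dict[str, int] = {}
    for pos, letter in enumerate(seq):
        if letter not in AA_RESIDUE_MASS:
            raise ValueError(
                f"non-standard residue {letter!r} at position {pos + 1}"
            )
        counts[letter] = counts.get(letter, 0) + 1
    n = len(seq)
    return {aa: counts[aa] / n for aa in sorted(counts)}


def build_biomass_reaction(
    comp: BiomassComposition,
    metabolite_ids: Dict[str, str],
    aa_fractions: Optional[Dict[str, float]] = None,
    amino_acid_ids: Optional[Dict[str, str]] = None,
    scale: Optional[float] = None,
    atp_maintenance: float = DEFAULT_ATP_MAINTENANCE,
    atp_id: Optional[str] = None,
    adp_id: Optional[str] = None,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Assemble the biomass pseudo-reaction from a composition table.

    ``metabolite_ids`` maps each non-protein component id to the model
    metabolite it drains.  Protein components are expanded into amino-acid
    drains by ``aa_fractions`` through ``amino_acid_ids`` (several residues
    may map to one pooled metabolite; their coefficients add).  ``scale``
    multiplies all concentrations — pass 1/duct_volume_fraction to convert
    bulk-needle measurements into per-epithelial-cell outputs.  A
    maintenance ATP hydrolysis of ``atp_maintenance`` mmol/gDW is included
    when ATP/ADP ids are given.
    """
    factor = 1.0 if scale is None else float(scale)
    stoich: Dict[str, float] = {}
    protein_conc = 0.0
    for component in comp.components:
        conc = component.concentration * factor
        if conc == 0.0:
            continue
        if component.product_class is ProductClass.PROTEIN:
            protein_conc += conc
            continue
        if component.component_id not in metabolite_ids:
            raise KeyError(
                f"no model metabolite mapped for component {component.component_id!r}"
            )
        met = metabolite_ids[component.component_id]
        stoich[met] = stoich.get(met, 0.0) - conc / component.mw
    if protein_conc > 0.0:
        if not aa_fractions or not amino_acid_ids:
            raise ValueError(
                "composition contains protein but no amino-acid fractions/ids given"
            )
        mean_residue_mass = sum(
            frac * AA_RESIDUE_MASS[aa] for aa, frac in aa_fractions.items()
        )
        total_residue_mmol = protein_conc / mean_residue_mass
        for aa, frac in aa_fractions.items():
            if aa not in amino_acid_ids:
                raise KeyError(f"no model metabolite mapped for residue {aa!r}")
            met = amino_acid_ids[aa]
            stoich[met] = stoich.get(met, 0.0) - frac * total_residue_mmol
    if atp_maintenance > 0.0 and atp_id and adp_id:
        stoich[atp_id] = stoich.get(atp_id, 0.0) - atp_maintenance
        stoich[adp_id] = stoich.get(adp_id, 0.0) + atp_maintenance
    return Reaction(
        id=reaction_id,
        name=f"{comp.cell_type} biomass",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
    )


def write_composition_tsv(comp: BiomassComposition, path: str) -> None:
    pd.DataFrame(
        [
            {
                "component": c.component_id,
                "class": c.product_class.value,
                "mg_per_gDW": repr(c.concentration),
                "mw_g_per_mol": repr(c.mw),
            }
            for c in comp.components
        ]
    ).to_csv(path, sep="\t", index=False)


def read_composition_tsv(path: str, cell_type: str = "") -> BiomassComposition:
    df = pd.read_csv(path, sep="\t")
    return BiomassComposition(
        cell_type or path,
        [
            BiomassComponent(
                component_id=str(row["component"]),
                product_class=ProductClass(row["class"]),
                concentration=float(row["mg_per_gDW"]),
                mw=float(row["mw_g_per_mol"]),
            )
            for _, row in df.iterrows()
        ],
    )
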