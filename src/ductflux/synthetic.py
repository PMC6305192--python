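"""Synthetic study system: a miniature plant-cell metabolic network, paired
cell-type expression profiles with controlled cross-contamination, and
end-product composition tables.

The miniature network is a deliberately small (≈58 reactions) but complete
caricature of needle-cell metabolism, with cytosol, plastid, mitochondrion
and extracellular compartments.  It contains light reactions, a lumped
Calvin–Benson cycle, sucrose import and degradation, glycolysis and
gluconeogenesis, the oxidative pentose-phosphate pathway, the citric-acid
cycle, oxidative phosphorylation, ethanolic fermentation, both directions
of ferredoxin-NADP⁺ reductase (FNR), lumped MEP and MVA isoprenoid
pathways, and synthesis plus sinks for monoterpenes, diterpenoids,
sesquiterpenes, protein, chlorophyll, starch, lignin and flavonoids.

Two cell-type variants are produced.  The *epithelial* (resin-duct
secretory) variant is heterotrophic: sucrose import is open and the
biomass objective drains the oleoresin terpenoid classes plus protein.
The *mesophyll* variant is photoautotrophic: sucrose import is closed and
biomass drains chlorophyll, starch, lignin, flavonoid and protein with
only trace terpenoids.

Lumped reactions use textbook net stoichiometries on the carbon and
cofactor species the model tracks (e.g. one triose phosphate plus one
pyruvate plus NADPH, ATP and two reduced ferredoxins per IPP through the
MEP pathway); elemental balance of species the model does not track is not
enforced.  The reverse (non-photosynthetic) FNR carries a one-ATP coupling
representing the metabolic cost of driving ferredoxin reduction against
the redox gradient, which also keeps the paired FNR isoforms from forming
a spurious closed energy cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .biomass import (
    BiomassComponent,
    BiomassComposition,
    ProductClass,
    aa_composition,
    build_biomass_reaction,
)
from .core import Compartment, MetabolicModel, Metabolite, Reaction
from .expression import ExpressionProfile
from .io import parse_equation
from .mapping import DbSource, GeneReactionMap

__all__ = [
    "ExpressionSimSpec",
    "make_mini_plant_model",
    "simulate_expression",
    "pure_expression",
    "make_biomass_table",
    "make_complete_map",
    "make_hit_records",
    "make_localization_records",
    "MESOPHYLL_MARKER",
    "EPITHELIAL_MARKER",
    "EPITHELIAL_ENRICHMENT",
    "MESOPHYLL_ENRICHMENT",
    "GST_LIKE_SEQUENCE",
    "RUBISCO_LIKE_SEQUENCE",
]

CELL_TYPES = ("epithelial", "mesophyll")

# Marker transcripts used for contamination estimation: a Rubisco
# small-subunit analog expressed only in the mesophyll baseline, and a
# diterpene-synthase (LAS) analog expressed only in the epithelial baseline.
MESOPHYLL_MARKER = "PITA_RBCS"
EPITHELIAL_MARKER = "PITA_LAS"

# Baseline TPM assigned to a marker in its home cell type before noise.
_MARKER_BASELINE = 2000.0

# Default subsystem-level enrichment fold changes defining the two
# cell-type expression programs.  Magnitudes follow the observed pattern:
# terpene-synthase transcripts roughly an order of magnitude higher in
# epithelial cells, MEP/MVA and fermentative/respiratory subsystems a few
# fold higher, photosynthetic subsystems strongly mesophyll-biased.
EPITHELIAL_ENRICHMENT: Dict[str, float] = {
    "monoterpene_synthesis": 10.0,
    "diterpene_synthesis": 8.0,
    "sesquiterpene_synthesis": 1.5,
    "mep_pathway": 2.0,
    "mva_pathway": 3.0,
    "sucrose_metabolism": 3.0,
    "glycolysis": 2.0,
    "oxidative_pentose_phosphate": 2.0,
    "citric_acid_cycle": 2.0,
    "oxidative_phosphorylation": 2.0,
    "fermentation": 3.0,
}
MESOPHYLL_ENRICHMENT: Dict[str, float] = {
    "light_reactions": 8.0,
    "calvin_cycle": 6.0,
    "chlorophyll_synthesis": 5.0,
    "starch_synthesis": 4.0,
    "lignin_synthesis": 3.0,
    "flavonoid_synthesis": 3.0,
}

# Synthetic stand-in reference proteins for the amino-acid composition of
# total protein: a glutathione-S-transferase-like sequence for the
# secretory cell type and a Rubisco-like sequence for the photosynthetic
# one.  Both are artificial 80-residue sequences with a typical globular
# composition, not database entries.
GST_LIKE_SEQUENCE = (
    "MAEVKLLGAWPSPFVTRVKLALALKGLSYEDVEENLGNKSELLLQSNPVHKKIPVLIHNG"
    "KPVCESLIILEYIDETWK"
)
RUBISCO_LIKE_SEQUENCE = (
    "MSPQTETKASVGFKAGVKDYKLTYYTPDYETKDTDILAAFRVTPQPGVPPEEAGAAVAAE"
    "SSTGTWTTVWTDGLTSLD"
)

# Class-proxy molecular weights (g/mol): alpha-pinene, longifolene,
# abietic acid, a diterpene alcohol, chlorophyll a, a starch glucosyl
# unit, a coniferyl unit and catechin.
_MW = {
    "monoterpenes": 136.23,
    "sesquiterpenes": 204.35,
    "resin_acids": 302.45,
    "other_diterpenoids": 288.47,
    "chlorophylls": 893.49,
    "starch": 162.14,
    "lignins": 180.20,
    "flavonoids": 290.27,
    "protein": 110.0,  # nominal mean residue mass; drains expand per residue
}

# Needle oleoresin class concentrations (mg per g dry weight) used for the
# epithelial composition: monoterpenes 5.76, sesquiterpenes 0.35, resin
# acids 3.81 and other diterpenoids 0.11.  The mesophyll composition
# allocates mass to chlorophyll, starch, lignin, flavonoid and protein at
# magnitudes typical for conifer foliage, with every terpenoid class held
# at or below 5% of its epithelial value.
_EPITHELIAL_COMPOSITION = [
    ("monoterpenes", ProductClass.MONOTERPENE, 5.76),
    ("sesquiterpenes", ProductClass.SESQUITERPENE, 0.35),
    ("resin_acids", ProductClass.DITERPENOID, 3.81),
    ("other_diterpenoids", ProductClass.DITERPENOID, 0.11),
    ("protein", ProductClass.PROTEIN, 50.0),
]
_MESOPHYLL_COMPOSITION = [
    ("chlorophylls", ProductClass.CHLOROPHYLL, 2.5),
    ("starch", ProductClass.STARCH, 40.0),
    ("lignins", ProductClass.LIGNIN, 30.0),
    ("flavonoids", ProductClass.FLAVONOID, 8.0),
    ("protein", ProductClass.PROTEIN, 120.0),
    ("monoterpenes", ProductClass.MONOTERPENE, 0.20),
    ("sesquiterpenes", ProductClass.SESQUITERPENE, 0.015),
    ("resin_acids", ProductClass.DITERPENOID, 0.15),
]


@dataclass
class ExpressionSimSpec:
    """Parameters of one simulated cell-type expression profile."""

    n_transcripts: int = 500
    cell_type: str = "epithelial"
    enrichment: Optional[Dict[str, float]] = None
    contamination_fraction: float = 0.0
    noise_dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if self.noise_dispersion <= 0.0:
            raise ValueError("noise_dispersion must be > 0")
        if self.enrichment is not None and any(
            f <= 0 for f in self.enrichment.values()
        ):
            raise ValueError("enrichment fold changes must be > 0")


# --- the miniature network ---------------------------------------------

# (id, name, equation, subsystem, genes, is_exchange, lb, ub)
# lb/ub of None mean the irreversible/reversible defaults [0,1000]/[-1000,1000];
# equations use '-->' (irreversible) and '<=>' (reversible).
_MINI_REACTIONS = [
    # exchanges
    ("EX_photon", "photon exchange", "photon_e --> ", "exchange", (), True, -100.0, 0.0),
    ("EX_co2", "CO2 exchange", "co2_e --> ", "exchange", (), True, -1000.0, 1000.0),
    ("EX_o2", "O2 exchange", "o2_e --> ", "exchange", (), True, -1000.0, 1000.0),
    ("EX_sucr", "sucrose exchange", "sucr_e --> ", "exchange", (), True, None, 0.0),
    ("EX_etoh", "ethanol exchange", "etoh_e --> ", "exchange", (), True, 0.0, 1000.0),
    # end-product sinks
    ("DM_mono", "monoterpene sink", "mono_c --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_sesq", "sesquiterpene sink", "sesq_c --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_dit", "diterpenoid sink", "dit_c --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_protein", "protein sink", "protein_c --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_chl", "chlorophyll sink", "chl_p --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_starch", "starch sink", "starch_p --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_lignin", "lignin sink", "lignin_c --> ", "sink", (), True, 0.0, 1000.0),
    ("DM_flav", "flavonoid sink", "flav_c --> ", "sink", (), True, 0.0, 1000.0),
    # absorbed photons that are not used photochemically are dissipated
    # as heat/fluorescence; this valve keeps forced light input feasible
    ("NPQ", "non-photochemical quenching (photon dissipation)",
     "photon_p --> ", "sink", (), True, 0.0, 1000.0),
    # transport
    ("PHOTt", "photon capture", "photon_e --> photon_p", "transport", (), False, None, None),
    ("CO2tc", "CO2 diffusion", "co2_e <=> co2_c", "transport", (), False, None, None),
    ("CO2tp", "CO2 plastid", "co2_c <=> co2_p", "transport", (), False, None, None),
    ("CO2tm", "CO2 mitochondrion", "co2_c <=> co2_m", "transport", (), False, None, None),
    ("O2tc", "O2 diffusion", "o2_e <=> o2_c", "transport", (), False, None, None),
    ("O2tp", "O2 plastid", "o2_c <=> o2_p", "transport", (), False, None, None),
    ("O2tm", "O2 mitochondrion", "o2_c <=> o2_m", "transport", (), False, None, None),
    ("SUCt", "sucrose import", "sucr_e --> sucr_c", "transport", (), False, None, None),
    ("ETOHt", "ethanol export", "etoh_c --> etoh_e", "transport", (), False, None, None),
    ("GAPtp", "triose phosphate translocator", "gap_c <=> gap_p", "transport", (), False, None, None),
    ("G6Ptp", "glucose 6-phosphate translocator", "g6p_c <=> g6p_p", "transport", (), False, None, None),
    ("PYRtp", "pyruvate plastid transport", "pyr_c <=> pyr_p", "transport", (), False, None, None),
    ("PYRtm", "pyruvate mitochondrial import", "pyr_c --> pyr_m", "transport", (), False, None, None),
    ("ATPtp", "plastid ATP/ADP translocator", "atp_c + adp_p <=> atp_p + adp_c", "transport", (), False, None, None),
    ("ATPtm", "mitochondrial ADP/ATP carrier", "atp_m + adp_c --> atp_c + adp_m", "transport", (), False, None, None),
    ("NADHsh", "malate shuttle (lumped)", "nadh_c + nad_m --> nad_c + nadh_m", "transport", (), False, None, None),
    ("MONOtp", "monoterpene export from plastid", "mono_p --> mono_c", "transport", (), False, None, None),
    ("DITtp", "diterpenoid export from plastid", "dit_p --> dit_c", "transport", (), False, None, None),
    # light reactions and FNR
    ("LIGHT", "light reactions (lumped PSII/PSI/ATPase)",
     "8 photon_p + 2 fdox_p + 3 adp_p --> 2 fdred_p + 3 atp_p + o2_p",
     "light_reactions", ("PITA_PSBA", "PITA_PSAA"), False, None, None),
    ("FNR_PS", "photosynthetic ferredoxin-NADP+ reductase",
     "2 fdred_p + nadp_p --> 2 fdox_p + nadph_p",
     "fnr", ("PITA_FNR1",), False, None, None),
    ("FNR_NPS", "non-photosynthetic ferredoxin-NADP+ reductase",
     "nadph_p + 2 fdox_p + atp_p --> nadp_p + 2 fdred_p + adp_p",
     "fnr", ("PITA_FNR2",), False, None, None),
    # carbon fixation and central carbon metabolism
    ("CALVIN", "Calvin-Benson cycle (lumped)",
     "3 co2_p + 9 atp_p + 6 nadph_p --> gap_p + 9 adp_p + 6 nadp_p",
     "calvin_cycle", ("PITA_RBCS", "PITA_PRK"), False, None, None),
    ("OPPPp", "oxidative pentose-phosphate pathway (plastid, lumped)",
     "3 g6p_p + 6 nadp_p --> 6 nadph_p + 3 co2_p + 5 gap_p",
     "oxidative_pentose_phosphate", ("PITA_G6PD1",), False, None, None),
    ("OPPPc", "oxidative pentose-phosphate pathway (cytosol, lumped)",
     "3 g6p_c + 6 nadp_c --> 6 nadph_c + 3 co2_c + 5 gap_c",
     "oxidative_pentose_phosphate", ("PITA_G6PD2",), False, None, None),
    ("GNGp", "hexose phosphate synthesis (plastid)",
     "2 gap_p --> g6p_p", "gluconeogenesis", ("PITA_FBP1",), False, None, None),
    ("GNGc", "hexose phosphate synthesis (cytosol)",
     "2 gap_c --> g6p_c", "gluconeogenesis", ("PITA_FBP2",), False, None, None),
    ("SUCDEG", "sucrose degradation (invertase + hexokinase)",
     "sucr_c + 2 atp_c --> 2 g6p_c + 2 adp_c",
     "sucrose_metabolism", ("PITA_INV1", "PITA_HXK1"), False, None, None),
    ("GLYC1", "glycolysis, hexose to triose",
     "g6p_c + atp_c --> 2 gap_c + adp_c",
     "glycolysis", ("PITA_PFK1",), False, None, None),
    ("GLYC2", "glycolysis, triose to pyruvate",
     "gap_c + nad_c + 2 adp_c --> pyr_c + nadh_c + 2 atp_c",
     "glycolysis", ("PITA_GAPC1", "PITA_PK1"), False, None, None),
    ("ACCOA", "cytosolic acetyl-CoA synthesis",
     "pyr_c + nad_c --> accoa_c + co2_c + nadh_c",
     "acetyl_coa", ("PITA_ACL1",), False, None, None),
    ("TCA", "pyruvate oxidation + citric-acid cycle (lumped)",
     "pyr_m + 4 nad_m + adp_m --> 3 co2_m + 4 nadh_m + atp_m",
     "citric_acid_cycle", ("PITA_CS1", "PITA_IDH1"), False, None, None),
    ("OXPHOS", "oxidative phosphorylation (lumped)",
     "2 nadh_m + o2_m + 5 adp_m --> 2 nad_m + 5 atp_m",
     "oxidative_phosphorylation", ("PITA_COX1", "PITA_ATP1"), False, None, None),
    ("FERM", "ethanolic fermentation",
     "pyr_c + nadh_c --> etoh_c + co2_c + nad_c",
     "fermentation", ("PITA_PDC1", "PITA_ADH1"), False, None, None),
    ("STARCHS", "starch synthesis",
     "g6p_p + atp_p --> starch_p + adp_p",
     "starch_synthesis", ("PITA_AGP1",), False, None, None),
    # isoprenoid precursor pathways
    ("MEP", "MEP pathway (lumped; HDS/HDR require reduced ferredoxin)",
     "gap_p + pyr_p + nadph_p + atp_p + 2 fdred_p --> "
     "ipp_p + co2_p + nadp_p + adp_p + 2 fdox_p",
     "mep_pathway", ("PITA_DXS1", "PITA_HDR1"), False, None, None),
    ("MVA", "MVA pathway (lumped)",
     "3 accoa_c + 2 nadph_c + 3 atp_c --> ipp_c + co2_c + 2 nadp_c + 3 adp_c",
     "mva_pathway", ("PITA_HMGR1", "PITA_MK1"), False, None, None),
    # terpenoid and other end products
    ("MONOS", "monoterpene synthases (lumped C10)",
     "2 ipp_p --> mono_p",
     "monoterpene_synthesis", ("PITA_PT1", "PITA_PT30"), False, None, None),
    ("DITS", "diterpene synthase / resin-acid oxygenases (lumped C20)",
     "4 ipp_p --> dit_p",
     "diterpene_synthesis", ("PITA_LAS", "PITA_TPS19"), False, None, None),
    ("SESQS", "sesquiterpene synthase (lumped C15)",
     "3 ipp_c --> sesq_c",
     "sesquiterpene_synthesis", ("PITA_STS1",), False, None, None),
    ("CHLS", "chlorophyll synthesis (lumped)",
     "4 ipp_p + 4 atp_p + 2 nadph_p --> chl_p + 4 adp_p + 2 nadp_p",
     "chlorophyll_synthesis", ("PITA_CHLG1",), False, None, None),
    ("AAS", "amino-acid synthesis (lumped)",
     "2 pyr_c + nadph_c + 2 atp_c --> aa_c + co2_c + nadp_c + 2 adp_c",
     "amino_acid_metabolism", ("PITA_AST1",), False, None, None),
    ("PROTS", "protein synthesis (per residue)",
     "aa_c + 4 atp_c --> protein_c + 4 adp_c",
     "protein_synthesis", ("PITA_RPL1",), False, None, None),
    ("LIGS", "monolignol synthesis (lumped phenylpropanoid)",
     "aa_c + nadph_c --> lignin_c + nadp_c",
     "lignin_synthesis", ("PITA_PAL1",), False, None, None),
    ("FLAVS", "flavonoid synthesis (lumped)",
     "aa_c + 3 accoa_c + nadph_c --> flav_c + 3 co2_c + nadp_c",
     "flavonoid_synthesis", ("PITA_CHS1",), False, None, None),
]

_MINI_METABOLITES = {
    Compartment.EXTRACELLULAR: ["photon_e", "co2_e", "o2_e", "sucr_e", "etoh_e"],
    Compartment.CYTOSOL: [
        "co2_c", "o2_c", "sucr_c", "g6p_c", "gap_c", "pyr_c", "accoa_c",
        "atp_c", "adp_c", "nad_c", "nadh_c", "nadp_c", "nadph_c", "ipp_c",
        "mono_c", "sesq_c", "dit_c", "aa_c", "protein_c", "lignin_c",
        "flav_c", "etoh_c",
    ],
    Compartment.PLASTID: [
        "photon_p", "co2_p", "o2_p", "g6p_p", "gap_p", "pyr_p", "atp_p",
        "adp_p", "nadp_p", "nadph_p", "fdred_p", "fdox_p", "ipp_p",
        "mono_p", "dit_p", "chl_p", "starch_p",
    ],
    Compartment.MITOCHONDRION: [
        "co2_m", "o2_m", "pyr_m", "atp_m", "adp_m", "nad_m", "nadh_m",
    ],
}

_BIOMASS_METABOLITE_MAP = {
    "monoterpenes": "mono_c",
    "sesquiterpenes": "sesq_c",
    "resin_acids": "dit_c",
    "other_diterpenoids": "dit_c",
    "chlorophylls": "chl_p",
    "starch": "starch_p",
    "lignins": "lignin_c",
    "flavonoids": "flav_c",
}


def make_biomass_table(
    cell_type: str, seed: int = 0, jitter: float = 0.0
) -> BiomassComposition:
    """End-product composition table for one cell type (mg/gDW).

    The epithelial table centers on the needle oleoresin measurements
    (monoterpenes 5.76, sesquiterpenes 0.35, total diterpenoids 3.92
    mg/gDW); the mesophyll table allocates mass to chlorophyll, starch,
    lignin, flavonoid and protein with terpenoid classes at ≤5% of the
    epithelial values.  ``jitter`` applies multiplicative log-normal noise
    with the given log-scale standard deviation; 0 returns the central
    values exactly.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    rows = (
        _EPITHELIAL_COMPOSITION if cell_type == "epithelial" else _MESOPHYLL_COMPOSITION
    )
    rng = np.random.default_rng([seed, CELL_TYPES.index(cell_type), 7])
    components = []
    for component_id, product_class, conc in rows:
        factor = float(rng.lognormal(0.0, jitter)) if jitter > 0 else 1.0
        components.append(
            BiomassComponent(component_id, product_class, conc * factor, _MW[component_id])
        )
    return BiomassComposition(cell_type, components)


def make_mini_plant_model(cell_type: str) -> MetabolicModel:
    """Build the miniature plant-cell model for one cell type.

    Both variants share the reaction set; they differ in the sucrose
    exchange bounds (open uptake for epithelial, closed for mesophyll) and
    in the biomass objective built from :func:`make_biomass_table`.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    metabolites = [
        Metabolite(mid, name=mid, compartment=comp)
        for comp, ids in _MINI_METABOLITES.items()
        for mid in ids
    ]
    reactions = []
    for rid, name, equation, subsystem, genes, is_exchange, lb, ub in _MINI_REACTIONS:
        stoich, reversible = parse_equation(equation)
        lower = lb if lb is not None else (-1000.0 if reversible else 0.0)
        upper = ub if ub is not None else 1000.0
        reactions.append(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=stoich,
                lower_bound=lower,
                upper_bound=upper,
                subsystem=subsystem,
                gene_ids=set(genes),
                is_exchange=is_exchange,
                db_source=DbSource.CUSTOM,
            )
        )
    sucrose = next(r for r in reactions if r.id == "EX_sucr")
    if cell_type == "epithelial":
        sucrose.lower_bound = -10.0  # sucrose import open: heterotrophic carbon
    else:
        sucrose.lower_bound = 0.0  # autotrophic: no oligosaccharide uptake

    comp = make_biomass_table(cell_type, jitter=0.0)
    reference_seq = (
        GST_LIKE_SEQUENCE if cell_type == "epithelial" else RUBISCO_LIKE_SEQUENCE
    )
    fractions = aa_composition(reference_seq)
    biomass = build_biomass_reaction(
        comp,
        metabolite_ids=_BIOMASS_METABOLITE_MAP,
        aa_fractions=fractions,
        amino_acid_ids={aa: "protein_c" for aa in fractions},
        atp_id="atp_c",
        adp_id="adp_c",
        reaction_id="BIOMASS",
    )
    reactions.append(biomass)
    model = MetabolicModel.from_lists(
        f"mini_{cell_type}",
        metabolites,
        reactions,
        biomass_reaction_id="BIOMASS",
        annotations={
            "photon_exchange_id": "EX_photon",
            "cell_type": cell_type,
        },
    )
    return model


def make_complete_map(
    model: MetabolicModel,
    db_source: DbSource = DbSource.ARABIDOPSIS_CORE,
    identity: float = 90.0,
) -> GeneReactionMap:
    """Gene-reaction map associating every gene-bearing reaction with all
    of its own transcripts (the 'complete evidence' scenario)."""
    grmap = GeneReactionMap()
    for rid in sorted(model.reactions):
        for gene in sorted(model.reactions[rid].gene_ids):
            grmap.add(rid, gene, db_source, identity)
    return grmap


def make_hit_records(
    model: MetabolicModel,
    seed: int = 0,
    n_decoys: int = 40,
    identity_range: tuple = (60.0, 95.0),
):
    """Synthetic sequence-similarity hit table consistent with the model.

    Every gene transcript of the model hits its own reaction(s) from the
    top-priority database at an identity drawn uniformly from
    ``identity_range``; ``n_decoys`` filler transcripts hit random
    reactions below the default 40% identity threshold and should be
    discarded by association.
    """
    from .mapping import HitRecord

    rng = np.random.default_rng([seed, 11])
    hits = []
    for rid in sorted(model.reactions):
        for gene in sorted(model.reactions[rid].gene_ids):
            identity = float(rng.uniform(*identity_range))
            hits.append(HitRecord(gene, rid, DbSource.ARABIDOPSIS_CORE, identity))
    rxn_ids = sorted(model.reactions)
    for i in range(n_decoys):
        rid = rxn_ids[int(rng.integers(len(rxn_ids)))]
        identity = float(rng.uniform(5.0, 35.0))
        hits.append(
            HitRecord(f"PITA_BG{i:05d}", rid, DbSource.METACYC, identity)
        )
    return hits


def make_localization_records(model: MetabolicModel, score: float = 0.9):
    """Localization predictions agreeing with each reaction's compartment.

    For every gene transcript, predicts the (majority) compartment of the
    non-extracellular metabolites of its reaction, so applying them to the
    model is a no-op — the baseline scenario for localization tests.
    """
    from .mapping import LocalizationRecord

    records = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        comps = [
            model.metabolites[mid].compartment
            for mid in rxn.stoichiometry
            if model.metabolites[mid].compartment is not Compartment.EXTRACELLULAR
        ]
        if not comps:
            continue
        majority = max(set(comps), key=comps.count)
        for gene in sorted(rxn.gene_ids):
            records.append(LocalizationRecord(gene, majority, score))
    return records


def _transcript_universe(model: MetabolicModel, n_transcripts: int) -> List[str]:
    genes = sorted(model.genes())
    if n_transcripts < len(genes):
        raise ValueError(
            f"n_transcripts {n_transcripts} smaller than the model's "
            f"{len(genes)} gene transcripts"
        )
    fillers = [f"PITA_BG{i:05d}" for i in range(n_transcripts - len(genes))]
    return genes + fillers


def _gene_subsystems(model: MetabolicModel) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for rxn in model.reactions.values():
        for gene in rxn.gene_ids:
            out.setdefault(gene, []).append(rxn.subsystem)
    return out


def pure_expression(
    model: MetabolicModel,
    cell_type: str,
    n_transcripts: int = 500,
    enrichment: Optional[Dict[str, float]] = None,
    noise_dispersion: float = 0.25,
    seed: int = 0,
) -> ExpressionProfile:
    """Uncontaminated expression profile for one cell type.

    A shared log-normal baseline (meanlog 2, sdlog 1.2 on the TPM scale) is
    drawn once per seed, multiplied by the cell type's subsystem enrichment
    fold changes, given cell-type-specific log-normal noise of scale
    ``noise_dispersion``, marker-masked, and rescaled to a total of 10⁶.
    The same seed always yields the same profile for each cell type, so
    the epithelial/mesophyll pair of one seed is a coherent sample pair.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    transcripts = _transcript_universe(model, n_transcripts)
    baseline_rng = np.random.default_rng([seed, 0])
    baseline = baseline_rng.lognormal(mean=2.0, sigma=1.2, size=len(transcripts))
    noise_rng = np.random.default_rng([seed, 1 + CELL_TYPES.index(cell_type)])
    noise = noise_rng.lognormal(mean=0.0, sigma=noise_dispersion, size=len(transcripts))
    if enrichment is None:
        enrichment = (
            EPITHELIAL_ENRICHMENT if cell_type == "epithelial" else MESOPHYLL_ENRICHMENT
        )
    subsystems = _gene_subsystems(model)
    values = {}
    for i, transcript in enumerate(transcripts):
        fold = 1.0
        for sub in subsystems.get(transcript, []):
            fold = max(fold, enrichment.get(sub, 1.0))
        values[transcript] = float(baseline[i] * fold * noise[i])
    # markers are strictly cell-type exclusive before mixing
    own_marker = EPITHELIAL_MARKER if cell_type == "epithelial" else MESOPHYLL_MARKER
    other_marker = MESOPHYLL_MARKER if cell_type == "epithelial" else EPITHELIAL_MARKER
    if own_marker in values:
        values[own_marker] = float(
            _MARKER_BASELINE * noise[transcripts.index(own_marker)]
        )
    if other_marker in values:
        values[other_marker] = 0.0
    profile = ExpressionProfile(f"{cell_type}_pure_seed{seed}", values)
    return profile.normalized()


def simulate_expression(
    model: MetabolicModel, spec: ExpressionSimSpec
) -> ExpressionProfile:
    """Simulated TPM profile with controlled cross-contamination.

    The profile is the mixture (1−ρ)·own + ρ·other of the two pure
    cell-type profiles of the same seed, renormalized to total 10⁶, where
    ρ is ``spec.contamination_fraction`` — emulating the admixture of the
    neighboring cell type picked up during laser-capture microdissection.
    """
    own = pure_expression(
        model,
        spec.cell_type,
        n_transcripts=spec.n_transcripts,
        enrichment=spec.enrichment,
        noise_dispersion=spec.noise_dispersion,
        seed=spec.seed,
    )
    other_type = "mesophyll" if spec.cell_type == "epithelial" else "epithelial"
    other = pure_expression(
        model,
        other_type,
        n_transcripts=spec.n_transcripts,
        noise_dispersion=spec.noise_dispersion,
        seed=spec.seed,
    )
    rho = spec.contamination_fraction
    mixed = {
        t: (1.0 - rho) * own.tpm[t] + rho * other.tpm[t] for t in own.tpm
    }
    profile = ExpressionProfile(
        f"{spec.cell_type}_rho{rho:g}_seed{spec.seed}", mixed
    )
    return profile.normalized()
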