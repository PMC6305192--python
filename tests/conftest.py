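"""Shared fixtures: mini models, expression profiles, and toy networks."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest
from hypothesis import settings

from ductflux.core import Compartment, MetabolicModel, Metabolite, Reaction
from ductflux.expression import ExpressionProfile
from ductflux.mapping import DbSource, GeneReactionMap
from ductflux.synthetic import (
    ExpressionSimSpec,
    make_complete_map,
    make_mini_plant_model,
    simulate_expression,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epi_model() -> MetabolicModel:
    return make_mini_plant_model("epithelial")


@pytest.fixture(scope="session")
def meso_model() -> MetabolicModel:
    return make_mini_plant_model("mesophyll")


@pytest.fixture(scope="session")
def epi_map(epi_model) -> GeneReactionMap:
    return make_complete_map(epi_model)


@pytest.fixture(scope="session")
def meso_map(meso_model) -> GeneReactionMap:
    return make_complete_map(meso_model)


@pytest.fixture(scope="session")
def epi_expression(epi_model) -> ExpressionProfile:
    return simulate_expression(
        epi_model, ExpressionSimSpec(cell_type="epithelial", seed=1)
    )


@pytest.fixture(scope="session")
def meso_expression(meso_model) -> ExpressionProfile:
    return simulate_expression(
        meso_model, ExpressionSimSpec(cell_type="mesophyll", seed=1)
    )


def build_toy(
    reactions: List[Tuple],
    biomass_id: str,
    model_id: str = "toy",
) -> MetabolicModel:
    """Assemble a toy model from (id, stoich, lb, ub, is_exchange[, subsystem]).

    Metabolites are created on the fly in the cytosol.
    """
    met_ids = sorted({m for r in reactions for m in r[1]})
    metabolites = [Metabolite(m, compartment=Compartment.CYTOSOL) for m in met_ids]
    rxns = []
    for entry in reactions:
        rid, stoich, lb, ub, is_exchange = entry[:5]
        subsystem = entry[5] if len(entry) > 5 else ""
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=is_exchange,
                subsystem=subsystem,
            )
        )
    return MetabolicModel.from_lists(
        model_id, metabolites, rxns, biomass_reaction_id=biomass_id
    )


def uniform_profile(grmap: GeneReactionMap, tpm: float = 100.0) -> ExpressionProfile:
    transcripts = sorted(
        {t for rid in grmap.reactions() for t in grmap.transcripts_for(rid)}
    )
    return ExpressionProfile("uniform", {t: tpm for t in transcripts})


def chain_toy() -> MetabolicModel:
    """EX_A (uptake ≤10) → R1: A→B → EX_B; biomass is R1."""
    return build_toy(
        [
            ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
            ("EX_B", {"B": -1.0}, 0.0, 1000.0, True),
        ],
        biomass_id="R1",
    )
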