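"""FBA, FVA, expression-weighted minimization, and the titration.

The weighted-minimization results are cross-checked against an
independently assembled LP: instead of the forward/reverse flux split
used by the implementation, the oracle keeps the natural flux variables
and adds auxiliary magnitude variables t_i with t_i >= v_i and
t_i >= -v_i, solved by a different HiGHS algorithm (dual simplex).
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from ductflux.core import SolverStatus, stoichiometric_matrix
from ductflux.expression import ExpressionProfile
from ductflux.fluxsim import (
    EfminOptions,
    efmin,
    efmin_weights,
    fba,
    fva,
    has_alternative_optima,
    pfba,
    reaction_expression,
    subsystem_flux,
    titrate_photosynthesis,
)
from ductflux.mapping import DbSource, GeneReactionMap

from conftest import build_toy, chain_toy, uniform_profile


def brute_force_weighted_min(model, weights, biomass_target):
    """Oracle: min sum w|v| via magnitude variables and dual simplex."""
    S, _, rxn_ids = stoichiometric_matrix(model)
    m, n = S.shape
    # variables [v_1..v_n, t_1..t_n]
    A_eq = np.hstack([S, np.zeros((m, n))])
    b_eq = np.zeros(m)
    # t >= v  ->  v - t <= 0 ;  t >= -v  ->  -v - t <= 0
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),
            np.hstack([-np.eye(n), -np.eye(n)]),
        ]
    )
    b_ub = np.zeros(2 * n)
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        if rid == model.biomass_reaction_id:
            bounds.append((biomass_target, biomass_target))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    bounds += [(0.0, None)] * n
    c = np.concatenate([np.zeros(n), [weights[rid] for rid in rxn_ids]])
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs-ds",
    )
    assert res.status == 0, f"oracle LP failed with status {res.status}"
    return float(res.fun), {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}


def _grmap_for(reaction_ids):
    grmap = GeneReactionMap()
    for rid in reaction_ids:
        grmap.add(rid, f"T_{rid}", DbSource.ARABIDOPSIS_CORE, 90.0)
    return grmap


class TestFba:
    def test_uptake_bound_limits_chain(self):
        assert fba(chain_toy()).objective_value == pytest.approx(10.0, abs=1e-9)

    def test_intermediate_bottleneck_wins(self):
        model = chain_toy()
        model.reactions["R1"].upper_bound = 4.0
        assert fba(model).objective_value == pytest.approx(4.0, abs=1e-9)

    def test_steady_state_residual_small(self, epi_model):
        dist = fba(epi_model)
        S, mets, rxns = stoichiometric_matrix(epi_model)
        v = np.array([dist.fluxes[rid] for rid in rxns])
        assert np.max(np.abs(S @ v)) <= 1e-6

    def test_infeasible_reported_in_status(self):
        model = chain_toy()
        model.reactions["R1"].lower_bound = 20.0  # demands more than uptake
        model.reactions["R1"].upper_bound = 30.0
        assert fba(model).status is SolverStatus.INFEASIBLE


class TestFva:
    def test_blocked_reaction_is_zero_zero(self):
        model = chain_toy()
        # a reaction producing a metabolite nothing consumes
        from ductflux.core import Metabolite, Reaction, Compartment

        model.metabolites["X"] = Metabolite("X", compartment=Compartment.CYTOSOL)
        model.reactions["RX"] = Reaction(
            id="RX", stoichiometry={"A": -1.0, "X": 1.0}, upper_bound=1000.0
        )
        ranges = fva(model, biomass_fraction=0.0)
        assert ranges["RX"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_chain_reaction_fully_coupled_at_fraction_one(self):
        ranges = fva(chain_toy(), biomass_fraction=1.0)
        assert ranges["R1"] == pytest.approx((10.0, 10.0), abs=1e-6)

    def test_parallel_equivalent_branches_each_span_zero_to_optimum(self):
        model = build_toy(
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
                ("R2a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("R2b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("BIO", {"B": -1.0}, 0.0, 1000.0, False),
            ],
            biomass_id="BIO",
        )
        ranges = fva(model, biomass_fraction=1.0)
        assert ranges["R2a"] == pytest.approx((0.0, 10.0), abs=1e-6)
        assert ranges["R2b"] == pytest.approx((0.0, 10.0), abs=1e-6)
        assert ranges["BIO"] == pytest.approx((10.0, 10.0), abs=1e-6)


class TestWeights:
    def test_weight_function_caps_and_floors(self):
        expression = {"R1": 100.0, "R2": 50.0, "R3": 0.0, "R4": None}
        weights = efmin_weights(expression)
        assert weights["R1"] == pytest.approx(1e-4)  # at ceiling -> floored
        assert weights["R2"] == pytest.approx(0.5)
        assert weights["R3"] == pytest.approx(1.0)
        assert weights["R4"] == pytest.approx(1.0)

    def test_all_zero_expression_falls_back_to_uniform(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ductflux.fluxsim"):
            weights = efmin_weights({"R1": 0.0, "R2": None})
        assert weights == {"R1": 1.0, "R2": 1.0}
        assert any("uniform" in r.message for r in caplog.records)

    def test_aggregation_modes(self, epi_model, epi_map, epi_expression):
        for mode in ("sum", "max", "mean"):
            values = reaction_expression(epi_model, epi_expression, epi_map, mode)
            assert values["EX_photon"] is None  # no genes
            assert values["MEP"] is not None and values["MEP"] > 0
        sums = reaction_expression(epi_model, epi_expression, epi_map, "sum")
        maxes = reaction_expression(epi_model, epi_expression, epi_map, "max")
        assert sums["MEP"] >= maxes["MEP"]


class TestEfmin:
    def test_flux_routed_through_expressed_branch(self):
        model = build_toy(
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
                ("R2a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("R2b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("BIO", {"B": -1.0}, 0.0, 1000.0, False),
            ],
            biomass_id="BIO",
        )
        grmap = _grmap_for(["R2a", "BIO"])
        expr = ExpressionProfile("e", {"T_R2a": 1000.0, "T_BIO": 1000.0})
        dist = efmin(model, expr, grmap)
        assert dist.fluxes["R2a"] == pytest.approx(10.0, abs=1e-6)
        assert dist.fluxes["R2b"] == pytest.approx(0.0, abs=1e-6)

    def test_unique_chain_fluxes_and_objective(self):
        model = chain_toy()
        grmap = GeneReactionMap()
        expr = ExpressionProfile("e", {})
        dist = efmin(model, expr, grmap)  # no evidence -> uniform weights
        assert abs(dist.fluxes["EX_A"]) == pytest.approx(10.0, abs=1e-6)
        assert dist.fluxes["R1"] == pytest.approx(10.0, abs=1e-6)
        assert dist.fluxes["EX_B"] == pytest.approx(10.0, abs=1e-6)
        assert dist.objective_value == pytest.approx(30.0, abs=1e-5)

    def test_constraint_contract_on_mini_model(
        self, epi_model, epi_map, epi_expression
    ):
        dist = efmin(epi_model, epi_expression, epi_map)
        S, mets, rxns = stoichiometric_matrix(epi_model)
        v = np.array([dist.fluxes[rid] for rid in rxns])
        assert np.max(np.abs(S @ v)) <= 1e-6
        target = fba(epi_model).objective_value
        assert dist.fluxes["BIOMASS"] == pytest.approx(target, abs=1e-6)

    def test_biomass_fraction_scales_target(self, epi_model, epi_map, epi_expression):
        opts = EfminOptions(biomass_fraction=0.5)
        dist = efmin(epi_model, epi_expression, epi_map, opts)
        target = 0.5 * fba(epi_model).objective_value
        assert dist.fluxes["BIOMASS"] == pytest.approx(target, abs=1e-6)

    def test_pfba_is_uniform_special_case(self):
        model = chain_toy()
        dist = pfba(model)
        assert dist.objective_value == pytest.approx(30.0, abs=1e-5)

    @pytest.mark.parametrize("case", ["chain", "parallel", "reversible", "branched"])
    def test_objective_matches_brute_force_oracle(self, case):
        """Implementation vs independently formulated LP on small toys."""
        if case == "chain":
            model = chain_toy()
            grmap = _grmap_for(["R1"])
            expr = ExpressionProfile("e", {"T_R1": 400.0})
        elif case == "parallel":
            model = build_toy(
                [
                    ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
                    ("R2a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                    ("R2b", {"A": -1.0, "B": 1.0}, 0.0, 6.0, False),
                    ("BIO", {"B": -1.0}, 0.0, 1000.0, False),
                ],
                biomass_id="BIO",
            )
            grmap = _grmap_for(["R2a", "R2b"])
            expr = ExpressionProfile("e", {"T_R2a": 100.0, "T_R2b": 900.0})
        elif case == "reversible":
            model = build_toy(
                [
                    ("EX_A", {"A": -1.0}, -8.0, 0.0, True),
                    ("R1", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0, False),
                    ("R2", {"B": -1.0, "C": 1.0}, -1000.0, 1000.0, False),
                    ("BIO", {"C": -1.0}, 0.0, 1000.0, False),
                ],
                biomass_id="BIO",
            )
            grmap = _grmap_for(["R1", "R2"])
            expr = ExpressionProfile("e", {"T_R1": 300.0, "T_R2": 700.0})
        else:
            model = build_toy(
                [
                    ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
                    ("R1", {"A": -1.0, "B": 1.0, "C": 1.0}, 0.0, 1000.0, False),
                    ("R2", {"B": -1.0, "D": 1.0}, 0.0, 1000.0, False),
                    ("R3", {"C": -1.0, "D": 1.0}, 0.0, 1000.0, False),
                    ("EX_C", {"C": -1.0}, 0.0, 1000.0, True),
                    ("BIO", {"D": -1.0}, 0.0, 1000.0, False),
                ],
                biomass_id="BIO",
            )
            grmap = _grmap_for(["R2"])
            expr = ExpressionProfile("e", {"T_R2": 500.0})
        assert len(model.reactions) <= 8
        opts = EfminOptions()
        dist = efmin(model, expr, grmap, opts)
        expression = reaction_expression(model, expr, grmap)
        weights = efmin_weights(expression)
        target = fba(model).objective_value
        oracle_obj, _oracle_v = brute_force_weighted_min(model, weights, target)
        assert dist.objective_value == pytest.approx(oracle_obj, abs=1e-6)

    def test_degeneracy_probe_flags_symmetric_branches(self):
        model = build_toy(
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, True),
                ("R2a", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("R2b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0, False),
                ("BIO", {"B": -1.0}, 0.0, 1000.0, False),
            ],
            biomass_id="BIO",
        )
        grmap = GeneReactionMap()
        expr = ExpressionProfile("e", {})
        assert has_alternative_optima(model, expr, grmap)
        # unique-route chain is not degenerate
        assert not has_alternative_optima(
            chain_toy(), ExpressionProfile("e", {}), GeneReactionMap()
        )


class TestTitration:
    def test_dark_point_shuts_down_photochemistry(
        self, epi_model, epi_map, epi_expression
    ):
        result = titrate_photosynthesis(
            epi_model, epi_expression, epi_map, fractions=[0.0]
        )
        dist = result.distributions[0]
        assert dist.fluxes["LIGHT"] == pytest.approx(0.0, abs=1e-9)
        assert dist.fluxes["FNR_PS"] == pytest.approx(0.0, abs=1e-9)

    def test_oxphos_rises_when_light_falls(self, epi_model, epi_map, epi_expression):
        result = titrate_photosynthesis(
            epi_model, epi_expression, epi_map, fractions=[1.0, 0.0]
        )
        oxphos = result.subsystem_summaries["oxidative_phosphorylation"]
        assert oxphos[1] >= oxphos[0] - 1e-9

    def test_single_fraction_equals_efmin_on_pinned_scenario(
        self, epi_model, epi_map, epi_expression
    ):
        result = titrate_photosynthesis(
            epi_model, epi_expression, epi_map, fractions=[1.0]
        )
        pinned = epi_model.copy()
        pinned.reactions["EX_photon"].upper_bound = pinned.reactions[
            "EX_photon"
        ].lower_bound
        direct = efmin(pinned, epi_expression, epi_map)
        for rid, flux in direct.fluxes.items():
            assert result.distributions[0].fluxes[rid] == pytest.approx(
                flux, abs=1e-6
            )

    def test_missing_photon_annotation_is_an_error(self, epi_map, epi_expression):
        model = chain_toy()
        with pytest.raises(ValueError, match="photon"):
            titrate_photosynthesis(model, epi_expression, epi_map)


class TestSubsystemFlux:
    def test_all_zero_distribution_sums_to_zero(self, epi_model):
        from ductflux.core import FluxDistribution

        dist = FluxDistribution(
            epi_model.id,
            {rid: 0.0 for rid in epi_model.reactions},
            0.0,
            SolverStatus.OPTIMAL,
        )
        assert all(v == 0.0 for v in subsystem_flux(dist, epi_model).values())

    def test_absolute_values_and_exchange_exclusion(self):
        from ductflux.core import FluxDistribution

        model = build_toy(
            [
                ("EX_A", {"A": -1.0}, -10.0, 0.0, True, "boundary"),
                ("R1", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0, False, "s1"),
                ("R2", {"B": -1.0, "A": 1.0}, -1000.0, 1000.0, False, "s2"),
            ],
            biomass_id="R1",
        )
        dist = FluxDistribution(
            "toy", {"EX_A": -7.0, "R1": 5.0, "R2": -5.0}, 0.0, SolverStatus.OPTIMAL
        )
        sums = subsystem_flux(dist, model)
        assert sums == {"s1": 5.0, "s2": 5.0}

    def test_mini_model_totals_match_manual_summation(
        self, epi_model, epi_map, epi_expression
    ):
        dist = efmin(epi_model, epi_expression, epi_map)
        sums = subsystem_flux(dist, epi_model)
        manual = {}
        for rid, rxn in epi_model.reactions.items():
            if rxn.is_exchange or not rxn.subsystem:
                continue
            manual.setdefault(rxn.subsystem, 0.0)
            manual[rxn.subsystem] += abs(dist.fluxes[rid])
        assert sums == pytest.approx(manual)
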