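"""Linear-programming flux prediction: FBA, FVA, expression-weighted flux
minimization, and the photosynthesis titration.

All LPs are solved with the HiGHS solver behind ``scipy.optimize.linprog``.
Variable ordering is fixed (reaction ids sorted) and solver options are
pinned, so repeated runs on one platform give bit-stable answers.

The expression-weighted flux minimization predicts a flux distribution by
minimizing

    sum_i  w_i * |v_i|     with  w_i = max(1 - e_hat_i, w_min)

subject to steady state S·v = 0, the reaction bounds, and the biomass flux
held at (a fraction of) its FBA optimum.  ``e_hat_i`` is the reaction's
aggregated transcript abundance normalized to a ceiling (a percentile of
the positive reaction-expression values, by default the maximum), so
highly expressed reactions are cheap to use and silent reactions expensive.
Reactions with no transcript evidence get full weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple
import logging

import numpy as np
from scipy.optimize import linprog

from .core import (
    FluxDistribution,
    MetabolicModel,
    SolverStatus,
    stoichiometric_matrix,
)
from .expression import ExpressionProfile
from .mapping import GeneReactionMap

__all__ = [
    "EfminOptions",
    "pfba",
    "TitrationResult",
    "fba",
    "fva",
    "efmin",
    "reaction_expression",
    "efmin_weights",
    "titrate_photosynthesis",
    "subsystem_flux",
    "DEFAULT_TITRATION_FRACTIONS",
    "PHOTON_EXCHANGE_ANNOTATION",
]

logger = logging.getLogger(__name__)

_LINPROG_OPTS = {"presolve": True}
_STATUS_MAP = {
    0: SolverStatus.OPTIMAL,
    2: SolverStatus.INFEASIBLE,
    3: SolverStatus.UNBOUNDED,
}

DEFAULT_TITRATION_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.10, 0.0)
# Annotation key naming the photon exchange reaction of a model.
PHOTON_EXCHANGE_ANNOTATION = "photon_exchange_id"

W_MIN = 1e-4


@dataclass
class EfminOptions:
    """Tunables of the expression-weighted flux minimization.

    expression_aggregation
        How transcript TPMs map to a reaction-level value when several
        transcripts support one reaction: 'sum' (default), 'max' or 'mean'.
    normalization_cap
        Percentile (0, 100] of the positive reaction-expression values used
        as the e_hat = 1 ceiling.  100 = the maximum.
    biomass_fraction
        Fraction of the FBA biomass optimum the prediction must sustain.
    solver_tolerance
        Numerical tolerance used in feasibility checks of the result.
    """

    expression_aggregation: str = "sum"
    normalization_cap: float = 100.0
    biomass_fraction: float = 1.0
    solver_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if self.expression_aggregation not in ("sum", "max", "mean"):
            raise ValueError(
                f"unknown aggregation {self.expression_aggregation!r}"
            )
        if not 0.0 < self.normalization_cap <= 100.0:
            raise ValueError("normalization_cap must be in (0, 100]")
        if not 0.0 < self.biomass_fraction <= 1.0:
            raise ValueError("biomass_fraction must be in (0, 1]")


@dataclass
class TitrationResult:
    """Flux predictions across a ladder of photosynthetic-activity levels."""

    fractions: List[float]
    distributions: List[FluxDistribution]
    subsystem_summaries: Dict[str, List[float]]


def _solve(c, A_eq, b_eq, bounds):
    return linprog(
        c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs", options=_LINPROG_OPTS
    )


def _status(res) -> SolverStatus:
    return _STATUS_MAP.get(res.status, SolverStatus.INFEASIBLE)


def fba(model: MetabolicModel, objective_id: Optional[str] = None) -> FluxDistribution:
    """Flux balance analysis: maximize the objective flux.

    Maximizes the biomass reaction (or ``objective_id``) subject to
    S·v = 0 and the reaction bounds.  Infeasibility and unboundedness are
    reported in the status field, not raised.
    """
    objective_id = objective_id or model.biomass_reaction_id
    if objective_id not in model.reactions:
        raise ValueError(f"objective reaction {objective_id!r} not in model")
    S, met_ids, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective_id)] = -1.0
    bounds = [
        (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in rxn_ids
    ]
    res = _solve(c, S, np.zeros(S.shape[0]), bounds)
    status = _status(res)
    if status is not SolverStatus.OPTIMAL:
        return FluxDistribution(model.id, {}, float("nan"), status)
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}
    return FluxDistribution(model.id, fluxes, float(-res.fun), status)


def flux_range(
    model: MetabolicModel,
    reaction_id: str,
    fixed: Optional[Dict[str, float]] = None,
    minimum_fluxes: Optional[Dict[str, float]] = None,
) -> Tuple[float, float]:
    """Min and max attainable flux of one reaction under steady state.

    ``fixed`` pins reactions to exact fluxes; ``minimum_fluxes`` imposes
    per-reaction lower bounds (used for the biomass constraint in FVA).
    """
    S, _, rxn_ids = stoichiometric_matrix(model)
    n = len(rxn_ids)
    bounds = []
    for rid in rxn_ids:
        lb = model.reactions[rid].lower_bound
        ub = model.reactions[rid].upper_bound
        if fixed and rid in fixed:
            lb = ub = fixed[rid]
        if minimum_fluxes and rid in minimum_fluxes:
            lb = max(lb, minimum_fluxes[rid])
        bounds.append((lb, ub))
    j = rxn_ids.index(reaction_id)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[j] = sign
        res = _solve(c, S, np.zeros(S.shape[0]), bounds)
        if res.status != 0:
            raise RuntimeError(
                f"FVA subproblem for {reaction_id} ended with status {res.status}"
            )
        out.append(float(sign * res.fun))
    vmin, vmax = out
    return min(vmin, vmax), max(vmin, vmax)


def fva(
    model: MetabolicModel,
    biomass_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Flux variability analysis at a given biomass fraction.

    Per reaction, the minimum and maximum flux subject to steady state,
    bounds, and biomass ≥ ``biomass_fraction`` × the FBA optimum.
    """
    base = fba(model)
    if base.status is not SolverStatus.OPTIMAL:
        raise RuntimeError(f"FBA not optimal (status {base.status.value})")
    target = biomass_fraction * base.objective_value
    minimum = {model.biomass_reaction_id: target}
    out: Dict[str, Tuple[float, float]] = {}
    for rid in sorted(reactions if reactions is not None else model.reactions):
        out[rid] = flux_range(model, rid, minimum_fluxes=minimum)
    return out


def reaction_expression(
    model: MetabolicModel,
    expr: ExpressionProfile,
    grmap: GeneReactionMap,
    aggregation: str = "sum",
) -> Dict[str, Optional[float]]:
    """Aggregate transcript TPM to a per-reaction expression value.

    Reactions without mapped transcripts get ``None`` (distinct from an
    expressed-at-zero reaction).
    """
    out: Dict[str, Optional[float]] = {}
    for rid in sorted(model.reactions):
        transcripts = sorted(grmap.transcripts_for(rid))
        if not transcripts:
            out[rid] = None
            continue
        values = [expr.get(t, 0.0) for t in transcripts]
        if aggregation == "sum":
            out[rid] = float(sum(values))
        elif aggregation == "max":
            out[rid] = float(max(values))
        else:
            out[rid] = float(sum(values) / len(values))
    return out


def efmin_weights(
    expression: Dict[str, Optional[float]], normalization_cap: float = 100.0
) -> Dict[str, float]:
    """Turn reaction expression into minimization weights w = 1 − ê.

    ê is expression normalized to the ``normalization_cap`` percentile of
    the positive values and capped at 1; weights are floored at 1e-4 so no
    reaction is ever free.  Unmapped reactions weigh 1.  If every mapped
    value is zero, weights fall back to uniform 1 (plain parsimonious
    minimization) with a logged warning.
    """
    positive = [v for v in expression.values() if v is not None and v > 0.0]
    if not positive:
        logger.warning(
            "all reaction expression values are zero; falling back to uniform weights"
        )
        return {rid: 1.0 for rid in expression}
    ceiling = float(np.percentile(positive, normalization_cap))
    if ceiling <= 0.0:
        ceiling = max(positive)
    weights: Dict[str, float] = {}
    for rid, e in expression.items():
        if e is None:
            weights[rid] = 1.0
        else:
            e_hat = min(e / ceiling, 1.0)
            weights[rid] = max(1.0 - e_hat, W_MIN)
    return weights


def _weighted_min_flux(
    model: MetabolicModel,
    weights: Dict[str, float],
    biomass_target: float,
    tolerance: float,
) -> FluxDistribution:
    """Minimize sum_i w_i |v_i| at a fixed biomass flux.

    Each flux is split into nonnegative forward and reverse parts so the
    absolute value is linear.
    """
    S, _, rxn_ids = stoichiometric_matrix(model)
    m, n = S.shape
    # variables: [f_1..f_n, r_1..r_n], v = f - r
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rid == model.biomass_reaction_id:
            lb = ub = biomass_target
        bounds.append((max(lb, 0.0), max(ub, 0.0)))
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if rid == model.biomass_reaction_id:
            lb = ub = biomass_target
        bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    c = np.array([weights[rid] for rid in rxn_ids] * 2)
    res = _solve(c, A_eq, b_eq, bounds)
    status = _status(res)
    if status is not SolverStatus.OPTIMAL:
        return FluxDistribution(model.id, {}, float("nan"), status)
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for j, rid in enumerate(rxn_ids)}
    residual = float(np.max(np.abs(S @ v))) if n else 0.0
    if residual > 1e-6:
        raise RuntimeError(f"steady-state residual {residual:.3e} exceeds 1e-6")
    return FluxDistribution(model.id, fluxes, float(res.fun), status)


def pfba(model: MetabolicModel, biomass_fraction: float = 1.0) -> FluxDistribution:
    """Parsimonious flux prediction: minimize total |flux| at the optimum.

    The uniform-weight special case of the expression-weighted
    minimization.  Its solution never carries closed-cycle flux (a cycle
    only adds to the objective), which makes it the reference for loop
    resolution.
    """
    base = fba(model)
    if base.status is not SolverStatus.OPTIMAL:
        return base
    target = biomass_fraction * base.objective_value
    weights = {rid: 1.0 for rid in model.reactions}
    return _weighted_min_flux(model, weights, target, 1e-9)


def efmin(
    model: MetabolicModel,
    expr: ExpressionProfile,
    grmap: GeneReactionMap,
    opts: Optional[EfminOptions] = None,
    biomass_target: Optional[float] = None,
) -> FluxDistribution:
    """Expression-weighted flux minimization.

    Runs FBA first to find the biomass optimum, then minimizes the
    expression-weighted sum of absolute fluxes with biomass pinned at
    ``opts.biomass_fraction`` of that optimum — or at the absolute
    ``biomass_target`` when one is given (it must not exceed the optimum).
    The returned ``objective_value`` is the weighted flux sum (not the
    biomass flux).
    """
    opts = opts or EfminOptions()
    base = fba(model)
    if base.status is not SolverStatus.OPTIMAL or base.objective_value <= 0.0:
        raise RuntimeError(
            f"FBA must be optimal with positive biomass before weighted "
            f"minimization (status {base.status.value}, "
            f"optimum {base.objective_value!r})"
        )
    if biomass_target is None:
        target = opts.biomass_fraction * base.objective_value
    else:
        if biomass_target > base.objective_value + 1e-9:
            raise ValueError(
                f"biomass target {biomass_target} exceeds the FBA optimum "
                f"{base.objective_value}"
            )
        target = biomass_target
    expression = reaction_expression(model, expr, grmap, opts.expression_aggregation)
    weights = efmin_weights(expression, opts.normalization_cap)
    return _weighted_min_flux(model, weights, target, opts.solver_tolerance)


def has_alternative_optima(
    model: MetabolicModel,
    expr: ExpressionProfile,
    grmap: GeneReactionMap,
    opts: Optional[EfminOptions] = None,
    perturbation: float = 1e-7,
    flux_tolerance: float = 1e-5,
) -> bool:
    """Probe degeneracy of the weighted-minimization flux vector.

    Re-solves twice with weights perturbed by tiny deterministic
    tie-breaking terms of opposite orientation (proportional to the
    reaction's rank in sorted id order, ascending vs descending) and
    reports whether any individual flux differs between the two by more
    than ``flux_tolerance``.  When this returns True only the objective
    value of a prediction is meaningful, not single fluxes.
    """
    opts = opts or EfminOptions()
    base = fba(model)
    expression = reaction_expression(model, expr, grmap, opts.expression_aggregation)
    weights = efmin_weights(expression, opts.normalization_cap)
    target = opts.biomass_fraction * base.objective_value
    n = len(weights)
    ascending = {
        rid: w * (1.0 + perturbation * (k + 1))
        for k, (rid, w) in enumerate(sorted(weights.items()))
    }
    descending = {
        rid: w * (1.0 + perturbation * (n - k))
        for k, (rid, w) in enumerate(sorted(weights.items()))
    }
    lo = _weighted_min_flux(model, ascending, target, opts.solver_tolerance)
    hi = _weighted_min_flux(model, descending, target, opts.solver_tolerance)
    return any(
        abs(lo.fluxes[rid] - hi.fluxes[rid]) > flux_tolerance for rid in lo.fluxes
    )


def titrate_photosynthesis(
    model: MetabolicModel,
    expr: ExpressionProfile,
    grmap: GeneReactionMap,
    fractions: Sequence[float] = DEFAULT_TITRATION_FRACTIONS,
    opts: Optional[EfminOptions] = None,
) -> TitrationResult:
    """Predict fluxes across a ladder of photosynthetic-activity levels.

    For each fraction f the photon uptake is fixed at f times its
    reference capacity and the expression-weighted minimization re-run:
    incident light is absorbed, not optional, and any absorbed photons the
    network cannot use productively must exit through a quenching valve if
    the model provides one.  The model must designate its photon exchange
    reaction in ``annotations['photon_exchange_id']``; uptake is negative
    flux on the exchange, so the reference capacity is its lower bound.

    All points of the ladder share one biomass demand — the smallest FBA
    optimum over the fractions, scaled by ``opts.biomass_fraction`` — so
    the titration isolates how the network re-routes a fixed end-product
    output as the photon supply shrinks.  With per-scenario optima the
    demand itself would co-vary with light and confound the comparison.
    """
    photon_id = model.annotations.get(PHOTON_EXCHANGE_ANNOTATION, "")
    if photon_id not in model.reactions:
        raise ValueError(
            "model does not designate a photon exchange reaction "
            f"(annotation {PHOTON_EXCHANGE_ANNOTATION!r})"
        )
    reference_uptake = -model.reactions[photon_id].lower_bound
    if reference_uptake <= 0.0:
        raise ValueError(
            f"photon exchange {photon_id} has no uptake capacity to titrate"
        )
    opts = opts or EfminOptions()
    scenarios = []
    optima = []
    for f in fractions:
        scenario = model.copy()
        scenario.reactions[photon_id].lower_bound = -f * reference_uptake
        scenario.reactions[photon_id].upper_bound = -f * reference_uptake
        base = fba(scenario)
        if base.status is not SolverStatus.OPTIMAL or base.objective_value <= 0.0:
            raise RuntimeError(
                f"biomass infeasible at photosynthetic fraction {f:g} "
                f"(status {base.status.value})"
            )
        scenarios.append(scenario)
        optima.append(base.objective_value)
    shared_target = opts.biomass_fraction * min(optima)
    distributions: List[FluxDistribution] = [
        efmin(scenario, expr, grmap, opts, biomass_target=shared_target)
        for scenario in scenarios
    ]
    subsystems = sorted(
        {r.subsystem for r in model.reactions.values() if r.subsystem}
    )
    summaries = {
        sub: [subsystem_flux(d, model).get(sub, 0.0) for d in distributions]
        for sub in subsystems
    }
    return TitrationResult(list(fractions), distributions, summaries)


def subsystem_flux(
    dist: FluxDistribution, model: MetabolicModel
) -> Dict[str, float]:
    """Sum of absolute fluxes per subsystem, exchange reactions excluded."""
    out: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange or not rxn.subsystem:
            continue
        out[rxn.subsystem] = out.get(rxn.subsystem, 0.0) + abs(
            dist.fluxes.get(rid, 0.0)
        )
    return out
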