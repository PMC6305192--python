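"""Transform a reference reaction set plus transcript evidence into a
cell-type-specific, compartmentalized, loop-free, fully connected model.

The stages, in pipeline order:

1. :func:`associate_transcripts` — turn sequence-similarity hits into a
   gene-reaction map, keeping for each transcript only its best-identity
   hits from the highest-priority reference database.
2. :func:`apply_localization` — move reactions into the compartment their
   enzymes are predicted to occupy (majority vote over transcripts).
3. :func:`prune_unexpressed` — drop reactions with no transcript support
   (boundary, biomass and transport reactions are protected by default).
4. :func:`remove_nonfunctional` — drop dead ends and reactions that can
   carry no flux in any feasible steady state (flux-variability test).
5. :func:`detect_infeasible_loops` / :func:`resolve_loops` — find internal
   cycles able to carry flux with every exchange closed, and break them by
   tightening reversibility (or removal) without sacrificing biomass.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import (
    Compartment,
    MetabolicModel,
    Metabolite,
    SolverStatus,
    stoichiometric_matrix,
)
from .fluxsim import fba, pfba
from .mapping import DB_PRIORITY, GeneReactionMap, HitRecord, LocalizationRecord

__all__ = [
    "associate_transcripts",
    "prune_unexpressed",
    "remove_nonfunctional",
    "detect_infeasible_loops",
    "resolve_loops",
    "apply_localization",
    "default_protected_ids",
    "reconstruct_model",
    "DisconnectedObjectiveError",
    "IrreducibleLoopError",
]

LOOP_TOL = 1e-6
BLOCKED_TOL = 1e-9
# Window (percentage points of global identity) within which a transcript's
# co-best hits are all kept, so one transcript may support a multifunctional
# enzyme's several reactions.
COBEST_WINDOW = 1.0
DEFAULT_IDENTITY_THRESHOLD = 40.0


class DisconnectedObjectiveError(ValueError):
    pass


class IrreducibleLoopError(RuntimeError):
    def __init__(self, loop_ids: Set[str]):
        self.loop_ids = set(loop_ids)
        super().__init__(
            f"cannot break loops while keeping biomass feasible: {sorted(loop_ids)}"
        )


def associate_transcripts(
    hits: Iterable[HitRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> GeneReactionMap:
    """Build a gene-reaction map from sequence-similarity hits.

    Hits below ``identity_threshold`` percent global identity are
    discarded.  For each transcript, only hits from its highest-priority
    database with a surviving hit are considered (Arabidopsis core model >
    AraCyc > MetaCyc), and of those every target within 1 percentage point
    of the transcript's best hit is kept.  The result groups transcripts
    by target reaction.
    """
    if not 0.0 < identity_threshold <= 100.0:
        raise ValueError("identity_threshold must be in (0, 100]")
    by_transcript: Dict[str, List[HitRecord]] = {}
    for hit in hits:
        if hit.db_source not in DB_PRIORITY:
            raise ValueError(f"malformed db_source {hit.db_source!r}")
        if hit.global_identity >= identity_threshold:
            by_transcript.setdefault(hit.transcript_id, []).append(hit)
    grmap = GeneReactionMap()
    for transcript in sorted(by_transcript):
        surviving = by_transcript[transcript]
        best_db = min(DB_PRIORITY[h.db_source] for h in surviving)
        in_db = [h for h in surviving if DB_PRIORITY[h.db_source] == best_db]
        best_identity = max(h.global_identity for h in in_db)
        for hit in in_db:
            if hit.global_identity >= best_identity - COBEST_WINDOW:
                grmap.add(hit.target_id, transcript, hit.db_source, hit.global_identity)
    return grmap


def default_protected_ids(model: MetabolicModel) -> Set[str]:
    """Reactions protected from expression pruning by default.

    Biomass, every boundary (exchange/sink) reaction, and every transport
    reaction (touching more than one compartment): transporters are
    chronically under-annotated in transcript evidence.
    """
    protected = {model.biomass_reaction_id} if model.biomass_reaction_id else set()
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            protected.add(rxn.id)
            continue
        comps = {
            model.metabolites[mid].compartment for mid in rxn.stoichiometry
        }
        if len(comps) > 1:
            protected.add(rxn.id)
    return protected


def prune_unexpressed(
    model: MetabolicModel,
    grmap: GeneReactionMap,
    protected_ids: Optional[Set[str]] = None,
) -> MetabolicModel:
    """Remove reactions with no associated transcripts.

    Keeps exactly the reactions with ≥1 mapped transcript plus everything
    in ``protected_ids`` (defaults to :func:`default_protected_ids`);
    metabolites no longer referenced are dropped.
    """
    if protected_ids is None:
        protected_ids = default_protected_ids(model)
    unknown = protected_ids - set(model.reactions)
    if unknown:
        raise ValueError(f"protected ids not in model: {sorted(unknown)}")
    if (
        model.biomass_reaction_id
        and model.biomass_reaction_id not in protected_ids
        and model.biomass_reaction_id not in grmap
    ):
        raise DisconnectedObjectiveError(
            "biomass reaction has no transcript support and is not protected"
        )
    kept = [
        r.copy()
        for rid, r in sorted(model.reactions.items())
        if rid in protected_ids or rid in grmap
    ]
    used_mets = {mid for r in kept for mid in r.stoichiometry}
    return MetabolicModel.from_lists(
        model.id,
        [model.metabolites[mid] for mid in sorted(used_mets)],
        kept,
        biomass_reaction_id=model.biomass_reaction_id,
        annotations=dict(model.annotations),
    )


def _variability(
    model: MetabolicModel,
    reaction_ids: Optional[Iterable[str]] = None,
    close_exchanges: bool = False,
) -> Dict[str, Tuple[float, float]]:
    """Min/max steady-state flux per reaction, sharing one matrix build."""
    S, _, rxn_ids = stoichiometric_matrix(model)
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        if close_exchanges and rxn.is_exchange:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    b_eq = np.zeros(S.shape[0])
    targets = sorted(reaction_ids) if reaction_ids is not None else rxn_ids
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        vals = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(rxn_ids))
            c[j] = sign
            res = linprog(
                c, A_eq=S, b_eq=b_eq, bounds=bounds, method="highs",
                options={"presolve": True},
            )
            if res.status != 0:
                raise RuntimeError(
                    f"variability subproblem for {rid} failed (status {res.status})"
                )
            vals.append(float(sign * res.fun))
        out[rid] = (min(vals), max(vals))
    return out


def _dead_end_reactions(model: MetabolicModel) -> Set[str]:
    """Reactions touching a metabolite with no producer or no consumer."""
    producers: Dict[str, int] = {mid: 0 for mid in model.metabolites}
    consumers: Dict[str, int] = {mid: 0 for mid in model.metabolites}
    for rxn in model.reactions.values():
        for mid, coeff in rxn.stoichiometry.items():
            forward_open = rxn.upper_bound > 0
            reverse_open = rxn.lower_bound < 0
            if rxn.is_exchange:
                # a boundary reaction supplies/consumes from outside
                if (coeff > 0 and forward_open) or (coeff < 0 and reverse_open):
                    producers[mid] += 1
                if (coeff < 0 and forward_open) or (coeff > 0 and reverse_open):
                    consumers[mid] += 1
                continue
            if (coeff > 0 and forward_open) or (coeff < 0 and reverse_open):
                producers[mid] += 1
            if (coeff < 0 and forward_open) or (coeff > 0 and reverse_open):
                consumers[mid] += 1
    dead_mets = {
        mid for mid in model.metabolites if producers[mid] == 0 or consumers[mid] == 0
    }
    return {
        rxn.id
        for rxn in model.reactions.values()
        if any(mid in dead_mets for mid in rxn.stoichiometry)
    }


def _drop_reactions(model: MetabolicModel, drop: Set[str]) -> MetabolicModel:
    kept = [r.copy() for rid, r in sorted(model.reactions.items()) if rid not in drop]
    used = {mid for r in kept for mid in r.stoichiometry}
    return MetabolicModel.from_lists(
        model.id,
        [model.metabolites[mid] for mid in sorted(used)],
        kept,
        biomass_reaction_id=model.biomass_reaction_id,
        annotations=dict(model.annotations),
    )


def remove_nonfunctional(model: MetabolicModel) -> MetabolicModel:
    """Remove reactions that can carry no flux in any feasible state.

    Iterates to a fixed point: first topological dead ends (metabolites
    that are produced-only or consumed-only), then stoichiometrically
    blocked reactions found by flux variability with the biomass
    constraint relaxed to ≥ 0.  Raises if the biomass reaction itself
    would have to go.
    """
    current = model
    while True:
        removed_any = False
        # dead-end sweep to its own fixed point (cheap)
        while True:
            dead = _dead_end_reactions(current)
            if not dead:
                break
            if current.biomass_reaction_id in dead:
                raise DisconnectedObjectiveError(
                    "disconnected objective: biomass reaction is a dead end"
                )
            current = _drop_reactions(current, dead)
            removed_any = True
        ranges = _variability(current)
        blocked = {
            rid
            for rid, (lo, hi) in ranges.items()
            if abs(lo) < BLOCKED_TOL and abs(hi) < BLOCKED_TOL
        }
        if current.biomass_reaction_id in blocked:
            raise DisconnectedObjectiveError(
                "disconnected objective: biomass reaction is blocked"
            )
        if blocked:
            current = _drop_reactions(current, blocked)
            removed_any = True
        if not removed_any:
            return current


def detect_infeasible_loops(model: MetabolicModel) -> Set[str]:
    """Internal reactions able to carry flux with all exchanges closed.

    With every boundary reaction pinned to zero, any remaining nonzero
    steady-state flux must run in a closed cycle, which violates energy
    balance (a thermodynamically infeasible loop).  Returns every internal
    reaction whose maximum attainable |flux| exceeds 1e-6.
    """
    internal = [rid for rid, r in model.reactions.items() if not r.is_exchange]
    ranges = _variability(model, internal, close_exchanges=True)
    return {
        rid
        for rid, (lo, hi) in ranges.items()
        if max(abs(lo), abs(hi)) > LOOP_TOL
    }


def _closed_range(model: MetabolicModel, rid: str) -> Tuple[float, float]:
    return _variability(model, [rid], close_exchanges=True)[rid]


def resolve_loops(
    model: MetabolicModel,
    loop_ids: Set[str],
    policy: str = "tighten_reversibility",
) -> MetabolicModel:
    """Break closed-system cycles while preserving biomass feasibility.

    ``tighten_reversibility`` (default) walks the loop reactions in sorted
    id order and closes, for each reversible one, the direction in which
    it can cycle — reverting any change that lowers the biomass optimum by
    more than 1e-6.  ``remove`` deletes loop reactions outright under the
    same guard.  Raises :class:`IrreducibleLoopError` if loops survive.
    """
    if policy not in ("tighten_reversibility", "remove"):
        raise ValueError(f"unknown policy {policy!r}")
    reference = fba(model)
    if reference.status is not SolverStatus.OPTIMAL:
        raise RuntimeError("model must be FBA-solvable before loop resolution")
    # direction choices come from a parsimonious solution: a plain FBA
    # vertex may itself ride the loop, making its flux signs meaningless
    parsimonious = pfba(model)
    current = model.copy()
    for rid in sorted(loop_ids):
        if rid not in current.reactions:
            continue
        lo, hi = _closed_range(current, rid)
        if max(abs(lo), abs(hi)) <= LOOP_TOL:
            continue  # earlier edits already broke this cycle
        if policy == "remove":
            candidate = _drop_reactions(current, {rid})
            if rid == current.biomass_reaction_id:
                continue
            trial = fba(candidate)
            if (
                trial.status is SolverStatus.OPTIMAL
                and trial.objective_value >= reference.objective_value - LOOP_TOL
            ):
                current = candidate
            continue
        rxn = current.reactions[rid]
        if not rxn.reversible:
            continue  # tightening cannot change an irreversible reaction
        # candidate closures: prefer closing the direction opposite to the
        # reaction's parsimonious flux, so the productive direction survives
        reference_flux = parsimonious.fluxes.get(rid, 0.0)
        if reference_flux >= -LOOP_TOL:
            preference = ["reverse", "forward"]
        else:
            preference = ["forward", "reverse"]
        # only directions in which the reaction can actually cycle are
        # worth closing; anything else leaves the loop intact
        closures = [
            d
            for d in preference
            if (d == "forward" and hi > LOOP_TOL)
            or (d == "reverse" and lo < -LOOP_TOL)
        ]
        for direction in closures:
            old_lb, old_ub = rxn.lower_bound, rxn.upper_bound
            if direction == "forward":
                rxn.upper_bound = 0.0
            else:
                rxn.lower_bound = 0.0
            trial = fba(current)
            if (
                trial.status is SolverStatus.OPTIMAL
                and trial.objective_value >= reference.objective_value - LOOP_TOL
            ):
                break
            rxn.lower_bound, rxn.upper_bound = old_lb, old_ub
    remaining = detect_infeasible_loops(current)
    if remaining:
        raise IrreducibleLoopError(remaining)
    return current


_COMP_SUFFIX = {
    Compartment.CYTOSOL: "c",
    Compartment.PLASTID: "p",
    Compartment.MITOCHONDRION: "m",
    Compartment.PEROXISOME: "x",
    Compartment.EXTRACELLULAR: "e",
}
_SUFFIXES = set(_COMP_SUFFIX.values())
# deterministic tie-break order for localization votes
_COMP_ORDER = [
    Compartment.CYTOSOL,
    Compartment.PLASTID,
    Compartment.MITOCHONDRION,
    Compartment.PEROXISOME,
]


def _relocate_id(met_id: str, compartment: Compartment) -> str:
    base, sep, suffix = met_id.rpartition("_")
    if sep and suffix in _SUFFIXES:
        return f"{base}_{_COMP_SUFFIX[compartment]}"
    return f"{met_id}_{_COMP_SUFFIX[compartment]}"


def apply_localization(
    model: MetabolicModel,
    records: Iterable[LocalizationRecord],
    grmap: GeneReactionMap,
) -> MetabolicModel:
    """Assign each mapped reaction to its predicted compartment.

    For every internal reaction whose mapped transcripts carry
    localization predictions, the majority compartment wins (ties broken
    by highest mean score, then by cytosol < plastid < mitochondrion <
    peroxisome), and the reaction's non-extracellular metabolites are
    rewritten into that compartment.  Reactions without predictions keep
    the reference compartments.
    """
    by_transcript: Dict[str, List[LocalizationRecord]] = {}
    for rec in records:
        by_transcript.setdefault(rec.transcript_id, []).append(rec)
    out = model.copy()
    new_metabolites: Dict[str, Metabolite] = dict(out.metabolites)
    for rid in sorted(out.reactions):
        rxn = out.reactions[rid]
        if rxn.is_exchange:
            continue
        votes: Dict[Compartment, List[float]] = {}
        for transcript in grmap.transcripts_for(rid):
            for rec in by_transcript.get(transcript, []):
                if rec.compartment is Compartment.EXTRACELLULAR:
                    continue
                votes.setdefault(rec.compartment, []).append(rec.score)
        if not votes:
            continue
        best = max(
            votes,
            key=lambda comp: (
                len(votes[comp]),
                sum(votes[comp]) / len(votes[comp]),
                -_COMP_ORDER.index(comp),
            ),
        )
        new_stoich: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            met = out.metabolites[mid]
            if met.compartment in (Compartment.EXTRACELLULAR, best):
                new_stoich[mid] = new_stoich.get(mid, 0.0) + coeff
                continue
            new_id = _relocate_id(mid, best)
            if new_id not in new_metabolites:
                new_metabolites[new_id] = Metabolite(
                    id=new_id,
                    name=met.name,
                    compartment=best,
                    formula=met.formula,
                    charge=met.charge,
                )
            new_stoich[new_id] = new_stoich.get(new_id, 0.0) + coeff
        rxn.stoichiometry = {m: c for m, c in new_stoich.items() if c != 0.0}
    used = {mid for r in out.reactions.values() for mid in r.stoichiometry}
    return MetabolicModel.from_lists(
        out.id,
        [new_metabolites[mid] for mid in sorted(used)],
        [out.reactions[rid].copy() for rid in sorted(out.reactions)],
        biomass_reaction_id=out.biomass_reaction_id,
        annotations=dict(out.annotations),
    )


def reconstruct_model(
    model: MetabolicModel,
    hits: Iterable[HitRecord],
    localization: Iterable[LocalizationRecord] = (),
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    protected_ids: Optional[Set[str]] = None,
    loop_policy: str = "tighten_reversibility",
) -> Tuple[MetabolicModel, GeneReactionMap, Dict[str, object]]:
    """Run the full reconstruction pipeline; returns (model, map, provenance).

    The provenance dict records per-stage reaction counts and every
    reaction removed, with the removing stage, so a reconstruction can be
    audited or re-run bit-identically.
    """
    provenance: Dict[str, object] = {
        "identity_threshold": identity_threshold,
        "loop_policy": loop_policy,
        "stages": [],
    }

    def _log(stage: str, before: MetabolicModel, after: MetabolicModel) -> None:
        removed = sorted(set(before.reactions) - set(after.reactions))
        provenance["stages"].append(
            {
                "stage": stage,
                "reactions_before": len(before.reactions),
                "reactions_after": len(after.reactions),
                "removed": removed,
            }
        )

    grmap = associate_transcripts(hits, identity_threshold)
    localized = apply_localization(model, localization, grmap)
    _log("apply_localization", model, localized)
    pruned = prune_unexpressed(localized, grmap, protected_ids)
    _log("prune_unexpressed", localized, pruned)
    functional = remove_nonfunctional(pruned)
    _log("remove_nonfunctional", pruned, functional)
    loops = detect_infeasible_loops(functional)
    provenance["loops_detected"] = sorted(loops)
    resolved = resolve_loops(functional, loops, loop_policy) if loops else functional
    _log("resolve_loops", functional, resolved)
    return resolved, grmap, provenance
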