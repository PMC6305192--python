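"""End-to-end orchestration: contamination estimation → reconstruction →
biomass build → flux prediction → summaries, with a reproducibility
manifest.

The pipeline runs either on user-supplied inputs (tabular model, hit
table, localization table, expression TSVs) or, in demo mode, on the
synthetic study system generated from a single seed.  Every run writes a
manifest with SHA-256 hashes of all inputs and outputs plus the full
option set, sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

from . import __version__
from .contamination import estimate_contamination
from .core import MetabolicModel
from .expression import ExpressionProfile, read_expression_tsv, write_expression_tsv
from .fluxsim import (
    DEFAULT_TITRATION_FRACTIONS,
    EfminOptions,
    efmin,
    subsystem_flux,
    titrate_photosynthesis,
)
from .io import read_model_tabular, write_model_tabular
from .mapping import (
    GeneReactionMap,
    read_hits_tsv,
    read_localization_tsv,
    write_gene_reaction_map_tsv,
)
from .reconstruction import reconstruct_model
from .synthetic import (
    EPITHELIAL_MARKER,
    MESOPHYLL_MARKER,
    ExpressionSimSpec,
    make_biomass_table,
    make_hit_records,
    make_localization_records,
    make_mini_plant_model,
    simulate_expression,
)
from .biomass import write_composition_tsv

__all__ = ["PipelineConfig", "run_pipeline", "write_flux_tsv"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Paths left as None are filled by synthetic generation (demo mode).
    Every default that stands in for an unmeasured quantity (identity
    threshold, weighting options, titration ladder) is explicit here so
    each run records exactly what was assumed.
    """

    output_dir: str = "run"
    seed: int = 0
    # inputs; None = generate synthetically
    model_dir: Optional[str] = None
    epithelial_expression: Optional[str] = None
    mesophyll_expression: Optional[str] = None
    hits: Optional[str] = None
    localization: Optional[str] = None
    # synthetic-generation conditions
    n_transcripts: int = 500
    contamination_fraction: float = 0.1
    noise_dispersion: float = 0.25
    # reconstruction / flux options
    identity_threshold: float = 40.0
    loop_policy: str = "tighten_reversibility"
    efmin: EfminOptions = field(default_factory=EfminOptions)
    titration_fractions: Sequence[float] = DEFAULT_TITRATION_FRACTIONS

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        efmin_opts = EfminOptions(**raw.pop("efmin", {}))
        return cls(efmin=efmin_opts, **raw)

    def to_dict(self) -> Dict[str, object]:
        out = dataclasses.asdict(self)
        out["titration_fractions"] = list(self.titration_fractions)
        return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_flux_tsv(fluxes: Dict[str, float], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid in sorted(fluxes):
            fh.write(f"{rid}\t{fluxes[rid]:.10g}\n")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full workflow; returns (and writes) the run manifest.

    Stages: input generation/loading, marker-based contamination
    estimation in both directions, per-cell-type reconstruction, flux
    prediction (expression-weighted minimization; photosynthesis titration
    for the epithelial model), and subsystem summaries.  Any stage error
    aborts with the stage name attached.
    """
    for path_attr in ("epithelial_expression", "mesophyll_expression", "hits",
                      "localization", "model_dir"):
        path = getattr(config, path_attr)
        if path is not None and not os.path.exists(path):
            raise FileNotFoundError(f"configured input {path_attr} missing: {path}")

    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    manifest: Dict[str, object] = {
        "ductflux_version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    cell_types = ("epithelial", "mesophyll")

    def _stage(name: str):
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # --- stage: inputs ---------------------------------------------------
    stage = _stage("inputs")
    models: Dict[str, MetabolicModel] = {}
    expressions: Dict[str, ExpressionProfile] = {}
    for ct in cell_types:
        if config.model_dir is not None:
            models[ct] = read_model_tabular(os.path.join(config.model_dir, ct))
        else:
            models[ct] = make_mini_plant_model(ct)
        expr_path = getattr(config, f"{ct}_expression")
        if expr_path is not None:
            expressions[ct] = read_expression_tsv(expr_path, sample_id=ct)
        else:
            expressions[ct] = simulate_expression(
                models[ct],
                ExpressionSimSpec(
                    n_transcripts=config.n_transcripts,
                    cell_type=ct,
                    contamination_fraction=config.contamination_fraction,
                    noise_dispersion=config.noise_dispersion,
                    seed=config.seed,
                ),
            )
        expr_out = os.path.join(out_dir, f"expression_{ct}.tsv")
        write_expression_tsv(expressions[ct], expr_out)
        comp = make_biomass_table(ct, seed=config.seed)
        comp_out = os.path.join(out_dir, f"composition_{ct}.tsv")
        write_composition_tsv(comp, comp_out)
        stage[ct] = {"reactions": len(models[ct].reactions)}
    if config.hits is not None:
        hits = read_hits_tsv(config.hits)
    else:
        hits = make_hit_records(models["epithelial"], seed=config.seed)
    if config.localization is not None:
        localization = read_localization_tsv(config.localization)
    else:
        localization = make_localization_records(models["epithelial"])

    # --- stage: contamination -------------------------------------------
    stage = _stage("contamination")
    estimates = {
        "epithelial_by_mesophyll": estimate_contamination(
            expressions["epithelial"], expressions["mesophyll"], MESOPHYLL_MARKER,
            target_cell_type="epithelial", source_cell_type="mesophyll",
        ),
        "mesophyll_by_epithelial": estimate_contamination(
            expressions["mesophyll"], expressions["epithelial"], EPITHELIAL_MARKER,
            target_cell_type="mesophyll", source_cell_type="epithelial",
        ),
    }
    for key, est in estimates.items():
        stage[key] = est.to_dict()
    with open(os.path.join(out_dir, "contamination.json"), "w") as fh:
        json.dump({k: e.to_dict() for k, e in estimates.items()}, fh, indent=2)

    # --- stage: reconstruction ------------------------------------------
    stage = _stage("reconstruction")
    reconstructed: Dict[str, MetabolicModel] = {}
    grmaps: Dict[str, GeneReactionMap] = {}
    for ct in cell_types:
        model, grmap, provenance = reconstruct_model(
            models[ct],
            hits,
            localization,
            identity_threshold=config.identity_threshold,
            loop_policy=config.loop_policy,
        )
        reconstructed[ct] = model
        grmaps[ct] = grmap
        stage[ct] = provenance
        model_dir = os.path.join(out_dir, f"model_{ct}")
        write_model_tabular(model, model_dir)
        write_gene_reaction_map_tsv(
            grmap, os.path.join(out_dir, f"gene_reaction_map_{ct}.tsv")
        )

    # --- stage: flux prediction -----------------------------------------
    stage = _stage("flux")
    for ct in cell_types:
        dist = efmin(reconstructed[ct], expressions[ct], grmaps[ct], config.efmin)
        write_flux_tsv(dist.fluxes, os.path.join(out_dir, f"fluxes_{ct}.tsv"))
        sub = subsystem_flux(dist, reconstructed[ct])
        with open(os.path.join(out_dir, f"subsystem_flux_{ct}.tsv"), "w") as fh:
            fh.write("subsystem\tabs_flux_sum\n")
            for name in sorted(sub):
                fh.write(f"{name}\t{sub[name]:.10g}\n")
        stage[ct] = {
            "status": dist.status.value,
            "weighted_objective": dist.objective_value,
            "biomass_flux": dist.fluxes.get(
                reconstructed[ct].biomass_reaction_id, 0.0
            ),
        }
    titration = titrate_photosynthesis(
        reconstructed["epithelial"],
        expressions["epithelial"],
        grmaps["epithelial"],
        fractions=config.titration_fractions,
        opts=config.efmin,
    )
    with open(os.path.join(out_dir, "titration_epithelial.tsv"), "w") as fh:
        fh.write("subsystem\t" + "\t".join(f"{f:g}" for f in titration.fractions) + "\n")
        for name in sorted(titration.subsystem_summaries):
            row = titration.subsystem_summaries[name]
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
    stage["titration_fractions"] = list(titration.fractions)

    # --- manifest --------------------------------------------------------
    for root, _dirs, files in os.walk(out_dir):
        for fname in sorted(files):
            if fname == "manifest.json":
                continue
            path = os.path.join(root, fname)
            rel = os.path.relpath(path, out_dir)
            manifest["outputs"][rel] = _sha256(path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
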