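# Methods

## The modeling problem

Resin-duct epithelial cells are a heterotrophic secretory cell type: they
import sucrose, run glycolysis, the oxidative pentose-phosphate pathway,
the citric-acid cycle and oxidative phosphorylation to generate carbon
skeletons, reducing equivalents and ATP, and channel a large share of
carbon through the plastidial MEP pathway into monoterpenes and diterpene
resin acids. Mesophyll cells fix CO₂ photosynthetically and spread their
output over many end products at lower concentrations. `ductflux`
formalizes this contrast as two constraint-based models that differ in
(i) which boundary reactions are open (sucrose import only in the
epithelial variant), (ii) the biomass objective (measured oleoresin
classes + protein vs. chlorophyll/starch/lignin/flavonoid/protein with
trace terpenoids), and (iii) the expression profile used to weight flux
minimization.

## Flux prediction

FBA maximizes biomass under steady state (`S·v = 0`) and bounds. Flux
predictions then come from expression-weighted flux minimization: minimize
`Σ w_i |v_i|` with biomass fixed at its optimum (configurable fraction).
Weights are `w_i = max(1 − ê_i, 10⁻⁴)` with `ê_i = min(e_i/ceiling, 1)`,
where `e_i` aggregates the TPM of the reaction's mapped transcripts (sum
by default; max and mean selectable) and the ceiling is a percentile of
the positive reaction-expression values (default the 100th, i.e. the
maximum). The floor of 10⁻⁴ keeps even maximally expressed reactions from
carrying free flux, which would otherwise permit unbounded cycles.
Reactions with no transcript evidence weigh 1. If every mapped value is
zero the weights fall back to uniform 1 — plain parsimonious flux
minimization — with a logged warning. Absolute values are linearized by
splitting each flux into nonnegative forward/reverse parts; all LPs are
solved with HiGHS (scipy.optimize.linprog) with sorted variable ordering,
so repeated runs are bit-stable on one platform.

Weighted flux minimization has degenerate optima on symmetric networks.
`has_alternative_optima` re-solves with two opposite tiny rank-ordered
weight perturbations and flags predictions whose individual fluxes differ
between the two; when flagged, only the objective value should be
interpreted, not single fluxes. Tests assert individual fluxes only on
networks where the optimum is unique.

## Photosynthesis titration

The titration runs the weighted minimization at photon uptake pinned to
100, 75, 50, 25, 10 and 0% of the reference capacity. Two design choices
matter and are deliberate:

- **Photon uptake is pinned (lb = ub), not merely capped.** Incident
  light that a leaf absorbs is not optional; a pure flux minimizer with an
  optional photon influx would never pay the large photon flux and the
  titration would degenerate to the dark solution at every level. Any
  absorbed photons the network cannot use productively leave through a
  non-photochemical-quenching valve.
- **Biomass demand is held constant across the ladder** at the smallest
  FBA optimum over the fractions (times the configured biomass fraction).
  If each level used its own optimum, demand would co-vary with light
  supply and confound the comparison — respiration would track total
  output instead of compensating for lost photochemistry.

With these choices the expected physiology emerges from the LP: light
reactions fall linearly to zero, citric-acid-cycle plus
oxidative-phosphorylation flux rises monotonically as photons disappear,
and the ferredoxin-NADP⁺-reductase system switches from the
photosynthetic direction (reduced ferredoxin → NADPH) to the
non-photosynthetic direction (NADPH → reduced ferredoxin, feeding the
HDS/HDR steps of the MEP pathway).

## Reconstruction

Transcripts are associated to reactions from their best database hits:
hits under the identity threshold (default 40% global identity;
configurable and logged) are dropped; per transcript only the
highest-priority database with a surviving hit counts (curated core model
> AraCyc-like > MetaCyc-like); within it, every target within 1
percentage point of the best hit is kept, so one transcript can support a
multifunctional enzyme. Reactions without transcript support are removed,
except biomass, boundary reactions and transporters (reactions spanning
two compartments), which are protected by default because transporters
are chronically under-annotated; the protected set is switchable.

"Cannot carry flux" is defined by flux variability, not connectivity:
after an iterated dead-end sweep (metabolites with no producer or no
consumer), any reaction whose flux range is [0, 0] (|·| < 1e-9) with the
biomass constraint relaxed to ≥ 0 is removed, to a fixed point.

Thermodynamically infeasible loops are internal reactions that can carry
flux (> 1e-6) with every boundary reaction closed. Resolution tightens
reversibility greedily in sorted-id order: for each reversible loop
reaction the direction in which it can cycle is closed, preferring to
close the direction opposite its flux in a *parsimonious* reference
solution (a plain FBA vertex can itself ride the loop, making its signs
uninformative), and reverting any change that lowers the biomass optimum
by more than 1e-6. A `remove` policy deletes loop reactions under the
same guard. Loops that survive raise an error listing the irreducible
set. Full loopless-FBA inside the prediction LP is out of scope; loop
hygiene is a reconstruction step.

Localization predictions move a reaction into the majority compartment of
its mapped transcripts (ties: higher mean score, then cytosol < plastid <
mitochondrion < peroxisome), rewriting non-extracellular metabolites into
that compartment.

## Biomass objectives

A component measured at `c` mg/gDW with molecular weight `M` g/mol drains
`c/M` mmol/gDW in the biomass pseudo-reaction. Protein is expanded into
amino-acid drains by the mole fractions of a reference protein — a
glutathione-S-transferase-like composition for the secretory cell type,
a Rubisco-like one for the photosynthetic type (the shipped 80-residue
sequences are synthetic stand-ins with typical globular composition, not
database entries). Oleoresin classes are represented by one proxy
metabolite each with class-proxy molecular weights (α-pinene 136.23 for
monoterpenes, longifolene 204.35 for sesquiterpenes, abietic acid 302.45
for resin acids, a diterpene alcohol 288.47 for other diterpenoids). A
growth-associated maintenance of 30 mmol ATP/gDW (configurable) is
included when ATP/ADP ids are supplied. An optional `scale` factor
rescales bulk-tissue concentrations into cell-type-specific outputs —
pass the reciprocal duct volume fraction computed from needle geometry:
needle volume is cylinder over the proximal two-thirds plus an elliptical
distal cap, `(8/9)·A·L`, and ducts are full-length cylinders, so the
fraction is `(9/8)·Σa/A`, independent of needle length. The time base of
cell-type-specific output rates is a configuration constant, not derived.

## The synthetic study system

`make_mini_plant_model` builds a ~59-reaction, four-compartment network
(cytosol, plastid, mitochondrion, extracellular) with lumped textbook
stoichiometries: Calvin–Benson (3 CO₂ + 9 ATP + 6 NADPH → GAP), oxidative
pentose-phosphate (3 G6P → 3 CO₂ + 5 GAP + 6 NADPH), pyruvate oxidation +
citric-acid cycle (pyr → 3 CO₂ + 4 NADH + ATP), oxidative phosphorylation
at P/O 2.5, ethanolic fermentation, MEP (GAP + pyr + NADPH + ATP + 2
Fd_red → IPP), MVA (3 acetyl-CoA + 2 NADPH + 3 ATP → IPP), both FNR
directions, and synthesis + sinks for all eight end-product classes.
Metabolite balance is exact for everything the model tracks; elemental
balance of untracked species in lumped reactions (e.g. the porphyrin
moiety of chlorophyll) is not enforced. The light reactions produce 3 ATP
and 2 reduced ferredoxin per 8 photons. The non-photosynthetic FNR
carries a one-ATP coupling representing the cost of driving ferredoxin
reduction against the redox gradient; this also prevents the two
irreversible FNR isoforms from forming a closed energy-generating
2-cycle, keeping the base network loop-free so loop tests operate only on
deliberately planted cycles.

The expression simulator draws a shared per-seed log-normal baseline
(meanlog 2, sdlog 1.2 on the TPM scale — RNA-Seq abundances are
heavy-tailed), multiplies genes by their cell type's subsystem enrichment
fold changes (terpene synthases ~10× epithelial; MEP ~2×; MVA ~3×;
sucrose/glycolytic/respiratory/fermentative subsystems 2–3×; light
reactions 8×, Calvin 6×, chlorophyll/starch/lignin/flavonoid 3–5×
mesophyll), applies per-cell-type log-normal noise (sd 0.25), enforces
two strictly cell-type-exclusive markers (a Rubisco-small-subunit analog
in mesophyll, a diterpene-synthase analog in epithelial), and rescales to
a total of 10⁶ TPM. Contamination is linear mixing of the two same-seed
pure profiles, emulating laser-capture admixture. The simulator does not
model read-level sampling noise, transcript-length effects, batch
effects, or partial marker leakiness — so passing tests demonstrate
correctness of the estimators and flux machinery under the stated
generative model, not robustness to every artifact of real RNA-Seq.

The composition tables center the epithelial variant on measured needle
oleoresin values (monoterpenes 5.76, sesquiterpenes 0.35, resin acids
3.81, other diterpenoids 0.11 mg/gDW) plus 50 mg/gDW protein; the
mesophyll variant uses field-typical foliage values (chlorophyll 2.5,
starch 40, lignin 30, flavonoid 8, protein 120 mg/gDW) with every
terpenoid class at ≤ 5% of its epithelial value. Optional multiplicative
log-normal jitter (seeded) perturbs concentrations for robustness tests;
jitter 0 returns the central values exactly.

## Contamination estimation

The single-marker ratio `TPM(marker in target)/TPM(marker in source)` is
an upper bound on admixture: it attributes the target's entire marker
signal to contamination. Estimates above 1 are flagged, not clamped. When
both samples of a pair are contaminated at the same ρ, the ratio
converges to ρ/(1−ρ) rather than ρ — a property of the estimator itself,
asserted in tests; recovery tests therefore use an uncontaminated
reference sample. An optional multi-marker median is provided but off by
default. No deconvolution or correction of profiles is attempted.

## Numerical choices and limitations

- LP tolerances: steady-state residual ≤ 1e-6 enforced on every returned
  distribution; blocked-reaction threshold 1e-9; loop threshold 1e-6.
- Default bounds ±1000 (reversible) and [0, 1000] (irreversible)
  mmol·gDW⁻¹·h⁻¹; fluxes are relative model units.
- The tabular format stores numbers via `repr`, so write→read round trips
  are bit-exact; SBML round trips preserve structure and bounds to 1e-9
  but not subsystem/gene/provenance metadata (not part of core SBML).
- Gene sets are flat; Boolean enzyme-complex logic (AND/OR) is not
  modeled, matching a best-identity transcript-association procedure.
- Problem sizes: the shipped tests and the acceptance script run on the
  ~59-reaction synthetic network, 500-transcript profiles, 100-seed
  Monte-Carlo recovery (50 in the acceptance script); these sizes were
  chosen so the full study executes in seconds while leaving every
  code path exercised.
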