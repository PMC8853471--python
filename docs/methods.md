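# Methods note

This note records the model, the tunable parameters, the numerical choices,
and the limits of what the synthetic benchmarks demonstrate.

## Model and assumptions

The package treats organism reconstruction as *contextualisation* of a
curated universal stoichiometric network rather than draft-then-gapfill.
Three inputs are integrated simultaneously:

1. **Universal network** — metabolites (one elemental formula each, free-form
   compartment tags with one tag designating extracellular), reactions with
   signed stoichiometry and bounds restricted by convention to 0/±1000
   mmol gDW⁻¹ h⁻¹.  Exchange reactions are written `1 metabolite ⇌ ∅` with
   coefficient −1, so negative flux is uptake; after splitting reversibles,
   the uptake direction is the reverse component, which is what a medium
   constrains.  Secretion is never constrained by media application.
2. **Genomic evidence** — per-reaction bitscores aggregated from gene-level
   alignments: each reference sequence keeps its best query hit, and a
   reaction takes the maximum over its reference sequences (configurable to
   the mean).  Bitscores are used raw; no normalisation.
3. **Phenotypes** — binary growth calls per medium; `inconclusive` calls are
   conservatively mapped to no-growth at parse time and logged.

The core assumption inherited from constraint-based modelling is steady
state (`S·v = 0`) with flux bounds standing in for thermodynamic
directionality.  dgFBA's flux distributions are read strictly in a binary
way (which reactions carry flux, and in which direction); they are not
biological flux predictions.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `b_zero` | 500 | bitscore | evidence weight zero-crossing; accuracy is reported insensitive across 200–500 |
| `b_sat` | 1000 | bitscore | weight saturation knot (the printed anchors fix only 0 → −1, 500 → 0, high → 1; the knot itself is a required configuration value) |
| `biomass_min` | 0.1 | mmol gDW⁻¹ h⁻¹ | lower bound on biomass flux during each dgFBA solve; chosen equal to the growth-call threshold so every training solution itself qualifies as growth |
| `growth_threshold` | 0.1 | same | growth call iff FBA biomass flux is *strictly* greater |
| `eps` | 1e−6 | flux | net-flux magnitude above which a reaction counts as flux-carrying |
| `default_uptake` | 10 | mmol gDW⁻¹ h⁻¹ | uptake cap for supplied carbon sources in minimal-media simulations (a conventional glucose-scale limit; the source material does not state one) |
| sink cap | 1000 | flux | upper bound per artificial sink in the free-mass scan |
| rarefaction samples | 10 000 | — | subsets drawn per subset size |

Reactions absent from the evidence table weigh −1 (bitscore 0).  The biomass
pseudo-reaction carries no genomic evidence and is therefore also weighted
−1; it still carries flux because of its lower bound, and any growth beyond
the bound must pay for itself through positively weighted reactions.

## Design choices where the design was open

* **Biomass during dgFBA** is a lower bound (≥ 0.1), not an equality.  An
  equality would forbid evidence-maximising solutions from growing faster
  than the minimum; a lower bound keeps the LP feasible-monotone in weights.
* **CV denominator** is the number of observed growth conditions used for
  training.  Conditions whose dgFBA solve is infeasible contribute no FCRs
  but stay in the denominator, so certainty never inflates from failures.
* **Aggregation of gene evidence** uses the maximum of best-hit bitscores —
  the order-preserving, conservative choice; `mean` is available.
* **Structural reactions** (exchanges, biomass) are always retained in the
  assembled model regardless of CV, and are excluded from essentiality scans
  and pruning.
* **Pruning is explicit**: the net-benefit ranking (ties broken toward least
  annotation evidence) is emitted for the user; `--auto-prune N` applies
  greedy top-record removals for unattended runs and stops when no record
  has positive net benefit.
* **Rarefaction** draws, for each k, subsets of k *distinct* conditions
  (subsets resampled independently, 10 000 per k), so k = N deterministically
  reproduces the full union.
* **MCC** reports 0 with a degeneracy flag when any confusion-matrix marginal
  is zero.

## Numerical choices

LPs are solved with HiGHS via `scipy.optimize.linprog` — deterministic for a
fixed input, no randomised pivoting.  Infeasibility is a regular outcome
distinguished from solver failure (which raises).  Fluxes below `eps` after
forward/reverse recombination are treated as zero, so a reversible pair
circulating equal flux is not an FCR.  Elemental balance uses exact integer
formula counts with a 1e−9 tolerance on net coefficients; boundary and
biomass pseudo-reactions are exempt, and a missing formula renders a
reaction "uncheckable" rather than silently balanced.

**Alternate optima and flux loops.**  Two distinct degeneracies matter.
(i) Ties among equally optimal solutions make FCR sets solver-dependent; an
optional tie-break pass re-solves with the weighted objective pinned at its
optimum while minimising total flux (`canonical=True`).  It is off by
default: the single plain solve is the method's canonical behaviour.
(ii) Closed cycles whose weights sum positive are *objective-improving* and
run to their bounds; they are genuine optima, not ties, so the tie-break
cannot remove them.  The solver always stays bounded (all bounds finite) and
`saturated_components` reports flux pinned at bounds after a solve so users
can inspect inflated FCR sets.  The free-mass scan does not catch these
loops because they conserve mass.

## What the synthetic benchmarks emulate — and what they do not

The generator plants a known organism (linear pathways from distinct carbon
sources converging on one biomass precursor) inside a universal network with
shortcut and dead-end decoys, abstract unit-mass chemistry (balanced by
construction), evidence sampled high for planted and low for decoy reactions
with an optional label-noise fraction, and phenotypes *computed* by FBA on
the planted subnetwork.  An optional mis-annotation module adds a
well-scoring chain fed by a co-substrate present in every medium: it earns
certainty during training, produces false-positive growth calls, and gives
net-benefit pruning something real to correct.  Default scenario sizes stay
at ≤ 60 reactions and ≤ 12 conditions so that exhaustive oracles (vertex
enumeration of LP optima, brute-force knockout scans) remain sub-second; the
test and acceptance runs use these sizes throughout.

End-to-end recovery checks use unique-route scenarios (no reversible
internal reactions): the exact-recovery guarantee — every CV = 1 reaction is
planted, and the assembled model equals the reachable planted reactions —
holds only when the planted subnetwork is the unique support for the growth
conditions.  With reversible decoys, profitable flux loops (an
objective-improving cycle through a reversed shortcut and a planted chain)
legitimately enter the model; those scenarios exercise the loop report and
tie-break machinery instead.

Passing these benchmarks shows the pipeline's book-keeping and optimisation
behave as specified.  It does not show organism-scale accuracy: real
universal networks have branched, looped topology, genuinely ambiguous
evidence, cofactor coupling, and phenotype noise that the abstract chemistry
does not represent, and results on real data will also depend on the
alignment pipeline feeding the bitscore table, which is outside this
package's scope (it consumes precomputed tables).

## Known limitations

* Binary growth calls only; growth rates are not used.
* Evidence is consumed per reaction; boolean gene–protein–reaction rules
  (enzyme complexes, isozymes) are not modelled.
* Certainty values are relative to the training conditions: the model is a
  contextualisation of the universal network over known growth conditions
  and is not designed to predict growth in unseen media.
* Charge balance is not checked; formula inference is not attempted.
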