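# Methods

`h3opt` implements a three-route optimization scheme for the CDR-H3 loop of
antibody heavy-chain variable domains, together with the evaluation,
re-ranking and interface analytics that surround such a method. This note
documents the models, the parameters that matter, the synthetic data the
package tests itself on, and the numerical choices taken where the design
was genuinely open.

## The routing model

Given a predicted antibody model (e.g. an AlphaFold2 output) with
per-residue confidence scores (pLDDT-like, 0–100) and a CDR-H3 span:

1. **Confidence gate (CBM).** The mean confidence over H3 residues is
   computed on the 0–1 scale (pLDDT/100). If it is *strictly* greater than
   the cutoff (default **0.80**), the predicted loop is kept unchanged.
   The strict inequality matters at the boundary: a mean of exactly 0.80 is
   rejected. The cutoff is a configuration knob; 0.80 is the operating
   point used throughout.
2. **Template grafting (TGM).** If the gate rejects, the loop sequence is
   looked up in a template database of experimentally derived H3 loops.
   Only an exact, case-insensitive, full-sequence match qualifies — no
   fuzzy or homology search. A hit is grafted by a Kabsch fit on 8 anchor
   atoms — CA and carbonyl C of the first two loop residues, CA and
   backbone N of the last two — after which the template residues (side
   chains verbatim) replace the model's loop residues. Atoms outside the
   span are untouched, byte for byte. The achieved anchor RMSD is reported.
3. **Coordinate network (PSPM).** Otherwise a small attention network
   predicts the loop's CA trace (below), the trace is written back, and the
   loop geometry is idealized around it.

Gate-before-template precedence follows the validation behaviour of the
workflow this package models (high-confidence loops are retained even when
templates exist); a flag (`cbm_first=False`) flips the precedence.

## Features

For a chain of length L in a common aligned frame (all structures are
rigid-fitted to a reference on framework CA atoms, CDR-H3 excluded):

* residue features `[L, 34]`: one-hot amino-acid type (21 channels, UNK
  last) ++ CA coordinates (3, raw Å in the aligned frame) ++ sin/cos of
  (φ, ψ, ω) (6) ++ torsion-presence mask (3) ++ H3-membership mask (1).
* pair features `[L, L, 60]`: one-hot CA–CA distance bin (39) ++ one-hot
  type of residue *j* (21). Distances from 3.25 Å to 50.75 Å fall into 38
  equal 1.25 Å half-open bins; larger distances occupy the 39th bin;
  sub-range distances (clashes, the diagonal) clamp into bin 0 so every
  slice remains a valid one-hot.

Torsion angles are masked (set to 0, mask 0, sin/cos channels zeroed)
wherever a flanking atom is missing — φ at the first residue, ψ and ω at
the last. Coordinate channels are raw Å (not normalised); the choice is
recorded in the exported feature manifest.

## The coordinate network

Input projections lift residue features to `residue_channels` (default 64)
and pair features to `pair_channels` (default 64). One weight-shared block
is applied `block_iterations` times (default 4):

1. row-wise gated multi-head self-attention over residues (8 heads default)
   with an additive pair bias projected from the pair representation;
2. an outer-product-mean update carrying residue information into the pair
   representation;
3. outgoing then incoming triangular multiplicative updates on the pair
   representation.

Weight sharing makes the parameter count independent of the iteration
count. The triangular updates' output projections are zero-initialised, so
at initialisation they are exact identities; training turns them on.
After the iterations, provider embeddings (below) pass through a linear
layer, are concatenated with the residue representation, and three linear
head layers (hidden 64) emit per-residue 3-D coordinates; only H3-masked
positions are returned. Dropout (default 0.25) applies in training mode
after the attention update and after each head hidden layer.

Training minimises coordinate MSE (Å², mean over all 3n components) with
Adam (lr default 1e-4, decoupled weight decay 5e-4) under a staged
schedule: `freeze_plm` (embedding-provider parameters frozen),
`freeze_main` (only provider parameters train), `joint`. The mock provider
carries a trainable square projection precisely so these masks act on real
parameters; frozen-stage gradients are identically zero by construction.

**Embedding provider.** The network is conditioned on per-residue sequence
embeddings behind a small interface (`embed_dim`, `embed(sequence)`). The
bundled provider is a deterministic hash-based mock (default `embed_dim`
32): each row derives from a keyed hash of (seed, sequence, position),
giving reproducible, approximately unit-variance vectors. It deliberately
carries no biological signal; it exists so the architecture, training
machinery and pipeline are exercisable without a large language model. An
adapter around a real protein language model can implement the same
interface; nothing in the package requires one.

The residue representation is carried over between block iterations (not
re-projected from raw features); the alternative re-projection reading is
noted but not implemented.

## Loop refinement

`apply_predicted_calphas` writes the predicted CA trace into the model,
co-translating each loop residue rigidly by its CA displacement — a
chemically reasonable initialisation that preserves intra-residue geometry.

`idealize_loop` then minimises a geometric objective over the loop atoms:
harmonic bond terms (Engh/Huber-style ideal lengths: N–CA 1.458, CA–C
1.525, C–N 1.329, C–O 1.231, CA–CB 1.521 Å; k = 100), cosine-harmonic
angle terms (k = 50), an ω-planarity term (cos ω + 1)² (k = 20), and a
soft-sphere clash penalty below 2.8 Å (k = 50). Gradients come from the
package's autodiff; each pass is an L-BFGS-B minimisation (monotone line
search, so the objective never increases end to end).

Pass structure: (1) non-CA loop atoms with the CA trace hard-fixed;
(2) two damped release cycles with loop CA atoms under a harmonic restraint
(default force constant 10 kcal·mol⁻¹·Å⁻², anchored at the current trace);
(3) tethered free passes iterated until coordinates stop moving. Every
pass adds a very weak positional tether (0.05 kcal·mol⁻¹·Å⁻², three orders
softer than the bonded terms) to its own starting coordinates: the loop's
near-zero-stiffness collective modes are otherwise unconstrained and would
let the minimiser wander along essentially flat directions. A structure
whose initial objective is already below `already_ideal_objective`
(default 0.05, i.e. bond deviations ≲ 0.02 Å and no clashes) is returned
unchanged — this makes the operation exactly idempotent. A force constant
of `inf` keeps CA atoms hard-fixed throughout; 0 relaxes the loop fully.
An external minimiser can be substituted through a subprocess hook (PDB
text in, PDB text out).

## Metrics

* **Loop RMSDs** (CA / backbone / heavy / side chain, CB counted as side
  chain) are computed after a framework superposition — either all-Fv
  backbone heavy atoms or the V_H backbone excluding the H3 span — with no
  refitting on the loop. A side-chain RMSD over an all-glycine loop is NaN
  (empty selection convention). Matched selections must be equal length;
  mismatches are errors, not gaps.
* **TM-score** uses d0 = 1.24·(L−15)^⅓ − 1.8 (clamped to 0.5 below L=16,
  with a warning) and maximises the score over a documented search: Kabsch
  fits seeded from sliding windows (full length, L/2, L/4, length-4),
  iterative inlier re-fitting at progressive distance cuts around d0, and
  a local continuous polish (Nelder–Mead over the 6 rigid degrees of
  freedom) of the best candidates. Exact equivalence with external TM
  binaries is not promised; agreement to ~1e-3 with an independent
  multi-start search on fixtures is the tested contract.
* **GDT-TS / GDT-HA** use cutoffs {1, 2, 4, 8} and {0.5, 1, 2, 4} Å. All
  cutoffs are scored against one shared candidate-transform pool (window
  seeds plus per-cutoff inlier refinement), which makes the fractions
  monotone in the cutoff and guarantees GDT-HA ≤ GDT-TS structurally.
  Fixed-frame and single-global-fit variants are exposed.
* **Z-scores** standardise one target's metric across methods with the
  sample standard deviation (ddof = 1; population choice documented because
  it changes values); Z_ave is the equal-weight mean of the GDT-TS, GDT-HA
  and TM Z-scores.

## Ensemble re-ranking and Boltzmann analytics

Per-model energies (kcal/mol) are *inputs*. Δ_RMSD = RMSD(default top
model) − RMSD(candidate); positive means improvement; a target counts as
improved only for strictly positive Δ (a printed Δ of 0.00 is not an
improvement). Re-ranking sorts ascending by energy with lexicographic
model-id tie-breaks. Boltzmann weights use w ∝ exp(−(E − E_min)/kT) with
k = 0.0019872 kcal·mol⁻¹·K⁻¹ and T defaulting to 298.15 K (the source
experiments do not state T; it is configurable); Hartree inputs convert by
627.509. Weighted structure averages are per-atom convex combinations,
optionally followed by the idealizer ("minimized" variant).

Reference benchmark tables from published QM re-ranking / optimization and
MD loop-optimization experiments, and an MM/GBSA–MM/PBSA binding-affinity
comparison, ship as TSVs under `h3opt/data/` as the printed inputs to these
analytics.

## Surface and contacts

SASA is Shrake–Rupley (biotite's implementation) with Fibonacci point
meshes (default 960 points; totals change < 0.5 % on doubling), probe
1.4 Å, Bondi single-atom vdW radii. rASA normalises by the Tien et
al. (2013) theoretical maxima; a residue is "surface" iff rASA > 0.25
(strict). Property classes: hydrophobic {A V L I M F W P G}, positive
{K R}, negative {D E}, neutral-polar {S T N Q Y C H}; His sits in
neutral-polar by default and the classes are configurable.

Contacts: minimum heavy-atom distance per antibody/antigen residue pair,
contact iff ≤ 5 Å. Binding-site metrics label *antigen* residues by
any-loop-contact and compute precision / recall / accuracy over that
labelling (epitope framing; an empty predicted set gives precision null by
the 0/0 convention). Distance MSE is taken over pairs whose *native*
minimum distance is within each threshold. Contact propensity is a 20×20
(alphabetical one-letter) frequency matrix normalised to sum to 1.

## Synthetic fixtures

`make_toy_fv` builds toy V_H-like chains from ideal internal coordinates
(NeRF): two β-strand framework segments (φ, ψ = −120°, 130°) flanking a
loop whose φ ∈ [−150°, −45°] and ψ ∈ [−60°, 150°] are drawn from a seeded
generator, with retries until the chain is free of CA–CA (< 3.0 Å) and
heavy-atom (< 2.9 Å, ≥ 2 residues apart) clashes. Building the loop as
part of one continuous backbone keeps the chain exactly closed — no
separate loop-closure step is needed. The conserved framework Cys and
Trp-Gly flank are placed so the motif-based auto-annotation recovers the
span exactly. Defaults: 100 framework residues, loop length 12.

`perturb_model` emulates a predictor's loop error: a sine-windowed smooth
displacement field (zero at the loop ends, so junction geometry survives)
rigidly displaces each loop residue, scaled so the achieved loop CA-RMSD
equals the target exactly. Confidence is 100·(1 − |d_i|/8) plus Gaussian
noise (sd 5 by default), clamped to [0, 100] — the simplest mechanism that
reproduces the strong anticorrelation between confidence and loop error
seen in real predictors (the tests require Pearson r < −0.5 across 50
fixtures). Dataset splits mirror a ~1021/134/131 train/val/test
proportion (nearest-integer for train and validation, remainder to test).

**What the fixtures do not emulate:** real antibody sequence statistics,
side chains beyond CB, β-sheet pairing between framework strands, loop
ensembles, or any physical energy model. Passing tests therefore
demonstrate the correctness of the machinery (routing, grafting geometry,
featurization, optimisation, metrics) — not predictive accuracy on real
antibodies, which would require trained weights and experimental
structures.

## Problem sizes

The test and reproduction scripts run everything at desk scale by design:
toy chains of 24–112 residues, loops of 6–12, a reduced network (16
channels, 1 block iteration, mock embeddings) overfitted on four fixture
pairs, and 50–100 random pairs for the metric property suites. These sizes
were chosen so the full suite exercises every code path in minutes on one
CPU while keeping every numerical contract at full precision.

## Known limitations

* The motif-based auto-annotation is a heuristic tested on fixtures;
  real-world use should pass explicit spans from a numbering tool.
* The geometric idealizer restores ideal covalent geometry and removes
  clashes; it is not a force field and knows nothing about electrostatics,
  solvation or side-chain rotamers.
* The TM/GDT superposition searches are documented heuristics; scores are
  lower bounds on the true maxima (tight on the tested fixtures).
* mmCIF input, light-chain pairing logic and full Chothia/AHo renumbering
  are out of scope.
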