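# Methods

## Map data model

A regulatory map is a list of species (id, display name, kind ∈ {protein,
gene, rna, complex, phenotype, degradation, unknown}, compartment ∈
{cytoplasm, nucleus, extracellular, membrane}) and a list of signed
interactions (ordered sources → one target; category ∈ {state transition,
complex association, dissociation, transport, unknown transition, logical
activation}; sign ∈ {activation, inhibition, neutral}). Species identity
is the file id, not the display name, so the same molecule in two
compartments stays two nodes. Degradation sinks are retained in the data
model but excluded from logic inference and topology: they are
bookkeeping, not regulators.

Two file views are read: SIF-like signed edge tables (CSV/TSV, header
required; species-only rows with blank sign and target declare isolated
nodes so write→read round-trips preserve the species set exactly) and
CellDesigner-dialect SBML (species class annotations give the kind;
reaction-type annotations give category and sign; plain SBML degrades to
kind = unknown). Sign tokens map through one documented table; unknown
tokens are an error rather than a default — a silently flipped sign
corrupts every downstream Boolean rule. The published map's SBML (312
species) and CSV (340 nodes) views use different node conventions whose
mapping is not stated; they are treated as independent inputs with
independent censuses.

## Boolean translation

The translation template is the standard process-description convention:
for target t with activating reactions r₁..r_k and inhibiting regulators
i₁..i_m,

    f(t) = (OR over reactions of AND over that reaction's sources)
           AND NOT (i₁ OR … OR i_m).

Design choices where the convention leaves room:

* logical activations are ordinary activations in the OR block;
* unknown transitions follow their recorded sign (activation when the
  file records none — unknowns in curated maps are acknowledged
  interactions with unclear mechanism, not unknown direction);
* transport/dissociation (neutral sign) translate as activation of the
  destination form by the source form, preserving signal flow across
  compartments;
* a target with inhibitors but no activators is constitutively ON unless
  repressed, f(t) = NOT(…) — this keeps tumour-suppressor-style nodes
  (GSK-3β, p53) active in the resting state;
* in-degree-0 species are inputs with identity rules;
* phenotype nodes (EMT) are ordinary rule targets, read off the
  simulation like any other node.

Rules are negation-normal at the inhibitor block (NOT only above a
literal or an OR of literals), canonical text is fully parenthesised with
operands sorted inside commutative operators, and models round-trip
through SBML-qual Level 3 Version 1 (binary levels only; multilevel files
are rejected). The round-trip contract is truth-table equivalence per
rule, not structural identity.

## Simulation semantics

General asynchronous updating: one node chosen uniformly at random per
step; one step = one single-node update. Clamped inputs are resampled ON
with their clamp probability at every step. The synchronous scheme
(every node rewritten simultaneously) is available for fixed-point checks
and the exhaustive oracle. All randomness flows from one integer seed
(numpy Generator); ensemble run r uses seed + r, so any profile is
reproducible from its base seed.

Activity levels are ON-fractions over non-overlapping windows of 50
single-node updates, averaged over a 100-run ensemble (defaults; both
configurable). The initial state is not part of any window. The
"epithelial" preset sets the configured epithelial markers ON,
mesenchymal markers OFF, all other non-input nodes OFF, and inputs at
their clamp.

Attractors on models of ≤ 20 nodes are computed exactly: synchronous
attractors are the cycles of the deterministic update map; asynchronous
attractors are the terminal strongly connected components of the
single-node-flip state-transition graph (fixed points verified
f(s) = s). Larger models fall back to simulation; the engine's agreement
with the exhaustive analysis on seeded random models is part of the
acceptance computation.

Oscillation detection: after discarding the first 20 % of windows as
burn-in, a node is flagged when its window means stay strictly inside
(ε, 1−ε) with ε = 0.05 and the sequence is non-monotone. Sustained
oscillators hover mid-band; nodes that settle hit 0/1 and drop out.
Convention: ensemble-averaged profiles are used when asking "does this
specific node oscillate under this scenario" (single-run window means can
graze 0/1 by sampling); single-run profiles (ensemble = 1) are used for
planted-motif recovery, because averaging over a *bistable* motif whose
runs settle half to each fixed point yields a flat ≈ 0.5 curve whose
sampling noise would be indistinguishable from oscillation.

## Phenotype calling

With threshold τ (default 0.75) and marker ON-fractions (ef, mf):
epithelial when ef ≥ τ and mf ≤ 1−τ; mesenchymal for the mirror; hybrid
when both fractions ≥ 1−τ with at least one marker ON per side; otherwise
undetermined. The pure labels are checked before hybrid, so a state
satisfying both gets the pure label. Fractions are exact rationals.
Profiles are binarised at 0.5 per window before calling (simplest
unbiased cut; configurable). Default marker sets for the fixture:
epithelial {E-cadherin, ZO-1, miR-200, GRHL2, OVOL2}, mesenchymal
{SNAIL, ZEB, TWIST, Goosecoid, N-cadherin}. Note that with five markers
per side, a single ON marker (0.2) falls below the 1−τ = 0.25 hybrid
floor: a lone surviving epithelial marker does not make a hybrid call.

## Topology battery

Shortest-path statistics (diameter, radius, characteristic path length)
are computed over connected node pairs only — disease maps are
disconnected, and only under this convention is a finite diameter
meaningful. The radius is the smallest positive eccentricity within the
largest component (isolated nodes would otherwise force radius 0).
Undirected mode collapses direction and merges parallel edges, counting
multi-edge node pairs before merging; directed mode merges parallel edges
per direction. Self-loops are excluded from clustering and degree
computations and reported separately. Clustering is the mean
Watts–Strogatz local coefficient with degree < 2 nodes contributing 0;
density is e/(n(n−1)) directed and 2e/(n(n−1)) undirected; directed
average neighbours counts distinct in- plus out-neighbours. Published
tool outputs for disease maps mix further unpublished conventions
(directed radius, the density/clustering row pairing); those values are
not targeted.

The scale-free check is a least-squares line on the raw log₁₀(degree) vs
log₁₀(count) histogram over occupied bins, exponent = −slope. This is
the conventional network-analyser readout, not a maximum-likelihood tail
fit; on finite preferential-attachment graphs it is biased low (≈ 1.9 on
an n = 2000, m = 2 graph whose theoretical exponent is 3), so it is used
as a descriptive scale-free indicator, with exactness tested on exactly
power-law histograms.

MCC(v) sums (|C|−1)! over the maximal cliques C containing v (|C| ≥ 2) on
the undirected simple projection, enumerated with Bron–Kerbosch with
pivoting; a node whose only maximal cliques are single edges thus scores
its edge count, and isolated nodes score 0. Ranking ties break
lexicographically for determinism.

## Synthetic maps and the fixture

The generator draws exactly n_edges distinct directed signed edges (no
self-loops), each inhibitory with probability inhibition_fraction, never
pointing into declared inputs or motif endpoints, then injects requested
motifs verbatim (mutual inhibition a⊣b⊣a, negative feedback a→b⊣a,
double-positive a→b→a). Keeping motif endpoints free of random incoming
edges is what makes a planted motif's dynamics attributable to the motif:
the recovery analysis plants a negative-feedback pair in 100 seeded
10-node maps (15 random edges, 30 % inhibition) and asks the oscillation
detector about the pair after 3000 updates — and symmetrically for
mutual-inhibition pairs, which must not be flagged.

The EMT-core fixture (21 nodes, 37 signed edges, single input TGFB) is a
desk-scale distillation of the TGFβ→EMT signalling core: receptor
activation abstracted to TGFB → receptor complex → SMAD complex
(collapsing individually curated phosphorylation states), SNAIL/SLUG and
ZEB1/2 merged into family nodes, one merged SMAD complex (which R-SMAD
carries the signal is unsettled), the PI3K/AKT arm with the
GSK-3β–SNAIL degradation brake and the TWIST–AKT double-positive loop,
the NF-kB–NKILA negative feedback, the guarding mutual inhibitions
(SNAIL–miR-34, ZEB–miR-200, ZEB–GRHL2, ZEB–OVOL2), and the p53→miR-34
arm shut off under stimulation via AKT→MDM2⊣p53. That arm, plus SNAIL's
repression of miR-200/GRHL2/OVOL2, is what lets stimulation dislodge the
guarded epithelial state at all: under the strict AND-NOT template a pure
two-node mutual inhibition is absorbing in whichever direction it starts.
Every edge carries a provenance note in the shipped manifest; the
AKT→MDM2 link is standard signalling biology and is marked as the one
edge without direct support in the underlying survey.

What the synthetic data do not emulate: the full map's size and degree
sequence, multi-valued activity, kinetics and time scales, dosage
(everything is binary), and expression data. Passing the fixture checks
shows the pipeline reproduces the *qualitative* published behaviour of
the core circuit under the stated semantics — not that the 340-node map,
or real cells, are quantitatively captured.

## Problem sizes and numerical choices

Fixture scenarios: 100-run ensembles of 5000 single-node updates
(≈ 238 updates/node on 21 nodes), 50-update windows. Fixed-point
uniqueness: 30 independent 3000-update runs. Oracle suites: 200 seeded
random models of 5–8 nodes for attractor agreement (the independent
oracle is plain BFS mutual-reachability, no graph library), 200 seeded
graphs of 5–12 nodes for path-metric and MCC agreement (BFS and full
subset enumeration), 20 models for SBML-qual round-trips (exhaustive
truth tables, all rules ≤ 6 regulators). Motif recovery: 100 maps per
arm. These sizes make the whole analysis rerun in well under a minute
while keeping every agreement check exact rather than sampled.

## Known limitations

* Boolean semantics only; no multilevel logic, no rule-level
  probabilities, no ODE refinement.
* The CellDesigner reader covers the annotation subset needed for census
  and sign extraction (species class, reaction type); layout, modifiers
  of complex reactions and nested complex composition are ignored.
* Asynchronous activity levels depend on the window/ensemble convention;
  other simulators' activity curves are comparable qualitatively, not
  numerically.
* The hybrid call depends on τ and the marker lists; with the defaults a
  single discordant marker cannot trigger it.
* The raw-histogram power-law fit is descriptive, not inferential.
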