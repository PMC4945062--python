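# Methods

This note documents the models and algorithms implemented in `paleophylo`,
the conventions adopted where several were defensible, and the limits of what
a green test on synthetic data establishes.

## Character matrices and cell semantics

A matrix cell is one of five kinds: **determinate** (one state),
**polymorphic** (several states genuinely present), **uncertain** (scoring
could not decide among several states), **missing**, and **inapplicable**
(the structure the character describes is absent). The distinction is kept
through I/O because it is biologically meaningful, but *scoring* collapses
it: polymorphic and uncertain cells enter parsimony as their state set, and
missing/inapplicable cells as the full state set of the character. This is
the convention of the source analyses ("multistate taxa treated as
uncertain"; inapplicable scored as `?`) and keeps every algorithm
deterministic. No inapplicable-aware (ontology-driven) scoring is attempted.

Character classification counts **determinate cells only**: a character is
invariant when at most one state is determinately observed, informative when
at least two states are each determinately observed in at least two taxa,
and otherwise variable-but-uninformative. Counting uncertainty sets would
make classification depend on interpretation of partial uncertainty; the
conservative rule keeps it reproducible.

The canonical on-disk form is a restricted NEXUS dialect (symbols `0-9A-Z`,
`MISSING=?`, `GAP=-` for inapplicable, `{..}` uncertain, `(..)` polymorphic,
one `CHARSET` per partition, and a `[STATECOUNTS ...]` comment preserving
per-character state spaces). Output is canonical and byte-stable, so
read → write → read is the identity. DNA partitions map A,C,G,T to states
0–3; IUPAC ambiguity codes default to partial-uncertainty sets (an option
degrades them to missing, since the original parsimony treatment is not
recorded).

## Parsimony

Unordered (Fitch) lengths are computed with set operations on bitmasks,
vectorized across characters; polytomies use Hartigan's exact generalization
(per-state child counts; added cost = #children − max count). Ancestral
**MPR sets** come from a two-sided dynamic program with 0/1 costs: a
down-pass gives the minimal subtree cost per node and state, an up-pass the
minimal outside cost, and a state belongs to a node's MPR set iff the two
sum to the global minimum. Leaves report their observed sets (the standard
terminal-set convention). The implementation is checked against exhaustive
enumeration of all internal labelings on every tree shape up to 7 leaves and
4 states.

A **synapomorphy** on the branch into a clade is *unambiguous* when no
minimum-length labeling assigns the same state to both ends of that branch
(equivalently, parent and child MPR sets are disjoint), and *ambiguous* when
a change occurs in some but not all reconstructions. ACCTRAN/DELTRAN
tie-breaking is deliberately not implemented: the set-theoretic definition
is deterministic and matches the way "unambiguous" is used in the source
analyses. Bit-compatibility with PAUP* output is not attempted.

Fit indices use the standard bookkeeping: per character, min steps =
(number of determinately observed states − 1, floored at 0) and max steps =
(number of determinate cells − largest single-state count). Polymorphic and
uncertain cells contribute to neither bound; with pathological uncertainty
patterns the observed length can therefore exceed the nominal maximum, which
only affects diagnostics, never inference.

## Tree search

Rooted binary trees are searched and scored as unrooted objects (Fitch
length is root-invariant; verified by a rerooting property test). Stepwise
random addition inserts each taxon at a length-minimizing attachment; ties
break by the seeded RNG. Swapping (NNI, SPR, TBR) uses an exact shortcut:
for a pruned component with Fitch root set R and a target edge with "point
set" P (the states assignable to a new point subdividing that edge in some
minimum reconstruction), the reattached length is L(core) + L(pruned) + 1 if
R and P are disjoint, else + 0 — exact because one junction edge absorbs at
most one step per character. A full SPR neighborhood therefore costs a few
vectorized operations per prune site. TBR additionally pairs core point sets
with the pruned component's own per-edge point sets. Above 40 taxa TBR is
truncated to SPR by default (the published 100,000-replicate TBR setting is
cluster-scale and remains expressible through `SearchConfig`).

The search keeps every distinct topology at the best length (bounded by
`keep`), explores equal-length neighbors of the optima (plateau sweep), and
then applies the "min" collapse rule: an internal branch is removed when no
character forces a change on it in every minimum reconstruction. The two
edges of a degree-2 root are one unrooted edge and are collapsed as a unit.
An optional parsimony-ratchet loop (25% character upweighting by column
duplication) is available for rugged landscapes.

Bremer support sweeps suboptimal trees: a shortest-first SPR/TBR closure
over all trees within `cap` extra steps (bounded by `max_trees`), after
which BS(clade) = shortest swept length lacking the clade − best length;
clades unbroken inside the sweep report the cap. The sweep can in principle
miss a tree whose only access paths pass above the cap; the exhaustive
decay oracle in the tests shows agreement on small instances. Jackknife
support deletes each character independently with probability 0.36 ≈ 1 −
e⁻¹ (the standard parametrization behind the cited 36% setting) and tallies
bipartitions of each replicate's consensus.

## Likelihood models

The Mk model uses the closed form
P(same) = 1/k + (k−1)/k · e^(−kt/(k−1)),
P(diff) = 1/k − 1/k · e^(−kt/(k−1));
DNA families (JC, HKY, SYM, GTR) build reversible rate matrices normalized
to one expected substitution per unit branch length. Gamma rate variation is
the usual mean-of-equal-probability-bins discretization (default 4
categories; the bin means come from the incomplete-gamma identity and
average exactly 1). +I is a two-component mixture with the gamma mixture
nested (rate-0 category with weight p_inv; gamma rates are not rescaled —
conventions differ between programs, and this one is stated here).

The "variable" coding correction divides each site likelihood by
1 − Σₛ L(constant column s), the ascertainment correction for matrices that
never record invariant characters; partitions conditioned this way must not
contain invariant-coded characters (error otherwise), and a non-positive
denominator raises with tree/model context. Per-character k for Mk is the
character's defined state count, not the observed one (the matrix defines
the state space). No tree or parameter optimization is provided — the
module exists so the models used alongside parsimony are evaluable,
testable, and usable by the simulator; Bayesian tree inference (MCMC,
convergence diagnostics) is out of scope.

## Chronology

A fossil's first appearance datum (FAD) is the median of the narrowest
published interval (width ties go to the younger interval); extant tips are
0 Ma. Minimum clade ages propagate by post-order maximum; the difference
between a node's age and a child's own minimum is the child lineage's ghost
range. Stem and crown ages are distinct API calls because the two are easy
to conflate (the farmed clade's 145 Ma minimum is crown-inclusive — the
fossil sits inside the clade — while e.g. the rock-shrimp lineage's Late
Jurassic age comes from a stem fossil). Ages are point values; no tip-dating
likelihood or clock model is used.

The packaged reference topology is a reduced, genus-level rendition of the
published combined-evidence tree (31 tips) carrying every named clade and
all seven fossil placements. The Solnhofen fossils carry the interval
(150, 140) Ma (FAD 145 Ma, matching the published first-appearance dots);
*Ifasya madagascariensis* carries the Induan stage (251.9–251.2 Ma, FAD
251.55 Ma), the narrowest literature assignment for the Middle Sakamena
Group — the whole-Early-Triassic interval would put its median at 249.55 Ma
and contradict the published "> 250 Ma" split. The Cenomanian and Albian
intervals of the two remaining fossils are period-level approximations and
can be overridden with a user age table.

## Trait coding

Thresholds follow the published scheme verbatim: body size small ≤ 5 cm <
medium < 20 cm ≤ large, with class representatives 2.5 / 12.5 / 27.5 cm
(the large class closes at the 35 cm maximum recorded total length); depth
zones at 200 / 1,000 / 4,000 m with boundaries belonging to the shallower
zone; minimum water temperature with boundaries at 7 and 15 °C, a boundary
value joining the colder class ("between 7 and 15 °C" read as inclusive).
Depths are stored as positive magnitudes to avoid mixed-sign bugs. The
packaged ancestral gill formulas carry the published per-appendage gill
counts (totals 24/20/19/18/17); the per-segment *epipod* decomposition is
synthetic — only the totals 7/7/6/5/5 are published — and is labelled as
such in the source.

## Synthetic data: what it emulates, and what a green test means

The generator produces study-shaped bundles: a birth–death tree (birth 0.02,
death 0.005 /lineage-My) conditioned on 56 survivors, *sparsely sampled*
(10% of a larger simulated clade — the study sampled roughly one species
per genus across a deep superfamily, so terminals are anciently divergent),
rescaled to a 300 Ma root; 7 fossil tips Poisson-sampled along branches with
10 My stratigraphic intervals centered on the truth; 339 unordered phenomic
characters under Mk+G and 1,480 molecular sites in three partitions
(GTR/SYM/HKY with +I+G); fossils keep morphology only and lose a further
30–80% of phenomic cells, extant taxa 5%.

Clock rates, gamma shape (α = 1) and invariable fractions (phenomic 0.12,
genes 0.45) were calibrated once against the *published dataset properties* —
the per-partition character classification (phenomic 47/37/255, molecular
841/109/530) and the overall homoplasy level (CI ≈ 0.32) — and then frozen.
The generator does **not** emulate correlated morphological characters,
ontology-linked inapplicability cascades, among-lineage rate variation
(strict clock only), non-uniform fossil preservation, or alignment artifacts
(the real alignments were gapless).

Consequence worth stating plainly: at the published homoplasy level,
maximum parsimony on 56-taxon simulated matrices recovers the generating
topology only approximately (Robinson–Foulds 6–10 among extant taxa in our
experiments; the shortest trees are genuinely shorter than the true tree).
A green homoplasy-free recovery test establishes the search machinery is
sound; the bundle-level recovery number measures the information content of
the stated world, not implementation quality. Support values and dating
soundness (propagated minimum age ≤ true age, ≥ oldest sampled fossil in
the clade) hold on every simulated bundle.

## Numerical and reproducibility conventions

All randomness flows from integer seeds through `numpy.random.Generator`;
pipeline stages draw named substream seeds from the master seed, and every
output file carries the config hash, so a rerun from the same config and
inputs is byte-identical. Tie-breaks (equal-length insertion points, equal
best moves) resolve through the seeded RNG; tree serialization orders
children by smallest descendant label so identical topologies print
identically. Degenerate inputs are handled explicitly: empty interval lists,
k = 1 characters (zero steps, no possible change), all-invariant matrices
(RI reported as NaN), star trees (nothing to collapse), and all-characters-
deleted jackknife replicates (redrawn and counted).
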