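# Methods

## The model

The built-in network has 30 Boolean nodes in a fixed order that defines the
bit layout of every state vector: the seven extracellular stimuli
(`IFNg_e, IL1b_e, GM_CSF_e, LPS_e, IC_e, IL4_e, IL10_e`), then the seven
receptors, fourteen intracellular regulators and the two secreted products
in rule-table order. Identifiers are ASCII canonicalizations of the
biological names (NF-κB → `NF_kB`, PPARγ → `PPARg`, GM-CSF → `GM_CSF_e`);
a display-name table preserves the typeset forms. Input nodes carry no
update rule and are constant under every scheme — equivalently, they update
by the identity. Each of the 23 non-input nodes has a rule over `&`, `|`,
`!`, parentheses and the constants `0`/`1`; all 23 curated rules are unate
(each regulator acts with a single sign), and the signed-edge derivation
asserts that the syntactic NOT-parity of each literal agrees with
truth-table monotonicity.

The interaction structure contains exactly two feedback loops, both
positive: IL-1β → IL-1R → NF-κB → IL-1β (pro-inflammatory autocrine loop)
and IL-10 → IL-10R → STAT3 → IL-10 (anti-inflammatory autocrine loop),
coupled through STAT3 ⊣ NF-κB. Everything else is a feed-forward cascade
from the inputs. This observation does a lot of work below.

## Update semantics

*Synchronous*: all non-input nodes recompute simultaneously;
`batch_successors` evaluates all rules bitwise over uint64 bit-planes
(64 states per machine word), bit-exact with the scalar step.

*Asynchronous*: one time step is a full sweep — every non-input node
updates once, in a fresh uniformly random permutation, each update seeing
the partially updated state. This is a design choice the source material
left open (a single-node update per step is the main alternative); a sweep
is the semantics used by the common simulation libraries for this model
class, and eight single-node updates could not traverse the four-layer
receptor→TF→product cascade that the polarization time courses clearly do
traverse in eight steps. Fixed points coincide under both schemes; the
suite checks invariance of every enumerated steady state under sampled
sweep permutations.

Ensembles tile a start state into R replicates (default 10⁴), impose the
stimulus on the input bits, and record per-node ensemble means after each
of T sweeps (default 8). All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; derived sub-seeds are produced with a
CRC-tagged `SeedSequence`, so identical configurations give byte-identical
outputs across processes.

## Attractor enumeration

Because inputs are constant, the synchronous state space splits exactly
into 2⁷ independent functional graphs over the 2²³ internal states. Two
exact methods are implemented per input condition:

* **exhaustive** — build all internal states as bit-planes, evaluate every
  rule bit-parallel, form the successor-index array, and find the cycle
  set by iterated squaring of the map: the image of the iterate is
  monotonically decreasing and stabilizes exactly on the union of cycles,
  from which each cycle is walked off. Fixed points are length-1 cycles.
* **reduced** (default) — first substitute the input values into all rules
  and iterate constant folding: any node whose rule collapses to 0/1 given
  inputs and already-folded nodes converges to that constant along every
  trajectory and cannot participate in an attractor. The remaining free
  nodes (for this model, the two feedback loops and their dependents —
  typically 5–9 nodes) are enumerated exhaustively. This is exact, not an
  approximation, and runs the full 128-condition census in ~20 ms.

Equivalence of the two methods is asserted by property tests on random
networks (≤16 internal nodes, full-space naive enumeration as the oracle)
and on sampled input conditions of the macrophage network; the acceptance
script repeats the cross-check at run time. Cycles are reported starting
from their lexicographically smallest state (big-endian in node order), so
reports diff cleanly. A guard refuses exhaustive sweeps beyond 24 coupled
nodes. Steady states are full 30-node states, inputs included: states that
agree on internal nodes but differ on inputs are distinct.

## Phenotype classification

Ten marker nodes determine the call: STAT1, STAT5, NF-κB, IL-12 (M1 side)
and PPARγ, STAT6, JMJD3, ERK, STAT3, IL-10 (M2 side). The definitions are:
M0 — *no* node active anywhere (all 30, per the literal definition, not
just markers); M1 — IL-12 plus at least one of STAT1/STAT5/NF-κB; M2a —
PPARγ, STAT6, JMJD3 and IL-10 all active; M2b — ERK and IL-10; M2c — STAT3
and IL-10. The definitions constrain only the nodes they name, so they
overlap by construction (any ERK⁺STAT3⁺IL-10⁺ state matches M2b and M2c).
A state matching exactly one definition is canonical; two or more, hybrid;
none, unclassified. Canonical + hybrid + unclassified always partitions
the input set.

A strict variant (`mode="patterns"`) additionally requires every marker
*outside* the matched definition to be off — the expression-pattern-row
reading. For the enumerated steady states the two variants give identical
canonical counts; the strict variant reclassifies all 42 hybrids as
unclassified (they all violate some off-requirement). Both are reported;
neither reaches the originally published canonical total (see below).

## Polarization protocols

*Representative start states.* For each phenotype, enumerate the fixed
points under its eliciting stimulus (M1: all four of IFN-γ, IL-1β, LPS,
GM-CSF on; M2a: IL-4; M2b: IC+LPS, with IC+IL-1β as a config variant;
M2c: IL-10), keep those classified canonically to that phenotype, and take
the lexicographically smallest. The original protocol did not name which
steady state it used; this rule is deterministic and reproducible.

*Restimulation.* When a polarized state is challenged with a new stimulus,
all seven input bits are reset to the new stimulus (the environment
changes); internal nodes keep their polarized values. The "M1 stimulus" in
stochastic ensembles draws an independent uniformly random non-empty
subset of the four pro-inflammatory inputs per replicate — the literal
reading of "a combination of random M1-related stimuli".

*Resilience statistic.* For each M2 start under M1 stimuli: the maximum,
over time steps and over the M1 markers inactive at step 0, of the
ensemble-mean activation. Markers already active at the start are excluded
by the restriction rule.

*Knockout scan.* Every one of the 14 internal regulators is clamped to 0
(knockout) and 1 (ectopic expression) by replacing its rule with the
constant; the full census and classification are recomputed over all 128
input conditions (the original scan's input scope was unstated; all
conditions is the choice made here). Fold changes divide by the wild-type
count; 0/0 is reported as 1 (unchanged) and k/0 as infinite, rendered `NA`
in CSV.

## Robustness

One perturbation sample: draw a uniform random 30-bit state, flip one
uniformly chosen bit (inputs included — a flipped input persists in the
successor because inputs are constant), advance both states one
synchronous step, record the Hamming distance of the successors divided
by 30. Whether perturbed states should instead be drawn from trajectories
was left unstated originally; uniform drawing is the recorded assumption.
The exact expectation is

E[HD]/n = (1/n²) · Σᵢ [ 1{i input} + Σⱼ Pr₍ₛ₎( fⱼ(s) ≠ fⱼ(s ⊕ eᵢ) ) ],

with the inner probability (the Boolean sensitivity/activity of rule j in
variable i) read off per-rule truth tables. For the shipped model this is
28/900 = 0.0311, rounding to 0.03 at two decimals (half-up); the sampled
statistic at 10⁵ flips must and does agree within 4 Monte-Carlo standard
errors.

*Null models.* Two are available. `matched` preserves the reference's
node count, input set and per-node in-degrees and draws uniform random
truth tables. A uniform random function has expected sensitivity 1/2 per
regulator, so this null's mean is (7 + 46/2)/900 ≈ 0.0333 — statistically
indistinguishable from the curated network's 0.0311, and the comparison
does not separate (empirical p ≈ 0.4). `fixed_k` is the classical
homogeneous-K random Boolean network with K = the reference's maximum
in-degree (6): mean ≈ 0.084, and the curated network falls far below the
null's 5% quantile with the minimal attainable p = 1/100. The robustness
conclusion is therefore a statement about *which* ensemble of random
networks one compares against — sparse degree-matched randomizations are
nearly as noise-damping as the biology, dense ones are not. Both numbers
are reported; a pinned test documents the non-separation of the matched
null. The p-value convention is (1 + #{null ≤ observed})/N, so p = 0.01
at N = 100 means the observed mean undercuts every null draw.

## Synthetic generator

Random networks preserve node count, the constant-input set, and either
the reference's per-node in-degrees or a homogeneous K. Regulators are
drawn uniformly without replacement from all nodes except the target
(no self-loops, matching the reference's structure); rules are uniform
random truth tables, stored in disjunctive normal form with the regulator
set declared explicitly (a uniform table can be constant or ignore a
regulator; the declared set is what degree matching preserves). Generated
rules need not be unate and the generator preserves no topological motifs
beyond degrees — a green robustness test therefore establishes a
statement about degree- or K-matched ensembles only, not about nulls that
preserve, e.g., pathway layering or sign balance. Random states are
i.i.d. uniform bits. Everything is reproducible from a seed and
serializes to the rule-file format.

## Relation to the published counts

The original report of this network states 30 nodes and 49 interactions,
and a synchronous census of 1056 attractors: 1040 steady states, 16
three-state limit cycles, with 228 steady states mapping to canonical
phenotypes (M2a > M2c > M1 > M2b). The printed rule table, however, yields
46 interactions, and its published interaction list 43; the three to six
missing edges are described only as transcriptional auto-regulatory loops
in a schematic and are enumerated nowhere. These loops matter: with the
printed rules, a feedback vertex set argument gives a hard bound — the two
loops admit at most 2² fixed-point combinations per input condition, so at
most 512 steady states could exist across all 128 conditions. The
published 1040 is therefore *impossible* for any reading of the printed
rules; the published model must have contained additional feedback.

An exhaustive reconstruction attempt — all subsets of up to five
self-activation loops over the 23 internal nodes, under OR-latch
(`rule | self`), AND (`rule & self`), activator-OR
(`(activators | self) & !inhibitors`) and mixed semantics, plus
threshold/majority dynamics with tie-keep, each scored by its exact census
— found no completion that reproduces the published profile (1040 steady
states, 16 period-3 cycles, 228 canonical, the published frequency
ordering, and the three hand-derivable resting-state fixed points
simultaneously). The nearest completions reproduce the attractor totals
but break the classification counts and the resting-state oracle. Since
the deposited machine-readable model is not retrievable in this
environment and an under-determined reconstruction would amount to curve
fitting, the package ships the printed rules exactly.

Consequences, all exhaustively verified for the printed rules:
244 attractors (156 steady states, 88 period-3 cycles — all cycles from
the two autocrine loops), 113 canonical steady states (M2a 40 = M2c 40 >
M1 26 > M2b 6, plus M0), and a weaker anti-inflammatory lock: under M1
challenge the IL-10 latch of an M2a/M2b cell collapses in the minority of
sweep orderings in which STAT3 is updated before its inhibitors decay has
completed and IL-10 is updated after all its activators are off, letting
≈21%/≈13% of replicates reach canonical M1 and pushing the peak M1-marker
reactivation to ≈27%/≈42% (M2c is fully locked, 0%). The corresponding
acceptance tests assert the published values and are intentionally left
failing as documentation of the discrepancy; the mean-HD value (0.03),
the resting-state fixed points, the IL-4 fixed point, the knockout
signatures (STAT6 knockout abolishes M2a, STAT3 knockout abolishes M2c)
and the M2c lock all reproduce exactly.

## Limitations

Boolean levels cannot express graded cytokine doses or timescale
separation between signalling and transcription; the sweep semantics makes
one "time step" a full network update, so step counts are not calibrated
to wall-clock biology. Basin sizes are not computed (nothing quantitative
was published about them). The robustness statistic is a one-step measure;
multi-step divergence (Derrida curves) is out of scope. The classifier
implements marker logic only — it knows nothing about expression levels of
non-marker genes, chemokines or surface receptors that experimentalists
also use to type macrophages.
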