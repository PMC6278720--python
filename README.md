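# macpolnet

Logical (Boolean) modelling of macrophage polarization.

Macrophages differentiate into functional phenotypes set by their cytokine
environment: the pro-inflammatory, classically activated M1 state (elicited
by IFN-γ, LPS, IL-1β, GM-CSF; secretes IL-12) and the anti-inflammatory,
alternatively activated M2 states — M2a (IL-4), M2b (immune complexes with
LPS or IL-1β) and M2c (IL-10), all marked by IL-10 secretion. `macpolnet`
ships a curated 30-node Boolean gene-regulatory network of this process
(7 extracellular stimuli as constant inputs, 7 receptors, 14 intracellular
transducers/transcription factors, and the secreted products IL-12 and
IL-10) together with the analyses a logical modeller asks of it:

* **Attractor enumeration** — every synchronous steady state and limit cycle
  across all 2⁷ input conditions, by exact exhaustive analysis (bit-parallel
  sweeps of the 2²³ internal states, or an equivalent constant-propagation
  reduction that runs in milliseconds).
* **Phenotype classification** — marker-based calls (M0, M1, M2a, M2b, M2c,
  hybrid, unclassified) for any set of states; hybrids are states matching
  two or more canonical marker definitions, the substrate of the
  polarization-continuum interpretation.
* **Polarization protocols** — stochastic asynchronous ensembles (random
  update-order sweeps) for M0→M1/M2 polarization, the 16 initial-state ×
  stimulus repolarization matrix, and a resilience statistic for the
  re-activation of pro-inflammatory markers in M2 cells under M1 stimuli.
* **In-silico genetics** — systematic knockout (clamp 0) and ectopic
  expression (clamp 1) screens of all internal regulators, with per-phenotype
  steady-state counts and fold changes.
* **Robustness** — the one-step perturbation statistic (normalized Hamming
  distance between synchronous successors of a state and its single-bit
  flip), its exact truth-table expectation, and an empirical comparison
  against random Boolean network nulls.
* **Synthetic data** — degree-matched and homogeneous-K random Boolean
  networks and uniform random states, used for the robustness null and the
  property tests.

The formal object is a Boolean network: each node holds 0/1 and updates by a
logic rule over its regulators, e.g.

```
NF_kB := (IL1R | TLR4) & !(STAT3 | FcgR | PPARg | KLF4)
```

Under the synchronous scheme all nodes update simultaneously; a *steady
state* satisfies s = F(s) (and is invariant under any update order), a
*limit cycle* is a periodic orbit of F. Asynchronous simulations update all
non-input nodes once per time step in a fresh random permutation. Networks
round-trip through the plain-text `targets, factors` rule dialect, so any
model in that format can be analysed, not just the built-in one.

## Worked example

```python
import macpolnet as mp

net = mp.macrophage_network()
report = mp.all_attractors(net)
print(report.n_fixed_points, report.n_cycles, sorted(set(report.cycle_lengths)))
# 156 88 [3]
print(mp.classify_report(net, report.steady_states()).to_dict())
# {'M0': 1, 'M1': 26, 'M2a': 40, 'M2b': 6, 'M2c': 40, 'hybrid': 42, 'unclassified': 1}
```

Across the 128 input conditions the printed rule set has exactly 244
attractors: 156 steady states and 88 three-state limit cycles (all cycles
come from the IL-1β→IL-1R→NF-κB and IL-10→IL-10R→STAT3 feedback loops).
Of the steady states, 113 map to exactly one canonical phenotype; M2a and
M2c dominate (40 each), M1 has 26, M2b — whose pathway is the least
characterized — only 6, and 42 states are hybrid.

The same analyses from the shell:

```
$ macpolnet attractors -o out
156 steady states, 88 cycles (lengths [3]), 244 attractors

$ macpolnet robustness --null fixed_k --seed 1 -o out
mean normalized HD 0.0312 (exact 0.0311); null 5% quantile 0.0756; p = 0.01

$ macpolnet resilience --replicates 10000 --seed 1 -o out
M2a    0.2689
M2b    0.4217
M2c    0.0000
```

The robustness line says: flipping one random bit of a random state changes,
on average, 3% of the node states one synchronous step later (0.0312
sampled over 10⁵ flips, 0.0311 by exact computation from the rule truth
tables) — far below dense random Boolean networks with K = 6 regulators per
node (null 5% quantile 0.076), i.e. the curated wiring damps noise
significantly (empirical p = 0.01 with 100 random networks). Against
in-degree-matched random networks the statistic does *not* separate; see the
methods note. The resilience numbers are the peak ensemble-mean activation
of the initially-inactive M1 markers (STAT1, STAT5, NF-κB, IL-12) when each
M2 steady state is challenged with random pro-inflammatory stimulus
combinations for eight asynchronous sweeps (10⁴ replicates): an M2c
macrophage never re-activates them (STAT3 locks the IL-10 loop), while M2a
and M2b cells escape to the pro-inflammatory programme in a minority of
update orderings.

Other subcommands: `validate` (rule-derived signed edges vs a curated edge
table), `classify`, `polarize`, `repolarize`, `knockout-scan`, `generate`
(random networks), and `pipeline` (all stages plus a manifest with seeds and
checksums).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the library: the exhaustive attractor
census over all input conditions (total attractors, steady states, limit
cycles — the enumeration is verified in-process against the bit-parallel
full-space sweep), the canonical phenotype count of the steady states, the
mean normalized Hamming distance under single-bit perturbations (10⁵
samples, cross-checked against the exact expectation), and the peak
M1-marker reactivation of M2 macrophages under pro-inflammatory challenge
(10⁴ asynchronous replicates). The seed drives all Monte-Carlo sampling;
the census is deterministic.
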