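# Methods

## Model and assumptions

rnaforge treats computational RNA design as a sparse-reward reinforcement
learning problem. The environment's ground truth is an MFE fold predictor;
"solved" means exact partner-table equality between the candidate's
predicted fold and the target. Three assumptions follow from this framing:

- **Single-structure MFE objective.** The engine contract returns exactly
  one minimum-free-energy structure per sequence. Ensemble-based
  objectives (partition function, ensemble defect) are out of scope; any
  sequence whose single MFE structure equals the target is accepted.
- **Nested structures only.** Pseudoknots are excluded end-to-end: the
  dot-bracket parser rejects crossing brackets, the `PairMap` validator
  enforces nestedness, and both fold engines emit nested structures only.
  The minimum hairpin loop of three unpaired bases (pair span ≥ 4) is
  enforced at parse time, matching what thermodynamic folders can emit.
- **Exact-match termination.** Partial structural similarity earns no
  reward; the only reward is `solve_reward` (default 1.0) on the
  transition whose refreshed fold equals the target.

Two engines implement the fold contract. `ViennaEngine` wraps the
ViennaRNA bindings (Turner nearest-neighbour parameters, default options)
and is the production engine. `NussinovEngine` is a self-contained
maximum-base-pairing dynamic program with a declared score of −1 kcal/mol
per pair, built so the unit tests are hermetic; its tie-breaks are
deterministic (prefer leaving the 5' base unpaired at equal score, then
the smallest partner index). It is a deliberately crude energy model and
is never used for the energy-based analyses.

## Environment mechanics

Actions mutate a single base. The pair-fixing rule keeps target-paired
duos legal: after setting position *i* to base *b*, if the target pairs
*i* with *j* and {*b*, s[j]} is not one of GC/AU/GU, then s[j] is set to
the Watson–Crick complement of *b*. The complement was chosen (over, say,
a random legal partner) because it is deterministic and always produces a
GC or AU pair; the fix is part of the same environment step, so one action
changes at most two bases. No-op mutations are excluded by masking their
logits to −∞ before the softmax — mathematically equivalent to zeroing
and renormalizing afterwards, but numerically cleaner and exact (masked
entries are identically 0).

The softmax is global over the flattened N×4 logits rather than per-base,
because a single action is sampled from the whole matrix per step.

A lucky random initialization whose fold already equals the target counts
as a 0-step solve; the environment folds the current sequence at every
state, including the first.

## Network and optimization

Column order (A, C, G, U) and the conv7 neighbour-column order
(−2, −1, 0, +1, +2, target partner, fold partner) are fixed constants of
the checkpoint format. Missing neighbours (chain ends; unpaired positions)
contribute zero feature vectors. Weights use variance-scaled (He) normal
initialization with a recorded seed; biases start at zero.

The network, backward pass and optimizer are written directly against
NumPy. The backward pass is validated two ways: a per-row brute-force
reference for the graph convolution, and central finite differences of
the full actor-critic objective on a miniature network (4 channels, one
block, length 6), which agree with the analytic gradients to relative
error below 10⁻³ (observed ~10⁻⁸).

Training is advantage actor-critic with:

| parameter | default | units | rationale |
|---|---|---|---|
| `lr0` | 10⁻⁵ | — | published schedule start |
| `lr_decay` / `lr_interval` | 0.8 / 100,000 | — / env steps | published schedule |
| `total_steps` / `phase1_steps` | 1.5M / 0.5M | env steps | published protocol |
| `gamma` | 0.95 | — | sparse terminal reward; keeps 20–60-step credit horizons useful |
| `entropy_coef` (β) | 0.01 | — | standard A3C exploration bonus |
| `value_loss_weight` | 0.5 | — | standard critic weighting |
| `n_step` | 20 | env steps | update segment length |
| `n_workers` | 8 | threads | asynchronous workers |
| `step_cap` | 400 | env steps | bounds episodes on length-32 targets |
| `validation_step_cap` | 1,000 | env steps | failure charge during validation |
| optimizer | RMSProp (decay 0.99, ε 10⁻⁶) | — | adaptive SGD with statistics shared across workers |

"Steps" are environment steps summed across workers; the learning-rate
interval and the 1.5M total count these. Workers are Python threads
updating the shared parameter arrays in place without locking
(Hogwild-style); bookkeeping (step counter, logs, validation triggers)
sits behind a small lock. Exact reproducibility therefore holds only in
single-worker mode, which is what the test suite and the desk-scale runs
use. Episode targets are drawn uniformly from the active curriculum
phase. Every `validation_interval` steps the current policy attempts the
whole validation holdout; the snapshot with the lowest cumulative step
count is kept as the best network. Segment updates use n-step discounted
returns bootstrapped with V(s) after truncation and 0 after a solve; the
advantage is treated as a constant in the policy-gradient term.

## The target generator: what it emulates and what it does not

`generate_targets` reproduces the self-generated training distribution:
fold `n_target_sequences` uniform-random sequences of `target_length` and
keep distinct structures with occurrence counts (the sequences are
discarded). At the published scale (100,000 × length 32, Turner engine)
this yields ≈46k unique structures, ≈34k of them singletons — the
acceptance script recomputes these numbers from scratch.

This distribution emulates the *fold image* of random sequence space:
mostly short hairpins, bulges and small internal loops, with frequency
inversely related to difficulty. It does **not** emulate human-designed
puzzle features — long symmetric multiloops, zigzags, deliberately
repetitive elements — so passing the desk-scale tests demonstrates that
the pipeline learns on its training distribution, not that it solves
Eterna-grade puzzles. The benchmark harness accepts Eterna100-style CSV
files for users who want to run the full protocol (five attempts × 24 h
each are the benchmark defaults).

## Desk-scale study conditions

The test suite trains at a reduced scale chosen once as a realistic
miniature of the pipeline: length-12 targets generated from 10,000 random
folds (≈30 unique structures), 20,000 single-worker environment steps,
`lr0 = 10⁻³` with the same ×0.8 decay applied every 5,000 steps,
`step_cap = 60`, five 4,000-step logging intervals. At length 12 every
structure recurs many times, so there are no singleton structures to hold
out for validation; instead the 20 highest-occurrence non-trivial
structures are split off before training and used to compare the trained
policy against a uniform-over-allowed-actions baseline under identical
seeds and caps. The larger learning rate compensates for the 75×-shorter
schedule; the published 10⁻⁵ remains the default for full-scale runs.

## Analyses

- **Boost survey.** For each solved structure containing hairpin 4-loops,
  the base at the boost position (5'-most unpaired loop base, closing-pair
  index + 1) is recorded; where it is not already G it is forced to G and
  ΔΔG = E(boosted | target) − E(original | target) is computed as a
  constrained free energy on the target structure. Aggregates (fraction
  G, mean ± sd ΔΔG, fraction stabilizing) are recomputed from the
  per-loop records.
- **Pair perturbation scan.** Each designed pair is perturbed two ways —
  swapping its bases, and rewriting it as G (5') / C (3'); the GC
  orientation was an open choice, fixed as 5'-G. A pair is robust iff both
  variants still fold exactly to the target.

## Numerical and protocol details

- The masked softmax subtracts the running maximum before exponentiation;
  masked entries never enter the sum.
- Solve verdicts are re-verified with an independent fold call before
  being reported or written to a solutions CSV; unsolved rows carry an
  empty sequence field.
- Benchmark runs are resumable: names already present in the output file
  are skipped, and per-puzzle RNG streams derive from (seed, row index),
  so a resumed run reproduces the identical final file.
- Checkpoints (`.npz`) store a format version, channel width, block
  count, the value head's training length, and the column-order constants;
  inference checkpoints may drop the value head, after which the policy
  runs on any sequence length.
- Degenerate inputs: empty structures, non-ACGU characters, unbalanced or
  crossing brackets, hairpin loops under three bases, no-op actions, and
  stepping a terminal state all raise `ValueError` with the offending
  position or pair named.

## Known limitations

- The Nussinov reference engine's −1/pair score makes loop-base identity
  energetically irrelevant, so energy-based analyses under it are
  degenerate by construction; use the Turner engine for science.
- Thread-based asynchrony shares the GIL; it interleaves rather than
  parallelizes the NumPy work, so multi-worker mode mainly serves the
  asynchronous-update semantics, not wall-clock speedup.
- Multi-worker runs are not bitwise reproducible (lock-free updates).
- The value head fixes the training length; curriculum and training sets
  must be single-length.
- Desk-scale training demonstrates learning progress, not benchmark-grade
  performance; full-scale (1.5M-step) training is a long single-CPU run
  at Python speed.
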