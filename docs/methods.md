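# Methods

## The model

A population of `n` agents is placed on an undirected communication graph.
A single binary hypothesis `h` is at stake; its ground truth is drawn once
per run, true with probability `p_truth = .6`. Every agent starts agnostic
(`P_sub(h) = .5`) and, over `steps = 50` time steps, receives two kinds of
reports asserting `h` or `not-h`:

* from **the world**: each agent independently receives a report with
  per-step probability `activity = .1`; the report matches the ground truth
  with objective accuracy `p` (symmetric for true and false hypotheses);
* from **neighbours**: an agent whose start-of-step belief strictly exceeds
  the assertion threshold `theta = .8` asserts `h` — or strictly below
  `1 - theta` asserts `not-h` — with probability `p_communicate = .25`; the
  assertion is broadcast to all its neighbours. Anyone in between is silent,
  and silence carries no evidential weight.

Belief revision is Bayesian under a *symmetric reliability* convention: a
source of perceived reliability `rho` reports the true state with
probability `rho` whichever way the truth lies, so one report multiplies the
belief odds by `(rho / (1 - rho))^(+/-1)`. Within a step an agent folds all
incoming reports into a single batch update, treating sources as
conditionally independent given the hypothesis (naïve Bayes) and using each
source's expected reliability *at the start of the step*.

Perceived reliability follows one of two strategies:

* **fixed trust** — `rho = .66` for every source, never revised. The value
  is deliberately `.66` exactly, not `2/3`, to match the convention that the
  fixed strategy assumes "moderately reliable" sources; the updaters' prior
  mean is `2/3` (below). The 1/300 discrepancy is intentional.
* **expectation-based updating** — each source (including the world channel)
  carries a distribution over its reliability `tau`, prior `Beta(2, 1)`
  (mean `2/3`). After a report whose content the receiver currently believes
  with probability `b_c` (its belief `b` for an `h`-assertion, `1 - b` for a
  `not-h`-assertion), the density is updated pointwise with likelihood

      P(report | tau) = b_c * tau + (1 - b_c) * (1 - tau)

  — the source either spoke truly and the content is true, or spoke falsely
  and the content is false — then renormalised. Belief and trust updates
  within one step both use start-of-step quantities, so the two revisions
  commute. This is what lets two agents with different beliefs diverge in
  how much they trust the *same* source, the mechanism behind rational-agent
  polarisation.

Updaters revise trust in the world channel exactly as in any other source:
the strategy is defined over "sources" and the world is just the one source
every agent shares; exempting it would hard-wire knowledge the agents are
not supposed to have.

### Shadow agents

Every networked agent is paired with a shadow: initialised with the same
prior and trust values, fed *exactly* the same world-report stream (the same
arrival indicators and the same contents, consumed from a shared random
substream), but never sending or receiving testimony. Differences between
the two populations are therefore caused by communication alone. With
communication disabled the two populations are bitwise identical at every
step — this pairing contract is enforced in tests.

## Networks

Watts–Strogatz small worlds. The lattice parameter `k` counts neighbours
**per side**, so the regular ring has degree `2k` (degree 4 at the default
`k = 2`); a degree-2 ring has zero clustering and could not express the
clustering effects the rewiring sweep studies. Each clockwise lattice edge
is rewired with probability `p_rewire` to a uniform non-neighbour,
conserving the edge count (`n * k`); `p_rewire = 0` is the exact lattice
(mean local clustering `3(k-1)/(2(2k-1))`, i.e. 0.5 at `k = 2`) and
`p_rewire = 1` a random graph. Disconnected outcomes are kept, not
repaired; runs record a connectivity flag. For `n <= 2k + 1` no such ring
exists and the generator saturates to the complete graph, which keeps the
smallest size in the sweeps (`n = 4`) well defined. Construction is
delegated to `networkx.watts_strogatz_graph` (the original rewiring
dialect) on a dedicated random substream.

## Numerics

* **Trust densities** live on a uniform grid of `G = 201` points over
  `[0, 1]` with composite-Simpson quadrature weights (G must be odd).
  Simpson rather than trapezoid matters: the posterior mean after repeated
  linear-likelihood updates must track the exact mixture-of-Betas expansion
  (each update splits `Beta(a, b)` into `Beta(a+1, b)` and `Beta(a, b+1)`
  with weights `b_c * a/(a+b)` and `(1-b_c) * b/(a+b)`), and trapezoid's
  O(h²) bias is ~1e-5 at this grid size while Simpson is exact to well below
  1e-6 over at least ten updates. The grid is renormalised after every
  update, so weights never underflow.
* **Beliefs** are kept at full floating precision and never clamped; batch
  updates are computed in product (odds) form, which cannot leave `[0, 1]`.
  Beliefs may saturate to exactly 0.0 or 1.0 in floating point after long
  one-sided report streams; dogmatic beliefs are absorbing, which is the
  correct Bayesian limit.
* **Reliability parameters** are validated to the open interval `(0, 1)`:
  `rho` in {0, 1} has a degenerate likelihood ratio and is rejected.
* **Randomness** is split into named substreams per run via
  `numpy.random.SeedSequence(seed).spawn(4)`: truth draw, network
  construction, world reports (consumed in per-step blocks indexed by agent
  and shared verbatim with the shadow population), and communication. One
  uniform is consumed per agent per step on the communication stream whether
  or not the agent is eligible to speak, keeping streams aligned across
  configurations. A run is a pure function of `(config, seed)`.
* **Experiment seeds** derive from
  `SeedSequence([base_seed, cell_index, replicate_index])`, truncated below
  2³¹ — collision-free over the standard designs (checked by enumeration)
  and independent of execution order, so parallel cells merge
  deterministically.

## Measurement

Beliefs are measured in the state after the final step. Accuracy is the
Brier score, `mean((b - 1[truth])^2)` over agents, averaged over replicate
runs. Polarisation:

* **minimal polarisation** — the population contains at least one agent with
  belief > .999 *and* one with belief < .001 (strict); aggregated as the
  proportion of runs;
* **maximal gap** — the largest difference between adjacent values of the
  sorted belief vector; aggregated as the mean over runs (median available);
* **belief SD** — the *population* standard deviation (the agent population
  is observed exhaustively, so no sample correction).

## Design choices where the design was open

* **Broadcast assertions**: one communication draw per agent per step; a
  success delivers to all neighbours. The per-link alternative (independent
  delivery per edge) is available behind `per_link_delivery`.
* **Mirrored lower threshold** at `1 - theta` for asserting `not-h`: the
  assertion rule is symmetric in the hypothesis and its negation.
* **Simultaneous updates** from start-of-step state, removing any dependence
  on agent iteration order.
* **Strict thresholds** everywhere (`b > theta`, not `>=`; extremist cutoffs
  `> .999`, `< .001`).
* **Rewiring-sweep accuracy axis**: 21 evenly spaced values strictly inside
  `(.5, 1)` (the interior points of `linspace(.5, 1, 23)`); a perfectly
  reliable world (accuracy 1) is excluded as degenerate. Configurable.
* **Agents never self-update** from their own assertions, and asserting
  costs nothing.

## What the simulator does and does not emulate

The world model generates every evidence stream internally; there is no
external data. It emulates the study conditions the package is built around:
binary ground truth per run, symmetric noisy world reports, threshold-gated
testimony, homogeneous agnostic priors. It does **not** emulate features of
real communication: asymmetric hit/false-alarm rates, deceptive or
motivated sources, heterogeneous priors, selective exposure or algorithmic
curation, dynamic network rewiring, or evidential silence. Passing tests
therefore show that the *mechanisms* (expectation-based trust revision and
network communication) produce the accuracy and polarisation patterns under
these idealised conditions — not that those mechanisms are the dominant
cause in any empirical network.

## Problem sizes in the test suite

The Monte-Carlo checks run the headline design (sizes 30/60/90 × accuracies
.55/.66/.75 × both strategies) at its standard 100 replicates per cell, and
the size × accuracy heatmap at a reduced scale chosen for desk-scale runs —
7 sizes (4–100) × 5 accuracies × 30 replicates, expectation-based updaters
only, since the size-effect checks concern that strategy. The full
21 × 21 × 100 heatmap design remains available through
`preset_rewiring_heatmap`. Shadow-pairing is verified bitwise over 100
seeded runs per strategy.

## Known limitations

* Updater runs cost O(steps × reports × G); the full rewiring heatmap at
  paper scale (hundreds of thousands of runs) wants `--jobs` on a
  multi-core machine.
* Minimal polarisation is a coarse indicator (a uniform belief spread also
  counts); the gap and SD measures are reported alongside it for that
  reason.
* With 30 replicates per cell, per-cell polarisation proportions carry
  Monte-Carlo noise of a few percentage points; monotonicity claims in the
  tests are therefore asserted on the aggregate contrasts stated there.
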