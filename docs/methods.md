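# Methods

## Data model

A temporal network is a fixed, ordered node set plus `L ≥ 1` symmetric
binary snapshot adjacencies `A(1)…A(L)` of width `δ`. Node identifiers are
arbitrary hashables mapped to dense indices in first-appearance order, so
every run over the same input is reproducible. Snapshot indices are 1-based
everywhere in the API. Binning of timestamped events uses half-open bins
`[t_start + (t−1)δ, t_start + tδ)`; an event exactly on an interior bin
boundary belongs to the later bin, and one exactly on the right edge of the
last bin is clamped into it. Contacts are undirected and unweighted:
repeated contacts of a pair within a bin collapse to a single edge.
Self-loops are dropped at parse time with a logged count.

Two time-boundary conventions are supported wherever the dynamics can run
past the recorded window: `periodic` (`A(L+1) = A(1)`, the default for
dynamics) and `truncate` (error past `L`). Periodicity is what makes a
finite recording define an epidemic threshold at all.

## Temporal dynamics-sensitive centrality

The linearized SIR recursion and the score `S_i(t)` are described in the
README. Two implementation routes exist and are cross-checked in the tests
to 1e−10 relative error:

* **per-seed**: run the recursion `y(r) = H(r) y(r−1)` for each seed
  (`N × t` sparse matvecs);
* **one-pass** (default): using symmetry of every `A(t)`,
  `S = Σ_r H(1)⋯H(r−1) (β A(r) 1)` accumulated backwards as
  `acc_r = u_r + H(r) acc_{r+1}` — `t` sparse matvecs total, memory one
  snapshot plus a few vectors. Left products `H^(r)` are never
  materialized; the dense `PropagatorState` helper that does build them is
  for verification on small networks only.

The cumulative `x(t)` deliberately over-counts (entries can exceed 1): the
linear coupling `mβ` ignores contact saturation `1 − (1−β)^m`, so `x` is an
influence measure, not a calibrated probability. The seed's own component
enters only through reinfection terms; no constant is added for the seed.
Scores are reported unnormalized by default because the evaluation metric
(Kendall tau) is invariant to monotone rescaling; `normalize_scores`
applies min–max scaling to [0, 1] (a constant vector maps to zeros) and
`shifted_scores` adds 1 — both purely presentational.

Default spreading parameters in the CLI mirror the evaluation experiments:
`β = 0.01`, `μ = 0.1`, horizon `t = 10` for method comparison, and horizon
`t = L` for the null-model experiment.

## Epidemic threshold

`ρ(M)` with `M = H(L)⋯H(1)` is computed by power iteration that applies the
`L` sparse factors in chronological order, renormalizing after every factor
and accumulating log-growth — stable even when `ρ(M)` overflows a double.
The start vector is all-ones (deterministic); convergence is declared when
the per-sweep log-growth changes by ≤ 1e−10, with a hard cap of 1e5 sweeps
(error carrying the last estimate beyond that). All factors are nonnegative
with positive diagonal for `μ < 1`, so the dominant eigenvalue is real and
equals `ρ`.

`β_c` is found by bisection on `[0, β_max]` (default `β_max = 1`, since `β`
is a probability), valid because `ρ` is nondecreasing in `β`; the default
bracket tolerance is 1e−6. Degenerate cases: `μ = 0` returns `β_c = 0` with
a warning (the SI dynamics never dies out); `ρ(M(β_max)) < 1` raises "no
threshold in range"; a disconnected aggregate emits a warning and `ρ` is
taken over the whole matrix (the maximum across components).

## SIR simulator

The Monte Carlo simulator uses the exact nonlinear coupling
`1 − (1−β)^k`. Within a step: infections are drawn from the set of nodes
infectious at the start of the step, then those same nodes recover with
probability `μ`; newly infected nodes become infectious at the next step.
This order is the unique discrete scheme whose linearization reproduces
`x(1) = βA(1)x(0)` and `P(2) = βA(2)H(1)x(0)` exactly on chains (recovering
before infecting would insert an extra `(1−μ)` factor at step 1). The
alternative (recover-first) ordering is a known variant; the chosen one is
fixed, not configurable.

Randomness comes from counter-based substreams keyed by
`(rng_seed, seed-node index, replicate index)` (numpy `SeedSequence` spawn
keys), making per-seed results reproducible and order-independent. Both
uniform draws (infection, recovery) are made every step for every node, so
runs with the same key are coupled across parameter values — this common
random numbers structure is what the monotonicity-in-`β`/`μ` tests exploit.

## Benchmark centralities

Static degree, closeness and betweenness act on the binary aggregated
network (networkx provides shortest paths and Brandes betweenness).
Closeness is the raw reciprocal total distance `1/Σ_j d_ij`; on a
disconnected aggregate that form is undefined, so the harmonic form
`Σ_j 1/d_ij` is used instead with a log notice. Betweenness counts
unordered pairs once, endpoints excluded.

Temporal variants run on the time-ordered expansion: a walk either waits
(`(v, s−1) → (v, s)`) or crosses a contact of snapshot `s`
(`(u, s−1) → (v, s)`); the temporal distance is the earliest arrival step
counted from the window start. Temporal degree is the window-averaged
snapshot degree; temporal closeness is `Σ_j 1/Δ_ij` with unreachable pairs
contributing 0; temporal betweenness counts earliest-arrival contact
sequences over *ordered* pairs (temporal reachability is directional), with
paths through `i` obtained by subtraction (re-running the count with `i`
removed, same arrival step required) at `O(N² L E)` cost. Walks are counted
as contact sequences: two sequences differing only in the timing of the
same hops are distinct, and spatial revisits are permitted (none can occur
at an earliest arrival of the target). These are documented simplifications
of the temporal-path centralities from the literature, adequate as ranking
baselines; waiting-time-weighted costs are out of scope. With identical
snapshots and a window at least the static diameter, temporal distances
collapse to static shortest-path lengths exactly — note that temporal
(harmonic-form) closeness then matches *harmonic* static closeness, which
can order a pair differently from the reciprocal-total form; both facts are
asserted in the tests.

## Time-order null model

The shuffle relocates single events of a pair to uniformly proposed
snapshots, accepting only moves into a slot where that pair has no event.
Relocation (not swapping — a swap between two events of the same unweighted
pair is a no-op) conserves exactly: per-pair contact counts, the aggregated
network, `N`, `L` and the total event count. "Completely randomized" is
operationalized as 10 full sweeps over all events in random order; the
kernel is symmetric on each pair's feasible slot subsets, so its stationary
law is uniform, and 10-sweep mixing is validated by chi-square uniformity
tests over the small enumerable state spaces. The inner loop is compiled
with numba; all randomness (visit order, proposals) is drawn beforehand
from numpy Generators, so results are exactly reproducible and the audit
log can replay the final configuration.

## Evaluation

Kendall's tau-b (scipy) compares rankings; a constant score vector raises
an error naming the offending side rather than returning NaN. The
method-comparison pipeline computes structural baselines once and
recomputes TDC per `(μ, β)` cell against a simulated SIR reference; the
time-order pipeline reports, per cell, tau between the original TDC vector
and the shuffled-ensemble mean, plus a dispersion of two standard
deviations of the per-shuffle taus.

## Synthetic generators and what they do (not) show

`generate_temporal_ba` draws `L` independent BA graphs (networkx) on one
labeled node set — `m = 1` by default, giving `m(N−m)` edges per snapshot —
with the node order re-permuted per snapshot so hubs move around;
`persistent_hubs=True` pins them. Independence across snapshots matches a
"fresh scale-free topology per time slice" idealization: there is no
temporal correlation, burstiness, or circadian rhythm, so passing tests on
these networks demonstrates correctness of the machinery, not fidelity to
human contact data. `generate_temporal_er` provides homogeneous fuzzing
instances. The toy fixtures (`chain_forward`, `chain_reversed`,
`fig1_style`) are fixed hand-checkable networks; `fig1_style` is a
synthetic 4-node/3-snapshot pattern defined in this repository.

## Problem sizes and numerical choices

* Double precision throughout; route-equivalence and static-reduction
  checks at 1e−10 relative; hand-derived toy values at 1e−12.
* Experiment defaults are desk-scale (SIR 10³ runs, 10² shuffles) with
  flags to raise them; the test suite and acceptance script use scaled
  sizes: temporal-BA networks of `N = 200`, `L = 50` with 30 shuffles and
  20 replicate networks for the time-order experiment (threshold bisection
  at 1e−4 there — `β_c` enters only as a grid point), `N = 100`, `L = 20`
  with 2×10³ runs per seed for the TDC-vs-SIR tau, and 10⁵ runs for the
  chain consistency check.
* Statistical assertions use 3–4 standard-error bands, chi-square
  uniformity at α = 0.01, and a paired one-sided t-test at α = 0.05 for the
  threshold-trend experiment.

## Known limitations

* Directed, weighted, or interval contacts are not modeled; neither are
  waiting-time-weighted temporal paths, SEIR-type compartments, nor
  continuous-time dynamics.
* The linearized score diverges from simulated influence as `β` grows past
  the linear regime (`β k_max ≪ 1` no longer holding); it remains a useful
  ranking far beyond that, which is exactly what the tau experiments
  measure.
* No small-`L` correction to the threshold is applied; for very short
  recordings the periodic assumption itself dominates the estimate.
* Real-world contact datasets are supported through the contact-list loader
  and CLI but not bundled.
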