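# Methods

## The model

The simulator is a discrete-time, one-dimensional individual-based model
of refuge-to-forage movement. Space is continuous; time advances in
periods. A group of `n` individuals starts at the refuge (position 0) and
must reach the foraging region `[d_food, ∞)`. The model assumes:

* every individual knows about the foraging site from the start and its
  motivation to move there only grows (the outward probability ramps
  linearly in time);
* speeds are individual constants drawn once from U(0.95, 1.0) — close
  enough to 1 that travel differences are driven by decisions, not
  locomotion;
* there is no energetics, no predation, no collision cost, and no spatial
  structure beyond the single axis.

Within a period each individual makes exactly one decision, in an order
reshuffled every period. The decision cascade is: (1) already at the
foraging site → frozen forever; (2) behind the refuge (possible after
backward social steps) → forced one step outward; (3) otherwise draw
u ~ U(0,1) once; if `u < p_i(t)` step outward, else perform the social
action of the configured rule (`central`, `nearest_neighbour`,
`majority`, or `non_social` = stay put). Social actions read *live*
positions: individuals earlier in the period's order have already moved.
Social steps are full steps of length `s_i` and may overshoot the target
or carry an individual past `d_food` (it then freezes) or behind the
refuge (it is then forced outward at its next decision).

Tie conventions: a centroid or nearest neighbour exactly at the focal
position means no move; nearest-neighbour ties at identical distance are
resolved by one uniform draw among the tied set; the majority count uses
strict position comparisons, so co-located colleagues support neither
side and an exact tie means no move.

## Boldness indexing: the one genuinely open design choice

Two conventions anchor the boldness ladder `omega_i`:

* **`zero_based`** (package default): `omega_i = (i-1) * omega_difference`.
  This is the conventional written description of the model family, and
  what the configuration examples in the test suite pin down. Its
  consequence is extreme: individual 1 never ramps, so its departure is a
  pure geometric wait with mean `1/p_baseline` periods per step. At the
  baselines (`p_baseline = 0.001`, `d_food = 100`) individual 1 alone
  needs ~10^5 periods while a centroid-following group finishes in ~170.
  Every group statistic is then dominated by one individual, and the
  rescaled event times of individuals 2..n are squashed into a few
  thousandths of the unit interval.
* **`one_based`**: `omega_i = i * omega_difference`. Every individual
  ramps; all timescales are comparable (non-social baseline end time
  ~450 periods); the rescaled identity profile is a graded staircase.

The group-level summary statistics this package is meant to reproduce —
end-time gaps of a few hundred periods between non-social and social
groups, and identity F ratios of order 10^5 rather than 10^9 — are
attainable only under `one_based`. All sweep protocols behind
`scripts/acceptance.py` and the heavier end-to-end tests therefore run
`one_based`; the engine-level unit tests exercise the documented
`zero_based` default. Both variants share every other mechanism.

## Scheduling and random numbers

One seeded `numpy.random.Generator` per simulation covers everything, in
a fixed documented order: `n` speed draws at creation; then per period a
Fisher–Yates shuffle of the not-yet-arrived individuals (`k-1` bounded
integer draws for `k` active individuals), followed per scheduled
individual by at most one uniform draw plus one bounded integer draw on a
nearest-neighbour tie; in the sweep harness, one final bounded integer
draw selects the focal individual after the run ends. Arrived individuals
are dropped from the schedule: they can never move again and their
probability is never read, so this is behaviourally identical to
shuffling the whole group while making long non-social runs ~10× cheaper.

The pure-Python reference engine and the numba kernel consume this stream
identically; the test suite asserts bit-identical event logs across both
paths for every rule and both indexings. Sweep child seeds are
`SeedSequence([master_seed, rule_index, value_index, replicate_index])`,
so results are independent of execution order and social arms are
seed-paired with the non-social arm at the same cell — common random
numbers that sharpen the ordering-difference metric.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `n` | group size | 10 | ≥2 for social rules |
| `p_baseline` | outward probability at t=0, per period | 0.001 | (0, 1] |
| `omega_difference` | per-rank probability increment, per period | 0.001 | ≥0 |
| `d_food` | refuge-to-forage distance, units | 100 | >0 |
| `threshold` | departure line, units | 10 | 0 < threshold < d_food |
| `rule` | interaction rule | `non_social` | |
| `omega_indexing` | boldness anchoring | `zero_based` | see above |
| `max_steps` | runaway guard, periods | 10^6 | sweeps use 5·10^7: the smallest `p_baseline` grid cell legitimately averages ~10^6 periods under `zero_based` |

`p_i(t)` is deliberately not clamped at 1 — the comparison `u < p`
behaves identically either way and the closed form
`p_i(t) = p_baseline + t·omega_i` stays exact (to 1e-12 over at least
10^3 periods, asserted in tests).

Event times are first passages recorded online (position ≥ boundary at
the end of the individual's decision); the `≥`-vs-`>` choice differs only
on measure-zero events, and later backward moves never rescind an event.

## The analysis layer

Within each run, each measure (travel, leave, arrival time) is min–max
rescaled to [0, 1]; an all-equal run maps to all zeros (the run carries
no ordering information — an event of negligible probability in
practice).

The repeated-measures ANOVA is a classic balanced mixed design with runs
as subjects: the swept parameter (categorical) is tested against the
runs-within-levels stratum, and individual identity — and its interaction
with the parameter, which is kept in the model — against the within-run
residual. The decomposition is implemented as explicit sums of squares
(the degenerate conventions below need direct control) and is verified in
tests against `pingouin.mixed_anova` to 1e-8 on random balanced tables,
plus a frozen hand-worked table. The one-way ANOVA of per-run measures on
the swept parameter is likewise explicit and verified against
`scipy.stats.f_oneway`. Degenerate conventions: a zero numerator sum of
squares yields F = 0; a positive numerator over a zero denominator yields
F = +inf, capped at the sentinel 1e12 in CSV output.

The exact error structure behind the historically reported F values for
this model family is not recoverable from their magnitudes alone: under
the structure above (and under every standard alternative we scanned —
no-interaction pooling, random-parameter denominators, raw or transformed
responses) the identity-stratum values reproduce to within an order of
magnitude (travel times within ~10%), while the parameter-stratum values
for the non-social rule do not. The package reports what its own
documented pipeline computes; the acceptance test encoding the
parameter-stratum magnitude is expected to fail and says so.

The ordering-difference metric pairs replicate r of a social rule with
replicate r of the non-social rule at the same grid cell and subtracts
rescaled values per identity, giving a value in [−1, 1]: negative means
the individual moved earlier in the group order when social. Whether the
original protocols paired replicates this way is unknowable from the
outside; pairing is a pure variance-reduction choice and does not bias
the per-identity medians.

## Problem sizes

The sweep protocols used by the acceptance script and the end-to-end
tests run 200 replicates per grid cell (20 cells per sweep, ~4000 runs
per sweep), the scale at which the variance-partitioning statistics were
designed to be read; the focal-protocol machinery supports the full
10,000-replicate scale (guarded by a configurable run cap). The test
suite's micro-sweep fixture (3 increments × 20 replicates × 4 rules at
`d_food = 30`) is regenerated deterministically at test time rather than
shipped as data.

## What the simulations do and do not show

The simulator is both the model and its own data generator: passing tests
demonstrate internal consistency (oracle equivalence, invariants,
reproducibility) and that the stated group-level phenomena — slower
non-social completion, the centroid rule's depart-late/cross-fast
trade-off, latency compression under whole-group attention, and the
erosion of identity separability by every social rule — are robust
properties of the model at these parameters. They say nothing about real
animals: there is no observation noise, no individual variation beyond
the imposed ladder and speed jitter, and the single spatial dimension
suppresses flanking, visual occlusion and density effects that shape real
collective motion.

## Known limitations

* One spatial dimension; `k`-nearest generalisations, repulsion zones and
  visual fields are out of scope.
* The `non_social` + `zero_based` combination produces extreme-duration
  runs by construction; use the sweep `max_steps` override.
* F ratios are reported as variance-ratio descriptors only; no p-values,
  sphericity corrections or post-hoc contrasts.
* `numba` compiles the kernel on first use (~20 s); pass
  `use_kernel=False` to `run_simulation` for the pure-Python path (also
  the only path that records trajectories).
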