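# Methods

## Problem and model

A cohort of `n` subjects, each carrying one of `T` nominal treatments
(counts `t_1..t_T`), must be split into `B` processing batches of sizes
`b_1..b_B` with `Σt = Σb` (exact fit; partially filled batches are
rejected as a validation error rather than padded). Allocations are
B×T incidence matrices `N` with column sums `t` and row sums `b`.

Quality is judged under the fixed-effects model
`y = μ + treatment + batch + ε` with both factors dummy-coded against
their first level. The D-criterion is `det(XᵀX)`; zero means treatment
and batch are confounded, and within one problem a larger determinant
means a smaller generalized variance. Scores are *not* comparable across
problems. A full-dummy coding with intercept would be structurally
singular, so drop-one coding is forced; dropping the *first* level is an
arbitrary convention, harmless because the determinant is invariant
under batch and treatment relabeling (unimodular reparameterization —
property-tested).

Simple-contrast variances (the variance of each estimated pairwise
treatment difference) are read from the inverse information matrix with
the error variance set to 1; only relative comparisons between
allocations of the same problem are used.

## Preallocation

`t = B·q + t*` with `0 ≤ t*_i < B`; the quotient `q_i` of each treatment
is placed in every batch, residual capacities are
`b*_k = b_k − Σ_i q_i`, and the remainder is a binary design problem
(each treatment at most once per batch). Because the preallocated part
is identical in every batch, it cannot differentiate remainder
allocations, so the heuristic's concurrence bookkeeping starts at zero
after preallocation. Negative residual capacity (a batch smaller than
the per-batch quota) is an infeasibility error.

## The SBA heuristic

Batches are filled in the given order (batch order is re-randomized post
hoc, so only the multiset of batch compositions matters). Within batch
`k` of residual capacity `b*_k`, with `Λ` the concurrence matrix of the
remainder rows completed so far:

1. **Forced**: treatments with `t*_i = B − (k−1)` must be in every
   remaining batch; if more are forced than the capacity holds, the
   state is infeasible and an error is raised.
2. **Never chosen** (`Λ_ii = 0`): added next; if they exceed the
   remaining capacity, a uniformly random subset is taken (preserves the
   exchangeability of equally-untouched treatments).
3. **Seed pair**: if the batch is still empty and capacity ≥ 2, the pair
   with minimal *off-diagonal* `Λ_ij` starts it (the diagonal is a
   replication count, not a concurrence, so it does not compete).
4. **Column-sum picks**: remaining slots take the candidate `j`
   minimizing `Σ_{i∈C} Λ_ij` over the already-chosen set `C`.

`Λ` and `N` are updated once per batch, after the full set is chosen.
Every tie is broken uniformly at random from one seeded generator — the
sole source of stochasticity, which is what makes repeated runs explore
different allocations. Forced treatments are applied strictly before the
never-chosen rule: forcing is a feasibility requirement, zero-diagonal
only a preference. A batch that starts empty with capacity 1 (possible
only in synthetic states, not in the benchmark settings) takes the
least-replicated candidate, ties at random.

If at any point fewer treatments remain available than a batch's
residual capacity, the pass raises an infeasibility error rather than
underfilling the batch: every completed allocation therefore satisfies
the row- and column-sum contract exactly. Such dead ends never occur on
the benchmark settings or on near-equal batch structures; adversarial
hand-built batch vectors can produce them.

## The RBA baseline

Identical preallocation; each batch then receives a uniformly random set
of distinct available treatments of the full residual capacity, except
that forced treatments (remaining count = remaining batches) are always
included. Random choice can still strand capacity in rare corner cases,
so a dead-ended pass restarts with fresh draws (bounded at 1000
attempts, after which infeasibility is raised). Selection is uniform
over treatments, not weighted by remaining counts — the minimal reading
of a random binary allocation, empirically consistent with the measured
optimal-hit rate on the balanced benchmark setting.

## Exhaustive oracle

`search_space_size` returns the exact product `Π_k C(T, b*_k)` (an
upper bound that ignores column constraints). Enumeration refuses to run
above a configurable cap (default 1e7). Consecutive equal-capacity
batches are constrained to nondecreasing lexicographic row order:
batch identity is arbitrary before the post-hoc order randomization and
the score is row-permutation invariant, so this visits each design class
once instead of once per reordering. Recursion prunes states where any
remaining count exceeds the number of remaining batches. Tests
cross-check the canonical enumeration against a naive enumerator without
canonicalization on tiny instances.

## Numerical choices

* **Exact integer determinants.** Scores such as 309 561 102 vs
  309 416 760 (a 0.05% gap) must rank exactly, and large settings
  produce determinants beyond 1e21, so the scoring path never touches
  floating point: `XᵀX` is assembled directly from the incidence matrix
  in integers and eliminated fraction-free (Bareiss) with the diagonal
  batch block ordered first, which clears `B−1` pivots at `O(T²)` cost
  each (~1 ms for T=10, B=20 in pure Python). Tests verify bit-exact
  agreement with a symbolic-arithmetic oracle on random instances.
* **Contrast variances in float64.** Variances are only compared
  relatively at the percent scale; the information matrices involved are
  well-conditioned once non-singularity is established (checked via the
  exact determinant, not via the float inverse).
* **Seeding.** Experiment harnesses derive the seed of allocation `i`
  from a master seed through a counter-based seed sequence, so runs are
  independent and any single allocation can be regenerated in isolation.
  Derived seeds fit in 31 bits.
* **Ties in best-of-n** keep the earliest allocation, making the
  selection deterministic given the seed.

## Benchmark settings and evaluation scale

The four registered settings vary treatment-size imbalance, treatments
per batch slot, and search-space size: A (5×6 subjects, batches of 3 —
balanced, optimum known in closed form as the all-triples balanced
incomplete-block design), B (10×10, batches of 5), C (6,7,8,8,9, batches
of 3), D (5,5,8,8,10,10,12,12,15,15, batches of 5). Batch sizes are
derived from a maximum size as near-equal, larger first — the rule
anchored by the worked six-batch example [8,8,7,7,7,7] for 44 subjects;
batch order is randomized post hoc anyway.

The evaluation protocol mirrors the "best of n allocations per run,
many runs" usage. Problem sizes used here are chosen for single-core
desk scale as the package's own defaults: 1000 single allocations per
algorithm for per-allocation hit rates; 200 runs of best-of-1000 for the
run-level rates on setting C; 120 runs of best-of-200 per algorithm for
the run-level comparison on setting D. The run-level rate on setting C
is a threshold-crossing statistic of the best of `n` draws
(`1 − (1−p)^n` for per-allocation probability `p`), so `n = 1000` is
part of the statistic's definition and is not scaled down; only the
number of runs is. The setting D comparison is relative (RBA run-bests
vs the SBA median run-best at equal `n`), which is meaningful at reduced
`n`. Full 1000×1000 experiments remain available behind
`evaluate --full-scale`.

Measured reference behavior of this implementation, at large sample
sizes: setting A optimal-hit rates 96.4% (SBA) and 4.5% (RBA) per single
allocation; setting C per-allocation probability of the top score
6.6e-4 for SBA, giving a best-of-1000 run rate near 48%, with RBA
reaching the top score in essentially every run; setting D RBA reaches
the SBA median run-best in ≈2% of runs; no confounded allocation has
ever been observed from either algorithm on any setting. The two
recurring setting C score classes differ by less than 7% in every
simple-contrast variance, so the practical difference between them is
minimal.

## Post-hoc randomization

An incidence matrix fixes batch compositions only. The processing plan
applies, in order: (i) a uniform permutation of batch rows, (ii) uniform
assignment of each treatment's named samples to that treatment's slots,
(iii) independent uniform shuffling of processing order within each
batch. All three conserve batch compositions, so the plan's incidence
(and score) equals the allocation's — asserted end-to-end in tests.
Plans are CSV (`sample_id,treatment,batch,position`, 1-based) with a
JSON provenance sidecar carrying algorithm, seeds and score.

## Synthetic test data

Property tests draw random problems as: 2–5 treatments, counts 1–8,
near-equal batches from a maximum size of 2–5. These cover imbalance and
non-divisible remainders but deliberately stay within near-equal batch
structures — the only shape the batch-size derivation produces — so they
say nothing about adversarial hand-built batch vectors (where SBA may
legitimately raise infeasibility). Manifests in tests are generated
programmatically from the problem's counts; no real cohort data is used
or emulated beyond the counts themselves, since the algorithms are
exchangeable over subjects by construction.

## Known limitations

* Single nominal treatment variable only; no multi-factor designs,
  continuous covariates, or covariate-stratified subject assignment.
* The heuristic ignores how many subjects remain to be allocated (it
  only tracks what has been allocated), so under strong size imbalance
  it concentrates on slightly suboptimal but more concurrence-flat
  designs; the affected contrasts differ by a few percent in variance.
* Optimality is never guaranteed; the exhaustive oracle is the only
  certificate and is limited to small search spaces.
* Greedy feasibility (forced-inclusion) is not a completeness proof:
  pathological batch-size vectors can dead-end, which surfaces as an
  explicit infeasibility error, never as a silently underfilled batch.
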