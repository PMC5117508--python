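# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Ordering model

The ordering cost couples every gene pair (i, j) to its four list
neighbours: `F = Σ_{i<j} d_ij^α (|A_ij − A_{i+1,j}| + |A_ij − A_{i−1,j}| +
|A_ij − A_{i,j+1}| + |A_ij − A_{i,j−1}|)` with `d_ij = |i − j|`. Minimising
F rewards orders in which the association matrix is locally smooth, i.e.
associated genes form blocks near the diagonal.

* **α (distance exponent).** Not dictated by the model; default α = 1
  (linear distance penalty, the minimal reading of `d^α`), exposed as a
  parameter everywhere.
* **Boundary handling.** Neighbour terms whose index leaves 1..N are
  *omitted*, not zero-padded; zero-padding would penalise edges at the list
  ends for a purely structural reason. This choice changes F and has a
  visible consequence: because the matrix diagonal is structurally zero,
  mid-list edges carry intrinsic neighbour disagreements that end-of-list
  edges avoid, so for tiny graphs the optimum can differ from the
  "intuitive" order (for a 3-gene path the hub-at-the-end orders cost 5
  while hub-in-the-middle costs 10 — verified by full enumeration, and
  pinned in the tests).
* **Degenerate inputs.** N < 2 is an error; a single gene has no
  neighbourhood to smooth.

## Annealing schedule

One MCS = N attempted random pair swaps; acceptance is Metropolis-like
(ΔF ≤ 0 always, else `exp(−ΔF/T)`); T drops by a fixed decrement every
`steps_per_level` MCS (100 by default).

* **Self-scaling T₀.** The model gives no temperature scale, and a fixed T₀
  cannot suit both 6-gene and 600-gene networks. Default T₀ = 90th
  percentile of |ΔF| over 10·N random swaps from the initial state, so the
  walk starts near-free for any size.
* **Decrement.** T₀ / `n_levels` with 200 levels by default; `n_levels`
  exists so scaled-down runs can cool faster without hand-picking
  temperatures.
* **Termination.** When T ≤ t_final (default 0), a zero-temperature polish
  accepts only ΔF ≤ 0 swaps until one full MCS brings no strict
  improvement; the final cost is re-anchored by a full recomputation to
  cancel float drift from incremental updates.
* **Restarts.** Restart r draws its initial permutation with seed
  `seed + r` and anneals independently; the lowest-cost state seen anywhere
  is returned. Everything is reproducible from (network, schedule, α,
  seed).
* **Incremental ΔF.** A swap of positions a, b touches only the ≤ 6 list
  rows {a−1, a, a+1, b−1, b, b+1}; ΔF is the partial-cost difference over
  pairs meeting that set, exact to full recomputation within 1e−9 (tested
  per swap). The sweep is numba-compiled; the public `cost_function` is an
  independent vectorised numpy implementation, and the `OrderingState`
  invariant cross-checks the two on every constructed state.
* **Exhaustive oracle.** For N ≤ 10 all N! orders are enumerated; ties are
  broken toward the lexicographically smallest gene order so the oracle is
  deterministic.

## Windowed profiles

`k_i = (1/(2r+1)) Σ_{j=−r..r} h_{i+j}` for 1-based i in r+1 … N−r−1
(length N − 2r − 1; the last full window is deliberately not reported, per
the profile-length contract). Default r = 30 for both expression and
term-enrichment profiles. Window sums use exact convolution of the raw
vector, so an all-ones window yields exactly 1.0 for indicator input.

List genes missing from the expression table become NaN rows; a window
averages over its measured genes only (divisor = count present), which
avoids biasing profiles toward zero. A window with < 50% coverage raises an
error rather than reporting a mean that no longer represents the
neighbourhood.

## Class comparison and significance

* Per-sample transcriptograms are averaged within class; Δᵢ is the ratio of
  class means (zero reference mean is an error naming the position).
* The per-position test is a two-tailed Welch t-test on per-sample profile
  values (a t-test needs within-class variance, so "class averages" is read
  as testing the difference of class means from replicates). Zero-variance
  positions are resolved explicitly: P = 1 if both classes are constant and
  equal, P = 0 (logged warning) if constant and different — a measure-zero
  event for continuous data, but explicit behaviour beats NaN.
* **Permutation FDR.** Labels are reassigned uniformly at random among
  arrangements preserving class sizes, sampled *with replacement* and
  without excluding the identity; with 3 + 3 samples only 20 distinct
  arrangements exist, and the identity plus its mirror reproduce the
  observed split, so on true signal the estimator has a floor of ≈ 2/20 =
  0.1. `FDR(p*) = mean_perm #{permuted P ≤ p*} / #{observed P ≤ p*}`,
  NaN when nothing is observed significant. Defaults: 500 permutations,
  cutoff grid {0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001, 0.00005}.
* **Multiplicity.** Adjacent positions share 2r of their 2r+1 window genes,
  so neighbouring P values are strongly dependent; the permutation FDR —
  not per-position Bonferroni over N − 2r − 1 tests — is the intended
  control.
* **Calling a significant region.** The benchmark module calls a region
  significant when some position has P < 0.01 *and* the estimated FDR at
  the 0.01 cutoff is below 0.12, mirroring the working criterion used when
  reading relative transcriptograms (peaks at P < 0.01 with FDR ≈ 0.1).
* **Volcano.** FC is the ratio of class means on the linear scale
  (`2^(mean difference)` for log2 input — matching how fold changes are
  conventionally reported); flagged when FC > 2 or FC < 1/2 with Welch
  P < 0.01. Note the Welch test with triplicates has Welch–Satterthwaite
  df ≈ 4 and true size ≈ 0.035 at nominal 0.05: it is conservative, and
  per-gene power at P < 0.01 is the limiting factor for recovering
  moderate fold changes from n = 3.
* **Gene sets.** Each sample is reduced to its mean over member genes;
  classes are compared by Welch tests on those per-sample means, with
  `**`/`*` markers at P < 0.01 / 0.05.

## Preprocessing

Fixed order: per-array min-shift to 1 → log2 → quantile normalisation →
detection filter → range filter → replicate-probe averaging.

* Quantile normalisation (sorted values replaced by rank-wise means across
  arrays) is the canonical realisation of "make the cumulative intensity
  distributions comparable"; it preserves within-array rank order exactly
  and equalises the per-array distributions to machine precision. Ties are
  resolved by stable sort order.
* LoD = mean + 1.96·sd of negative-control values on the normalised scale,
  pooled across arrays by default (a per-array option averages per-array
  estimates); probes whose 90th percentile across samples is below LoD are
  dropped. Fewer than two controls skips the filter with a warning.
* Range filter: probes with (q95 − q5) < log2(1.5) ≈ 0.585 across samples
  are dropped. Percentiles use linear interpolation (numpy default), which
  matters for probes near the cutoff and is therefore pinned in the tests.

## Synthetic data: what it emulates, what it does not

The generators emulate the study design the pipeline targets: a
planted-partition association network (within-module edge probability 0.9,
between 0.02; confidences Uniform(0.85, 0.999) within and Uniform(0.4,
0.95) between, so the 0.8 threshold keeps most within-module and few
between-module edges), module-aligned gene sets, triplicate log2 expression
with multiplicative module shifts per class, Gaussian noise (sd 0.25 on the
log2 scale, the domain the pipeline operates in), and probe tables with
background-level negative controls plus a planted below-LoD fraction.
Isolated genes are re-wired to a same-module partner so every gene keeps an
association after thresholding.

Not emulated: real STRING evidence channels, scale-free degree structure,
correlated (batch) noise, probe sequence effects, or spatial array
artifacts. Passing the closed-loop tests therefore demonstrates that the
pipeline recovers *concerted, module-aligned* shifts under independent
Gaussian noise — not robustness to batch confounding or annotation error.

## Benchmark problem sizes

The closed-loop benchmark uses 4 modules × 60 genes (240 genes, window
r = 30 → 179 profile positions), one module shifted 1.5×, triplicates,
noise sd 0.25, 500-permutation FDR, and a 60-level / 10-MCS-per-level
annealing schedule with a single restart — sizes chosen so a full 20-seed
sweep (signal + matched null) completes in minutes on one CPU while the
planted module still spans a full smoothing window. The small-graph oracle
comparison uses 50 random G(n ≤ 7, 0.4) graphs with 10 restarts each.

## Known limitations

* The annealer is a serial single-chain implementation; no parallel
  tempering or spectral seriation alternatives.
* The FDR estimator is the plain ratio estimator; with 3 + 3 samples its
  permutation null is coarse (20 arrangements) and estimates at small
  cutoffs are dominated by the identity/mirror floor.
* `exhaustive_order` is factorial-time and guarded at N ≤ 10.
* The preprocessing chain does not parse vendor feature-extraction files
  and performs no background subtraction or spatial correction.
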