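# Methods

## Model

A Boolean network (BN) on `n` genes assigns each gene `i` a Boolean
update function `f_i` of an ordered set `W_i` of `k` regulators; all
genes update synchronously, so the network is a deterministic self-map
on the `N = 2^n` states. States are encoded with the first-listed gene
as the most significant bit (so `010000 → 16` for six genes), and truth
table rows likewise encode the first-listed regulator as the MSB.

Modelling assumptions, all biologically motivated and all operative in
the code:

1. **Sparsity** — connectivity restricted to `k` regulators per gene
   (default 3), seeded from prior pathway knowledge; slots without prior
   support are *free* and can be optimised against the data.
2. **Robustness** — networks should be coherent: the coherency of a
   state is the fraction of its `n` Hamming-1 neighbours in the same
   basin of attraction; the network coherency is the mean over all `2^n`
   states (attractor states included — the alternative of excluding them
   is not meaningfully different at these sizes and the inclusive mean
   is canonical here). Constant maps score 1, the identity map 0.
3. **Small attractors** — deterministic synchronous BNs always settle
   into cycles; biologically plausible networks have few, short ones.
   Rejection sampling in the generator and the reporting in
   `InferenceResult` reflect this.
4. **Consistency** — among feasible completions, lower data
   inconsistency is preferred: per gene, `(1/L) Σ_rows min(y(0), y(1))`
   where `y(b)` counts observed next-step values `b` for that
   regulator-row over the `L` *distinct* transitions.

## Inference procedure

Given one or more transition sequences and a wiring:

1. **Tally** — every distinct consecutive pair `(S_t, S_{t+1})`
   (duplicates dropped within and across sequences) increments, for each
   gene, the counter at the row encoded by its regulators in `S_t` and
   the bucket given by its bit in `S_{t+1}`.
2. **Resolve** — each truth-table row takes the majority bucket;
   exact ties and never-observed rows take the gene's bit at the *steady
   state*, defined as the final observed time point of the primary
   sequence (not an attractor of the fitted network).
3. **Score** — for each observed state `S_i`, walk the fitted network
   forward (stopping when a generated state repeats; the start is
   excluded from the repeat check so a fixed point contributes its
   self-transition once) and count the visited states that appear among
   the later observations `{S_{i+1}, …, S_{L+1}}`, skipping off-path
   states rather than truncating. This *filter-and-continue* reading
   reproduces the worked example's score of 11 (per-start contributions
   3+3+2+2+1); truncate-at-first-miss does not.
   The reference maximum, `max_distinct_score`, scores the ideal
   successor map of the order-preserving deduplicated state list and
   equals `L(L+1)/2` on distinct-state paths.
4. **Refine** — when free wiring slots exist, they are resampled
   uniformly (no duplicate regulators within a gene) for up to
   `max_iters` iterations (default 100), keeping the best result by
   (score desc, raw inconsistency asc, coherency desc), stopping early
   at score = maximum with zero inconsistency. Fixed prior slots are
   never changed, even when no consistent network exists.

**Multi-path extension.** Paths with pairwise *distinct* terminal
attractors may be combined: the primary path SD₁ is the longest (ties
prefer a singleton attractor, then a seeded uniform choice); tallies
pool the distinct transitions of all paths; ties/unfilled rows use SD₁'s
steady state. The reported score/max are summed over paths.

A note on bounds: `score ≤ max_distinct_score` holds on distinct-state
paths (where both equal at most `L(L+1)/2`) and for the fitted networks
in practice, but is *not* a theorem for arbitrary networks on sequences
that revisit a state — a cyclic network can re-collect an earlier
observation (sequence `[a,b,a]` against the 2-cycle `a→b→a` scores 3
against a distinct-maximum of 1). Only the triangular bound
`score ≤ L(L+1)/2` is universal; the test suite asserts exactly that.

## Similarity ratio

A reference network's **paths** are: one per Garden-of-Eden state (STG
in-degree 0) — its distinct-state trajectory, which traverses transients
and then the attractor cycle exactly once — plus one path per attractor
cycle unreachable from every Garden-of-Eden state, started at the
cycle's smallest state. Paths through shared transient states are kept
per Garden-of-Eden state, without deduplication.

Each reference path with `L ≥ 1` transitions is scored on the candidate
with the inference scoring rule; a full match (`score = L(L+1)/2`)
contributes its score, anything less contributes `0.25 ·score`. The
ratio `R` divides the summed contributions by the summed maxima.
Zero-transition paths (isolated fixed points) are excluded from both
sums; if *every* path is zero-transition (the reference is a permutation
map), `R` is defined as 1 when the candidate preserves each of those
fixed points and 0 otherwise, preserving `R(bn, bn) = 1`.

`r_max` / `r_mean` enumerate combinations of `η` reference paths with
distinct terminal attractors (and at least `min_transitions` transitions
each), run multi-path inference on each combination with a given wiring
(the reference's own by default), and return the max / mean `R`. Above
`max_combinations` (default 200) a seeded subsample is used.

## Search-space analytics

Exact big-integer counts for the unconstrained (`N^N`) and constrained
(`C(n,k)^n·2^(n·2^k)`) model spaces; the fill probability of a fresh
truth-table cell at the `L`-th transition `(1−1/m)^{L−1}` (`m = 2^k`);
the expected filled-cell count `n·m(1−(1−1/m)^L)`; the residual search
space (also reported in log10, as the value overflows a double beyond
modest sizes); `L_ex` (reported as a real with its floor — the floor of
15.57 is the quoted 15); and the singleton-attractor fractions
`(N+1)^{N−1}/N^N` (all attractors fixed points — a count of rooted
forests over `N` labelled states) and `1/N` (exactly one attractor, a
fixed point — Cayley's `N^{N−1}` rooted trees over `N^N` maps). The
quoted "0.015" at `N = 64` is a truncation of `1/64 = 0.015625`; the
package reports full precision. Every formula has an exhaustive
(`N ≤ 6` self-map census, `m^L` ball-placement enumeration) or Monte
Carlo oracle beside it.

## Synthetic benchmark

The generator draws uniform regulator sets and i.i.d. fair-coin truth
table bits — the natural unstructured null; the original experiments'
generation recipe beyond "random networks with at least 4 attractors" is
unspecified, so uniformity is the documented choice. Benchmark shape
defaults to `n = 6, k = 3` with rejection sampling (budget 10⁴ draws)
for attractor constraints. Paths are noiseless Boolean trajectories into
attractors; the generator does **not** emulate measurement noise,
binarization error, asynchronous updates, or the population averaging of
microarray data. A green trend test therefore establishes that the
*algorithmic* pipeline recovers structure from few noiseless transitions
when connectivity is known — not performance on noisy continuous data.

Directional expectations verified on ≥50 seeded instances: mean `R_max`
non-decreasing in `η ∈ {1,2,3}`; true wiring beats random wiring;
the proposed method's single-path `R` at least matches a REVEAL baseline
fed the same best path. The originally reported per-network similarity values depend on a
specific reference network that is not available in machine-readable
form, so they cannot be reproduced exactly; the trends are the testable
content.

## Binarization

Per-gene exact Otsu: every midpoint between consecutive sorted unique
values is evaluated for between-class variance `w0·w1(μ0−μ1)²`; ties
take the smaller threshold; values above the threshold are ON. The
exact variant (not the 256-bin histogram classic) is used because six
time points cannot populate a histogram, and per-gene (not global)
thresholds because microarray genes have incomparable dynamic ranges.
A gene with identical values at every time point has no Otsu threshold;
`binarize` maps such genes to all-zeros with a warning by default
(`constant_policy="error"` restores strictness). The packaged HMEC
expression matrix is a synthetic stand-in constructed to binarize to the
published six-state binary trajectory; the raw intensities are not
redistributed.

## REVEAL baseline

For each target gene, predictor subsets of sizes 1..`k_max` are searched
in increasing size, lexicographic order; the first subset whose mutual
information with the target's next value equals the target's entropy
(tolerance 1e−9) is accepted — the determination criterion of the
original algorithm. Unobserved truth-table rows take the target's
overall majority value (ties → 0); undetermined targets (common with
five transitions) fall back to the best-MI subset, smallest and earliest
on ties — a documented guess, since the original method does not address
heavily under-determined data. Accepted sets are padded to a uniform
in-degree `k_max` with inert regulators so the result is an ordinary
`BooleanNetwork`. Transition pairs are used as-is (not deduplicated),
matching the original algorithm's use of the raw series.

## Numerical and degenerate-input choices

- Exhaustive state-space operations check a default cap of `n ≤ 20`
  (override explicitly).
- Attractor cycles are canonicalised to start at their smallest decimal
  state and sorted by it; basins partition the state space by
  construction.
- Transition sequences may be single-state (needed to represent isolated
  fixed points as paths); inference requires at least one transition.
- Self-regulation is permitted in wirings.
- Network equality compares induced successor maps, not encodings (two
  wirings with inert regulators can define the same dynamics).
- All randomness flows through `numpy.random.default_rng` seeds;
  inference, refinement, generation and subsampling are reproducible
  given (data, wiring, seed).

## Known limitations

- Synchronous, deterministic updates only; no probabilistic or
  asynchronous semantics, no perturbation analysis beyond coherency.
- Uniform in-degree `k` per network; regulation acts at lag 1 only, and
  `k` itself is not learned.
- Exhaustive attractor/coherency analysis is exponential in `n`;
  practical well below the `n ≤ 20` cap.
- The similarity ratio depends on the path decomposition of the
  *reference* network; it is not symmetric and is not a metric.
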