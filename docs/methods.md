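# Methods

## Model

Sequences are modelled as iid uniform letters over an alphabet A (binary
r/y for DNA, after mapping purines to r and pyrimidines to y), evolving by
independent per-position substitutions. Under this model, a set Q of n
distinct length-k words samples a fraction n/|A|^k of positions (sparsity
s = |A|^k/n), and the probability H_x that a run of x consecutive start
positions contains at least one sampled position equals the probability
that some word of Q occurs in a random sequence of length x + k − 1.

H_x is computed by a suffix-state dynamic program over counts C(i, w) of
avoiding sequences ending in each length-k word w. The DP is carried in
exact integer counts with a single rational division per run size, so all
word-set profiles are exact `Fraction`s; the optimizer uses an equivalent
float DP over state probabilities (verified against the exact path to
1e−14). States are indexed as base-|A| integers; memory is |A|^k, which
bounds practical word lengths at about k = 16 for the binary alphabet. The
sequence length x + k − 1 is guarded at 64 by default; the guard is a
configurable knob (`max_seq_len`), not a hard limit.

An independent oracle — exhaustive enumeration of all |A|^(x+k−1)
sequences — is part of the public API (`brute_force_hit_count`) and the
test suite asserts exact DP/oracle agreement for *every* nonempty binary
word set with k ≤ 3 and x ≤ 6, plus seeded random k = 4 sets.

## Separation analysis

Minimum separation is the smallest shift δ at which two words of Q can
co-occur (suffix/prefix compatibility); it equals k when no proper overlap
is possible. Maximum separation is defined over bi-infinite sequences,
excluding end effects: on the order-(k−1) de Bruijn graph whose edges are
the k-mers *not* in Q, a surviving cycle means some sequence avoids Q
forever (maximum separation ∞, the set is not a universal hitting set);
otherwise the answer is one more than the longest remaining path in edges.
A set with minimum separation b is polar at b and can contain no word with
period < b; this is asserted by direct period scan on random sets.

## Optimization

The objective is the weighted average of H_1 … H_u with weight d^(1−x) for
run size x: d = 1 is the plain average, d > 1 emphasizes short runs
(distant homology), d < 1 long runs (close homology). Weights are
normalized by default so scores are comparable across u; the argmax is
unaffected. Exact search enumerates all C(|A|^k, n) sets with exact
rational scores and reports *all* optima (ties are genuine); the
enumeration budget defaults to 2×10⁶ sets. The exact optima are reported
in their found orientation rather than yr-canonicalized, because the
yr-minimizing reversal maps reflection-equivalent optima onto each other
and would silently merge genuinely distinct ties (e.g. {ry} and {yr}).

Simulated annealing handles larger (k, n): the neighborhood replaces one
uniformly chosen word of Q with one uniformly chosen word outside it,
acceptance is Metropolis exp(Δ/T), cooling is geometric (default T₀ = 0.2,
factor 0.995, 20 000 steps, 4 restarts; all overridable). Scores are
cached per candidate set since the DP dominates the cost. The contract is
determinism given the seed and a final score never below the initial
random set's; no claim of global optimality is made.

At desk scale the weighted objective's directional effect appears as a
profile crossing rather than a separation-class change: for (k = 5, n = 8,
u = 7) the d = 4 optimum beats the d = 1/8 optimum on short runs and vice
versa on long runs, which the tests assert with frozen annealing seeds.
(Separation-class differentiation — a polar push-set versus a universal
pull-set of equal sparsity — emerges only at word lengths around k ≥ 9,
beyond exact enumeration; exhaustive checks at k ≤ 5 found the same set
optimal under all decays.)

## Syncmers

Subword hashes are modelled as iid continuous draws, so only relative
ranks matter and ties have probability zero (`classify_rank_window`
rejects tied ranks). Open syncmers (minimum j-mer at offset t, default
⌈w/2⌉) have density 1/w; closed syncmers (minimum first or last) 2/w;
d-fold down-sampling divides density by d and is modelled as an
independent keep event per window, which ignores the vanishingly rare case
of repeated k-mer content within a run.

Exact run-hitting probabilities are computed by divide and conquer on the
position of the minimum rank: conditioning on the global minimum of an
interval decides every window containing it (syncmer iff the minimum sits
at the scheme's offset), and the two flanks are independent uniform
sub-rankings, giving an O(L³) recursion in exact rationals for
L = x + w − 1 — far beyond the reach of L! permutation enumeration, which
is nevertheless retained as the independent oracle (guarded to L ≤ 10) and
asserted equal on the full small-parameter grid. Down-sampling enters as a
(1 − 1/d) survival factor per decided syncmer, i.e. inclusion–exclusion
over keep events. The Monte Carlo estimator draws uniform pseudo-hashes
per replicate and reports binomial standard errors.

## Downstream metrics

Sampled fraction of maximal exact matches between unrelated sequences:
(1 − p) Σ_{x≥1} H_x p^(x−1) with p the per-letter match probability (1/4
for uniform DNA). Because H_x ≤ 1, truncating after X terms drops at most
p^X; the series is cut at the first X with p^X < tol (default 10⁻¹²,
20 terms at p = 1/4).

Expected letter coverage: Σ_{x=1..m} H_x P_run(x), where P_run(x) is the
probability that exactly x of the m length-m windows covering a letter are
fully conserved, each letter independently conserved with probability q
(our parameterization of divergence). P_run is computed by exact
enumeration of the 2^(2m−1) conservation patterns (vectorized, guarded at
m ≤ 12). P_run is normalized over x = 0..m and the coverage sum starts at
x = 1, which reproduces the m = 1 closed form H_1·q. Conserved windows
overlapping one letter are necessarily consecutive, so the run-hitting
probability applies; the tests verify the formula against direct
letter-coverage simulation on mutated pairs.

Distance distribution: conditioned on a word occurrence starting at the
origin of an iid sequence (each word of Q equally likely), a renewal-style
DP tracks the last k letters and the absence of intervening occurrences;
P(D = d) is the mass entering Q at step d. The DP runs to a fixed d_max or
adaptively until the un-renewed mass falls below 10⁻¹² (it decays
geometrically for every set). Mean and variance are of the truncated
distribution; the mean recovers the sparsity s up to the tail. Within each
(k, n), ordering sets by the u = 32 average of H_x agrees with ordering by
negative distance variance in an exhaustive k ≤ 3, n ≤ 4 check (4389
pairs, zero inversions); this equivalence is asymptotic in u, and u = 32
proved large enough at that scale.

## Sequence application and synthetic data

Coordinates are 0-based half-open, forward strand only; BED intervals are
[i, i+k). Windows overlapping a masked (non-ACGT) letter are never
sampled and never shift coordinates. Word membership is a lookup table of
size |A|^k, evaluated with vectorized rolling window codes.

The synthetic generator draws iid uniform letters (the model's null) and
derives related sequences by independent substitutions: conserved with
probability q, else a uniformly chosen different letter. It deliberately
emulates only the model — no indels, no GC skew, no repeats, no cg
hypermutability — so simulation/theory agreement validates the
implementation, not the model's fit to real genomes. Real-DNA behaviour
(sparsity drift in AT-rich genomes, repeat-driven specificity loss) is
probed only qualitatively, by salting synthetic sequences with
microsatellite repeats and comparing repeat-containing versus
repeat-avoiding words of equal sparsity.

Maximal exact matches between two sequences are enumerated by anchoring
shared m-mers (sorted-array join), grouping anchors into maximal diagonal
runs; a MEM is "sampled" when any of its match start positions is sampled
in the first sequence (match content is identical in both sequences, so
one-sided sampling is sufficient). A quadratic-time scan is the oracle at
small scale. Both raw sampled match counts and maximal-match counts are
exposed, since conventions differ on de-duplicating matches within a run.

## Problem sizes and numerical choices

Test and verification workloads are sized for quick, repeatable runs:
megabase sequences for sparsity and run-hitting frequency checks, 3×10⁵
letter pairs (≈ 7.7×10⁵ maximal matches) for empirical sampled-fraction
checks, 10⁵ replicates for Monte Carlo syncmer estimates, annealing
verification on state spaces small enough for exact cross-checks. All
stochastic checks use fixed seeds and 3-standard-error tolerances (5 SD
for simple letter-frequency checks); standard errors for overlapping-window
statistics are computed on disjoint blocks wider than the dependence range.

## Known limitations

* The rank model for syncmers ignores hash collisions and repeated
  subwords; real hash functions over short j-mers will deviate.
* Annealing schedules are not tuned per problem; for large k the default
  step count may be far from the achievable optimum.
* Maximal-match enumeration is ungapped and forward-strand only.
* The grid scheme's profile uses min(x/s, 1)/s throughout: the value 1/s at
  x = s (the flatline) is kept in preference to the alternative reading
  that the scheme is optimal up to x = s, with which it is inconsistent at
  that single point.
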