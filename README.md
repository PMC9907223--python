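# wordsample

Optimal word-based sampling of DNA sequences.

Large-scale sequence comparison rarely looks at every position: it samples a
subset of positions in each sequence and finds seed matches only there.
`wordsample` is a toolkit for designing and evaluating such sampling schemes
— minimally overlapping word sets, syncmers, every-*s*th and grid sampling —
around a single quantity: the **run-hitting probability**.

Related sequences share *runs* of overlapping exact matches. A scheme that
samples positions where any member of a set *Q* of *n* length-*k* words
occurs (over the purine/pyrimidine alphabet {r, y} by default, a/g → r,
c/t → y) hits a run of *x* consecutive start positions with probability

    H_x = 1 − Σ_w C(x+k−1, w) / |A|^(x+k−1)

where C(i, w) counts the length-*i* sequences that avoid *Q* and end in *w*:

    C(k, w)   = 0 if w ∈ Q, else 1
    C(i+1, w) = 0 if w ∈ Q, else Σ_{a∈A} C(i, a ⊕ w′)     (w′ = w minus its last letter)

The scheme's sparsity is s = |A|^k / n (one sample per *s* positions on
average), and no scheme of sparsity *s* can beat H_x ≤ min(x/s, 1).
Maximizing the (weighted) average of H_1 … H_u over word sets yields schemes
that provably maximize one-hit sensitivity for randomly evolving sequences;
the same H_x values feed the sampled-fraction of maximal exact matches
between unrelated sequences (specificity), the expected letter coverage of
true alignments, and the distribution of distances between samples.

The package provides:

* `wordsample.words` — word sets, r/y encoding, yr-minimizing reversal, and
  min/max separation analysis (polar sets vs universal hitting sets);
* `wordsample.hitprob` — the exact DP above, a brute-force enumeration
  oracle, the upper bound, every-*s*th and grid reference schemes, and
  weighted objectives;
* `wordsample.optimize` — exact enumeration of optimal word sets, and
  simulated annealing for larger (k, n);
* `wordsample.syncmers` — open/closed syncmers under the random-hash-rank
  model: densities and exact or Monte Carlo run-hitting probabilities,
  including down-sampling;
* `wordsample.metrics` — sampled maximal-exact-match fraction, expected
  letter coverage, sampling-distance distributions;
* `wordsample.seqsample` — apply schemes to FASTA sequences (BED output),
  empirical sparsity/run-hitting/match counting, and the synthetic-sequence
  generators used by every simulation check;
* `wordsample.cli` — all of the above as `wordsample <subcommand>`.

## Worked example

The two 1-in-4 schemes "sample positions where `ry` occurs" and "… where
`rr` occurs" have the same density but different run-hitting probabilities,
because `ry` cannot overlap itself at shift 1:

```sh
$ printf 'ry\n' > ry.txt
$ wordsample hitprob --words ry.txt --u 3
x       hit_prob        upper_bound     deficit
1       0.25            0.25            0
2       0.5             0.5             0
3       0.6875          0.75            0.0625
```

H_2 = 1/2 for `ry` versus 3/8 for `rr`: a run of two overlapping matches is
hit whenever the word occurs in a length-3 sequence, and the quarter of
sequences starting with `ry` is disjoint from the quarter ending with `ry`,
while for `rr` those quarters overlap. The same asymmetry shows up
downstream — the fraction of maximal exact matches between unrelated random
DNA that each scheme samples:

```sh
$ wordsample specificity --words ry.txt --p 0.25
{ ... "fraction": 0.3270432..., "fraction_3dp": 0.327 }
```

giving 0.327 for `ry`, 0.291 for `rr`, and 0.332 for the theoretical upper
bound (attained by every-fourth positional sampling). Exact optimization
recovers the non-overlapping words as the best single 2-letter words:

```sh
$ wordsample optimize --k 2 --n 1 --u 2 --mode exact
# optimum 1
ry
# optimum 2
yr
```

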