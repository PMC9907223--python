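"""Downstream quality metrics of sampling schemes.

Three quantities connect run-hitting probabilities to what a seed-and-extend
or alignment-free pipeline actually experiences:

* the *specificity fraction*: the expected fraction of maximal exact matches
  between unrelated random sequences that get sampled,
  (1 - p) * sum_{x>=1} H_x p^(x-1), where p is the per-letter match
  probability (1/4 for DNA);
* the *expected coverage*: sum_{x=1..m} H_x P_run(x), proportional to the
  probability that one letter of a true alignment is covered by a sampled
  match, where P_run(x) is the probability that exactly x length-m matches
  overlap the letter under per-letter conservation probability q;
* the *distance distribution* between consecutive sampled positions of a
  word set in an iid sequence, whose variance the large-u average-hitting
  objective effectively minimizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

from .hitprob import HitProfile, run_hit_profile, upper_bound_profile
from .words import WordSet


@dataclass(frozen=True)
class MatchModel:
    """Match statistics parameters.

    p: probability that an exact match extends by one letter between
    unrelated sequences (1/4 for uniform DNA).  m: match (seed) length.
    q: per-letter conservation probability between related sequences.
    """

    p: float = 0.25
    m: int = 1
    q: float = 1.0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("need 0 < p < 1")
        if self.m < 1:
            raise ValueError("need m >= 1")
        if not 0 <= self.q <= 1:
            raise ValueError("need 0 <= q <= 1")


def _as_hx(scheme) -> Callable[[int], float]:
    """Coerce a word set, profile, or callable into an H_x accessor that can
    be evaluated at any run size x."""
    if isinstance(scheme, WordSet):
        cache = {}

        def hx(x: int, ws=scheme) -> float:
            if x not in cache:
                prof = run_hit_profile(ws, x, max_seq_len=x + ws.k)
                for i, p in enumerate(prof.probabilities, start=1):
                    cache[i] = float(p)
            return cache[x]

        return hx
    if isinstance(scheme, HitProfile):
        return lambda x: float(scheme.h(x))
    if callable(scheme):
        return lambda x: float(scheme(x))
    raise TypeError(f"cannot interpret {type(scheme)} as a hit profile")


def specificity_fraction(scheme, p: float = 0.25, tol: float = 1e-12) -> float:
    """Expected fraction of maximal exact matches between unrelated random
    sequences that get sampled: (1 - p) * sum_{x>=1} H_x p^(x-1).

    ``scheme`` may be a WordSet (H_x computed by the DP on demand), a
    HitProfile long enough for the truncation, or a callable x -> H_x.
    The series is truncated at the first X with analytic tail bound
    p^X < tol (H_x <= 1 makes the dropped tail at most p^X).
    """
    if not 0 < p < 1:
        raise ValueError("need 0 < p < 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    hx = _as_hx(scheme)
    nterms = max(1, math.ceil(math.log(tol) / math.log(p)))
    total = 0.0
    px = 1.0  # p^(x-1)
    for x in range(1, nterms + 1):
        total += hx(x) * px
        px *= p
    return (1 - p) * total


@dataclass(frozen=True)
class RunCountDistribution:
    """P_run(x): probability that exactly x length-m matches overlap one
    letter, for per-letter conservation probability q."""

    probabilities: tuple  # index 0..m
    m: int
    q: float

    def p(self, x: int) -> float:
        return self.probabilities[x] if 0 <= x <= self.m else 0.0


def run_count_distribution(model: MatchModel, exact_limit: int = 12) -> RunCountDistribution:
    """Distribution of the number of matches overlapping one letter.

    A letter of the alignment is overlapped by m candidate length-m windows;
    a window is a match iff all its m letters are conserved.  Exact mode
    enumerates all conservation patterns of the 2m - 1 letters those windows
    span, each letter conserved independently with probability q.  Guarded
    to m <= ``exact_limit`` (2^(2m-1) patterns).
    """
    m, q = model.m, model.q
    if m > exact_limit:
        raise ValueError(f"exact enumeration guarded to m <= {exact_limit}")
    nletters = 2 * m - 1
    patterns = np.arange(1 << nletters, dtype=np.uint32)
    window_mask = np.uint32((1 << m) - 1)
    counts = np.zeros(patterns.shape, dtype=np.int16)
    for i in range(m):
        mask = np.uint32(int(window_mask) << i)
        counts += (patterns & mask) == mask
    ones = np.bitwise_count(patterns).astype(np.float64)
    with np.errstate(divide="ignore"):
        weights = np.power(q, ones) * np.power(1 - q, nletters - ones)
    probs = np.bincount(counts, weights=weights, minlength=m + 1)
    return RunCountDistribution(tuple(probs), m, q)


def expected_coverage(profile, model: MatchModel) -> float:
    """sum_{x=1..m} H_x P_run(x): proportional to the probability one letter
    of a true alignment is covered by a sampled match.  ``profile`` must
    reach run size m."""
    hx = _as_hx(profile)
    if isinstance(profile, HitProfile) and profile.u < model.m:
        raise ValueError(f"profile reaches u={profile.u} < match length m={model.m}")
    dist = run_count_distribution(model)
    return float(sum(hx(x) * dist.p(x) for x in range(1, model.m + 1)))


@dataclass(frozen=True)
class DistanceDistribution:
    """Distribution of the distance D between consecutive sampled positions
    of a word set in an iid uniform sequence, conditioned on a sample at the
    origin.  Truncated at d_max; ``tail`` is the remaining mass."""

    probabilities: tuple  # P(D = d) for d = 1..d_max
    tail: float
    mean: float
    variance: float

    @property
    def d_max(self) -> int:
        return len(self.probabilities)

    def p(self, d: int) -> float:
        return self.probabilities[d - 1] if 1 <= d <= self.d_max else 0.0


def distance_distribution(
    ws: WordSet, d_max: int | None = None, tail_tol: float = 1e-12
) -> DistanceDistribution:
    """Distance to the next sampled position, by conditional DP.

    Condition on a word occurrence starting at position 0 of an iid uniform
    sequence (each word of Q equally likely there); extend one letter at a
    time tracking the last k letters and whether a new occurrence has
    started.  P(D = d) is the probability the first later occurrence starts
    at d.  When ``d_max`` is None the DP runs until the remaining mass drops
    below ``tail_tol`` (the tail decays geometrically for any set).  Mean
    and variance are of the truncated distribution; the mean approaches the
    sparsity s = |A|^k / n as the tail vanishes.
    """
    a = len(ws.alphabet)
    k = ws.k
    nstates = a**k
    in_q = np.zeros(nstates, dtype=bool)
    q_idx = np.asarray(ws.word_indices(), dtype=np.intp)
    in_q[q_idx] = True
    state = np.zeros(nstates)
    state[q_idx] = 1.0 / len(q_idx)
    shift = a ** (k - 1)
    prev_idx = np.arange(nstates) // a
    probs = []
    d = 0
    limit = d_max if d_max is not None else 10**7
    while d < limit:
        d += 1
        nxt = np.zeros(nstates)
        for letter in range(a):
            nxt += state[letter * shift + prev_idx]
        nxt /= a
        hit = nxt[in_q].sum()
        probs.append(float(hit))
        nxt[in_q] = 0.0
        state = nxt
        remaining = state.sum()
        if d_max is None and remaining < tail_tol:
            break
    tail = float(state.sum())
    p = np.asarray(probs)
    dd = np.arange(1, len(p) + 1)
    mean = float((p * dd).sum())
    var = float((p * dd**2).sum() - mean**2)
    return DistanceDistribution(tuple(probs), tail, mean, var)
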