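"""Run-hitting probabilities of sampling schemes.

Related sequences share runs of overlapping exact matches; a sampling scheme
is sensitive when it is likely to select at least one start position of each
run.  For a run of x consecutive start positions in an iid uniform sequence,
the *run-hitting probability* H_x of a word set Q is the probability that
some word of Q occurs in a sequence of length x + k - 1.

H_x is computed by dynamic programming over suffix states.  Let C(i, w) be
the number of length-i sequences that contain no word of Q and end in the
length-k word w.  Then

    C(k, w)     = 0 if w in Q else 1
    C(i + 1, w) = 0 if w in Q else sum_a C(i, a + w[:-1])
    H_x         = 1 - sum_w C(x + k - 1, w) / |A|^(x + k - 1)

The DP is carried out in exact integer counts, so small-alphabet profiles
are exact rationals; a float path exists for the optimizer's inner loop.

Analytic (non-word-based) reference schemes live here too: the universal
upper bound min(x/s, 1), which every-sth positional sampling attains, and
the two-coordinate grid scheme whose hitting probability flatlines at 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Sequence

import numpy as np

from .words import WordSet

#: default guard on the DP sequence length x + k - 1 (configurable per call)
DEFAULT_MAX_SEQ_LEN = 64

#: guard on exhaustive enumeration size |A|^length
BRUTE_FORCE_LIMIT = 2**24


@dataclass(frozen=True)
class HitProfile:
    """Run-hitting probabilities (H_1 ... H_u) of a sampling scheme.

    ``probabilities`` holds H_x for x = 1..u (exact ``Fraction`` entries or
    floats depending on how it was built); ``sparsity`` is the expected
    number of positions per sampled position, s = |A|^k / n for word-based
    schemes.  ``stderr`` carries per-entry standard errors for Monte Carlo
    estimates, else None.
    """

    probabilities: tuple
    sparsity: object
    label: str = ""
    stderr: tuple | None = None

    @property
    def u(self) -> int:
        return len(self.probabilities)

    def h(self, x: int):
        """H_x, 1-based in the run size x."""
        if not 1 <= x <= self.u:
            raise IndexError(f"run size {x} outside 1..{self.u}")
        return self.probabilities[x - 1]

    def as_floats(self) -> np.ndarray:
        return np.array([float(p) for p in self.probabilities])

    def upper_bound(self) -> np.ndarray:
        s = float(self.sparsity)
        x = np.arange(1, self.u + 1)
        return np.minimum(x / s, 1.0)

    def to_frame(self):
        """TSV-ready table: x, hit probability, upper bound, deficit."""
        import pandas as pd

        h = self.as_floats()
        ub = self.upper_bound()
        return pd.DataFrame(
            {"x": np.arange(1, self.u + 1), "hit_prob": h,
             "upper_bound": ub, "deficit": ub - h}
        )


def run_hit_profile(
    ws: WordSet, u: int, *, max_seq_len: int = DEFAULT_MAX_SEQ_LEN
) -> HitProfile:
    """Exact run-hitting probabilities H_1..H_u of a word set.

    Raises
    ------
    ValueError
        If u < 1, or u + k - 1 exceeds ``max_seq_len``.
    """
    if u < 1:
        raise ValueError(f"run-size limit u must be >= 1, got {u}")
    if u + ws.k - 1 > max_seq_len:
        raise ValueError(
            f"u + k - 1 = {u + ws.k - 1} exceeds the sequence-length limit "
            f"{max_seq_len}; raise max_seq_len to allow it"
        )
    a = len(ws.alphabet)
    k = ws.k
    nstates = a**k
    in_q = bytearray(nstates)
    for idx in ws.word_indices():
        in_q[idx] = 1
    # base case: length-k sequences
    counts = [0 if in_q[w] else 1 for w in range(nstates)]
    denom = a**k
    probs = [Fraction(denom - sum(counts), denom)]
    shift = a ** (k - 1)
    for _ in range(2, u + 1):
        nxt = [0] * nstates
        for w in range(nstates):
            if in_q[w]:
                continue
            prev = w // a
            tot = 0
            for letter in range(a):
                tot += counts[letter * shift + prev]
            nxt[w] = tot
        counts = nxt
        denom *= a
        probs.append(Fraction(denom - sum(counts), denom))
    return HitProfile(tuple(probs), ws.sparsity, label=f"words:k={k},n={ws.n}")


def run_hit_profile_float(ws_indices, k: int, a: int, u: int) -> np.ndarray:
    """Float DP over suffix-state probabilities; the optimizer's fast path.

    ``ws_indices`` are the words as base-``a`` integers.  Returns H_1..H_u.
    """
    nstates = a**k
    p = np.full(nstates, 1.0 / nstates)
    q = np.asarray(list(ws_indices), dtype=np.intp)
    p[q] = 0.0
    shift = a ** (k - 1)
    prev_idx = np.arange(nstates) // a
    out = np.empty(u)
    out[0] = 1.0 - p.sum()
    for x in range(1, u):
        nxt = np.zeros(nstates)
        for letter in range(a):
            nxt += p[letter * shift + prev_idx]
        nxt /= a
        nxt[q] = 0.0
        p = nxt
        out[x] = 1.0 - p.sum()
    return out


def brute_force_hit_count(ws: WordSet, length: int) -> int:
    """Number of length-``length`` sequences containing at least one word of
    the set, by exhaustive enumeration.  The independent oracle for the DP:
    H_x must equal ``brute_force_hit_count(ws, x + k - 1) / |A|^(x + k - 1)``.
    """
    a = len(ws.alphabet)
    if a**length > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"{a}^{length} sequences is beyond the enumeration guard"
        )
    words = ws.sorted_words()
    count = 0
    for tup in product(ws.alphabet, repeat=length):
        s = "".join(tup)
        if any(w in s for w in words):
            count += 1
    return count


def upper_bound_profile(s, u: int) -> HitProfile:
    """The universal bound H_x <= min(x/s, 1) on any scheme of sparsity s."""
    if s < 1:
        raise ValueError("sparsity must be >= 1")
    s = Fraction(s) if float(s).is_integer() else s
    probs = tuple(min(Fraction(x) / s, Fraction(1)) if isinstance(s, Fraction)
                  else min(x / s, 1.0) for x in range(1, u + 1))
    return HitProfile(probs, s, label=f"upper-bound:s={s}")


def every_sth_profile(s: int, u: int) -> HitProfile:
    """Every-sth positional sampling attains the upper bound exactly: it hits
    a run of x < s positions with probability x/s and longer runs surely."""
    p = upper_bound_profile(s, u)
    return HitProfile(p.probabilities, p.sparsity, label=f"every-sth:s={s}")


def grid_scheme_profile(s: int, u: int) -> HitProfile:
    """Matches whose start coordinates are divisible by s in *both* sequences.

    With a uniformly random diagonal offset, a run of x positions contains a
    coordinate divisible by s in the first sequence with probability
    min(x/s, 1), and the second coordinate also falls on the grid with
    probability 1/s, giving min(x/s, 1)/s: the hitting probability flatlines
    at 1/s for x >= s instead of reaching 1.
    """
    if s < 1:
        raise ValueError("sparsity must be >= 1")
    sf = Fraction(s)
    probs = tuple(min(Fraction(x) / sf, Fraction(1)) / sf for x in range(1, u + 1))
    return HitProfile(probs, sf, label=f"grid:s={s}")


@dataclass(frozen=True)
class Objective:
    """Weighted-average objective over run sizes 1..u.

    The weight of run size x is ``decay**(1 - x)``: it decreases by the
    factor ``decay`` for each unit increase in x.  ``decay`` > 1 emphasizes
    short runs (distantly related sequences), ``decay`` < 1 emphasizes long
    runs (closely related sequences), and ``decay`` = 1 is the plain average.
    """

    u: int
    decay: object = 1
    normalize: bool = True

    def __post_init__(self):
        if self.u < 1:
            raise ValueError("u must be >= 1")
        if not self.decay > 0:
            raise ValueError("decay must be positive")

    def weights(self, exact: bool = True):
        d = Fraction(self.decay) if exact and not isinstance(self.decay, float) \
            else float(self.decay)
        one = Fraction(1) if isinstance(d, Fraction) else 1.0
        w, out = one, []
        for _ in range(self.u):
            out.append(w)
            w = w / d
        return out


def objective_score(profile: HitProfile | Sequence, obj: Objective):
    """Weighted average sum_x weight_x * H_x over x = 1..u (normalized by the
    total weight unless ``obj.normalize`` is off)."""
    probs = profile.probabilities if isinstance(profile, HitProfile) else tuple(profile)
    if len(probs) < obj.u:
        raise ValueError(f"profile has {len(probs)} entries, objective needs {obj.u}")
    exact = isinstance(probs[0], Fraction)
    weights = obj.weights(exact=exact)
    total = sum(w * p for w, p in zip(weights, probs[: obj.u]))
    if obj.normalize:
        total = total / sum(weights)
    return total
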