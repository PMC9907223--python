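"""Syncmer schemes under the random-hash-rank model.

A length-k k-mer has w = k - j + 1 length-j subwords.  Hash each subword to
an integer; the k-mer is a *closed* syncmer if the minimum-hash subword is
the first or last one, and an *open syncmer with offset t* if the minimum is
at position t (1-based).  A d-fold *down-sampled* syncmer additionally
requires the whole-k-mer hash to fall in the lowest 1/d of its range.

We model the subword hashes as iid continuous draws, so only their relative
ranks matter (assuming the subword size j is large enough that ties are
rare).  Open syncmers then sample 1 in w positions and closed syncmers 2 in
w.  Run-hitting probabilities are computed exactly by a divide-and-conquer
over the position of the minimum rank, or by Monte Carlo over random rank
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np

from .hitprob import HitProfile


class TiedRanksError(ValueError):
    """Tied subword ranks: outside the continuous-hash model."""


@dataclass(frozen=True)
class SyncmerScheme:
    """An open or closed syncmer scheme.

    Parameters
    ----------
    k, j
        K-mer and subword lengths; w = k - j + 1 subwords per k-mer.
    kind
        "open" or "closed".
    offset
        1-based position t of the minimum subword, open syncmers only.
        Defaults to ceil(w/2), the offset that maximizes run-hitting
        probabilities.
    downsample
        d-fold thinning by whole-k-mer hash (1 = none).
    """

    k: int
    j: int
    kind: str = "open"
    offset: int | None = None
    downsample: int = 1

    def __post_init__(self):
        if not 1 <= self.j <= self.k:
            raise ValueError(f"need 1 <= j <= k, got j={self.j}, k={self.k}")
        if self.kind not in ("open", "closed"):
            raise ValueError(f"kind must be open or closed, got {self.kind!r}")
        if self.downsample < 1:
            raise ValueError("downsample factor must be >= 1")
        if self.kind == "open":
            t = self.offset if self.offset is not None else (self.w + 1) // 2
            if not 1 <= t <= self.w:
                raise ValueError(f"offset t={t} outside 1..{self.w}")
            object.__setattr__(self, "offset", t)
        elif self.offset is not None:
            raise ValueError("closed syncmers take no offset")

    @property
    def w(self) -> int:
        """Number of subwords per k-mer."""
        return self.k - self.j + 1

    @property
    def sparsity(self) -> Fraction:
        return 1 / syncmer_density(self)

    @property
    def label(self) -> str:
        t = f",t={self.offset}" if self.kind == "open" else ""
        ds = f",down={self.downsample}" if self.downsample > 1 else ""
        return f"{self.kind}-syncmer:w={self.w}{t}{ds}"


def classify_rank_window(ranks: Sequence, scheme: SyncmerScheme) -> bool:
    """Is a k-mer whose w subword ranks are ``ranks`` a syncmer?"""
    w = scheme.w
    if len(ranks) != w:
        raise ValueError(f"expected {w} ranks, got {len(ranks)}")
    if len(set(ranks)) != w:
        raise TiedRanksError("tied subword ranks are outside the rank model")
    arg = min(range(w), key=lambda i: ranks[i])
    if scheme.kind == "closed":
        return arg == 0 or arg == w - 1
    return arg == scheme.offset - 1


def syncmer_density(scheme: SyncmerScheme) -> Fraction:
    """Fraction of positions sampled: 1/w (open) or 2/w (closed), divided by
    the down-sampling factor."""
    w = scheme.w
    base = Fraction(1, w) if scheme.kind == "open" else Fraction(2, w)
    if scheme.kind == "closed" and w == 1:
        base = Fraction(1)  # single subword: first and last coincide
    return base / scheme.downsample


def _syncmer_window_at_min(scheme: SyncmerScheme, m: int, x: int) -> list[int]:
    """Window indices i (0-based, i <= x-1) that become syncmers when
    position m holds the minimum rank of an interval containing them."""
    w = scheme.w
    out = []
    if scheme.kind == "open":
        cands = [m - (scheme.offset - 1)]
    else:
        cands = [m, m - w + 1]
    for i in cands:
        if 0 <= i <= x - 1:
            out.append(i)
    return out


def syncmer_hit_profile_exact(scheme: SyncmerScheme, u: int) -> HitProfile:
    """Exact run-hitting probabilities H_1..H_u of a syncmer scheme.

    H_x is the probability, over a uniformly random ranking of the
    x + w - 1 subwords spanned by x consecutive k-mer windows, that at least
    one window is a (retained) syncmer.  Computed by recursing on the
    position of the minimum rank: windows containing the interval minimum
    are decided there (syncmer iff the minimum sits at the scheme's offset),
    and the two flanks are independent uniform sub-rankings.  Down-sampling
    retains each syncmer independently with probability 1/d, folded in as a
    (1 - 1/d) survival factor per decided syncmer.  All arithmetic is exact.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    w = scheme.w
    keep = Fraction(1, scheme.downsample)
    probs = []
    for x in range(1, u + 1):
        length = x + w - 1

        @lru_cache(maxsize=None)
        def no_hit(a: int, b: int, x=x) -> Fraction:
            # P(no retained syncmer among windows fully inside [a, b))
            if b - a <= 0:
                return Fraction(1)
            total = Fraction(0)
            for m in range(a, b):
                syncs = [
                    i
                    for i in _syncmer_window_at_min(scheme, m, x)
                    if a <= i and i + w <= b
                ]
                term = no_hit(a, m) * no_hit(m + 1, b)
                if syncs:
                    term *= (1 - keep) ** len(syncs)
                total += term
            return total / (b - a)

        probs.append(1 - no_hit(0, length))
    return HitProfile(tuple(probs), scheme.sparsity, label=scheme.label)


def _enumerate_hit_probability(scheme: SyncmerScheme, x: int) -> Fraction:
    """Brute-force oracle: enumerate all (x + w - 1)! rank permutations and,
    per permutation, apply inclusion-exclusion over the down-sampling keep
    events of its syncmer windows.  Guarded to x + w - 1 <= 10."""
    w = scheme.w
    length = x + w - 1
    if length > 10:
        raise ValueError("permutation enumeration guarded to x + w - 1 <= 10")
    keep = Fraction(1, scheme.downsample)
    total = Fraction(0)
    count = 0
    for perm in permutations(range(length)):
        count += 1
        nsync = sum(
            1
            for i in range(x)
            if classify_rank_window(perm[i : i + w], scheme)
        )
        # P(>=1 of nsync independent keeps) = 1 - (1-keep)^nsync
        total += 1 - (1 - keep) ** nsync
    return total / count


def syncmer_hit_profile_mc(
    scheme: SyncmerScheme, u: int, reps: int = 10_000, seed: int | None = None
) -> HitProfile:
    """Monte Carlo run-hitting probabilities with binomial standard errors.

    Each replicate draws iid uniform pseudo-hashes for the x + w - 1
    subwords (plus per-window keep events when down-sampled) and records
    whether any of the x windows is a retained syncmer.  Deterministic given
    the seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    w = scheme.w
    probs, errs = [], []
    for x in range(1, u + 1):
        hashes = rng.random((reps, x + w - 1))
        windows = np.lib.stride_tricks.sliding_window_view(hashes, w, axis=1)
        arg = windows.argmin(axis=2)  # (reps, x)
        if scheme.kind == "closed":
            is_sync = (arg == 0) | (arg == w - 1)
        else:
            is_sync = arg == scheme.offset - 1
        if scheme.downsample > 1:
            is_sync = is_sync & (rng.random((reps, x)) < 1.0 / scheme.downsample)
        hit = is_sync.any(axis=1)
        p = hit.mean()
        probs.append(float(p))
        errs.append(float(np.sqrt(p * (1 - p) / reps)))
    return HitProfile(
        tuple(probs), scheme.sparsity, label=scheme.label + ",mc", stderr=tuple(errs)
    )
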