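"""Search for word sets maximizing the (weighted) average run-hitting
probability.

Two modes, both fixing the word length k and the set size n:

* ``exact`` — evaluate every possible set of n length-k words and return all
  sets attaining the maximum objective (feasible only for small n);
* ``anneal`` — simulated annealing: swap one word in/out per step, Metropolis
  acceptance, geometric cooling, several restarts.  Deterministic given the
  seed; never returns a score below that of its random starting set.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Sequence

from .hitprob import Objective, objective_score, run_hit_profile, run_hit_profile_float
from .words import RY_ALPHABET, WordSet


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of a word-set search."""

    k: int
    n: int
    objective: Objective
    alphabet: tuple[str, ...] = RY_ALPHABET
    mode: str = "exact"
    seed: int | None = None
    steps: int = 20_000
    initial_temperature: float = 0.2
    cooling: float = 0.995
    restarts: int = 4
    exact_budget: int = 2_000_000

    def __post_init__(self):
        if self.n < 1 or self.n > len(self.alphabet) ** self.k:
            raise ValueError(
                f"n={self.n} infeasible for k={self.k} over {len(self.alphabet)} letters"
            )
        if self.mode not in ("exact", "anneal"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ExactSearchResult:
    optima: tuple[WordSet, ...]  # every maximizing set, lexicographic order
    score: Fraction


@dataclass(frozen=True)
class AnnealResult:
    best: WordSet
    score: float
    initial_score: float
    trace: tuple[float, ...]  # best score after each restart
    seed: int | None


def _all_words(alphabet: Sequence[str], k: int) -> list[str]:
    from itertools import product

    return ["".join(t) for t in product(alphabet, repeat=k)]


def enumerate_exact_optima(cfg: SearchConfig) -> ExactSearchResult:
    """All word sets of size n attaining the maximum objective score.

    The score is exact (rational arithmetic); ties are genuine ties.  Sets
    are returned with words sorted and the list ordered lexicographically.
    Raises ``ValueError`` when C(|A|^k, n) exceeds the configured budget —
    use anneal mode instead.
    """
    universe = _all_words(cfg.alphabet, cfg.k)
    total = comb(len(universe), cfg.n)
    if total > cfg.exact_budget:
        raise ValueError(
            f"exact enumeration of {total} sets exceeds budget "
            f"{cfg.exact_budget}; use mode='anneal'"
        )
    best_score: Fraction | None = None
    best_sets: list[tuple[str, ...]] = []
    for combo in combinations(universe, cfg.n):
        ws = WordSet(combo, alphabet=cfg.alphabet)
        score = objective_score(run_hit_profile(ws, cfg.objective.u), cfg.objective)
        if best_score is None or score > best_score:
            best_score = score
            best_sets = [combo]
        elif score == best_score:
            best_sets.append(combo)
    optima = tuple(WordSet(c, alphabet=cfg.alphabet) for c in sorted(best_sets))
    return ExactSearchResult(optima, best_score)


def simulated_annealing_search(cfg: SearchConfig) -> AnnealResult:
    """Heuristic search by simulated annealing.

    Each step replaces one uniformly chosen word of the current set with one
    uniformly chosen word outside it; the move is accepted if it does not
    lower the objective, else with probability exp(delta/T).  Temperature
    cools geometrically; the best set across all restarts is returned along
    with the per-restart best-score trace.  Objective evaluations are cached
    per candidate set (the DP dominates the cost).
    """
    universe = _all_words(cfg.alphabet, cfg.k)
    a = len(cfg.alphabet)
    pos = {c: i for i, c in enumerate(cfg.alphabet)}

    def word_index(wrd: str) -> int:
        v = 0
        for c in wrd:
            v = v * a + pos[c]
        return v

    obj = cfg.objective
    weights = [float(w) for w in obj.weights(exact=False)]
    wsum = sum(weights)
    cache: dict[frozenset, float] = {}

    def score_of(words: frozenset) -> float:
        try:
            return cache[words]
        except KeyError:
            h = run_hit_profile_float([word_index(w) for w in words], cfg.k, a, obj.u)
            s = float(sum(w * p for w, p in zip(weights, h)))
            if obj.normalize:
                s /= wsum
            cache[words] = s
            return s

    rng = random.Random(cfg.seed)
    best_words: frozenset | None = None
    best_score = -math.inf
    initial_score = None
    trace = []
    for _ in range(max(1, cfg.restarts)):
        current = frozenset(rng.sample(universe, cfg.n))
        cur_score = score_of(current)
        if initial_score is None:
            initial_score = cur_score
        restart_best, restart_best_score = current, cur_score
        t = cfg.initial_temperature
        outside = [w for w in universe if w not in current]
        for _ in range(cfg.steps):
            if not outside:  # n == |A|^k: nothing to swap
                break
            drop = rng.choice(sorted(current))
            add_i = rng.randrange(len(outside))
            add = outside[add_i]
            cand = (current - {drop}) | {add}
            cand_score = score_of(cand)
            delta = cand_score - cur_score
            if delta >= 0 or rng.random() < math.exp(delta / max(t, 1e-300)):
                outside[add_i] = drop
                current, cur_score = cand, cand_score
                if cur_score > restart_best_score:
                    restart_best, restart_best_score = current, cur_score
            t *= cfg.cooling
        trace.append(restart_best_score)
        if restart_best_score > best_score:
            best_words, best_score = restart_best, restart_best_score
    best = WordSet(best_words, alphabet=cfg.alphabet)
    return AnnealResult(best, best_score, initial_score, tuple(trace), cfg.seed)
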