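"""Word sets over a reduced alphabet, and their structural properties.

A word-based sampling scheme is defined by a set Q of n distinct length-k
words over a fixed alphabet A (by default the two-letter purine/pyrimidine
alphabet {r, y}).  The scheme samples every position of a sequence where a
word of Q starts.  This module holds the word-set container, the DNA -> r/y
encoder, the orientation heuristic that reverses a whole set to reduce its
total "yr" dinucleotide count, and the separation analysis that classifies a
set on the polar-set / universal-hitting-set spectrum:

* the *minimum separation* b is the smallest possible distance between two
  sampled positions over all sequences (a set whose samples are guaranteed
  to be >= b apart is a polar set at b);
* the *maximum separation* is the largest possible distance between
  consecutive sampled positions over bi-infinite sequences; it is finite
  exactly when the set is a universal hitting set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

RY_ALPHABET: tuple[str, str] = ("r", "y")
DNA_ALPHABET: tuple[str, str, str, str] = ("a", "c", "g", "t")

#: placeholder written at masked (non-encodable) positions
MASK_CHAR = "."

_PURINES = set("agAG")
_PYRIMIDINES = set("ctuCTU")


class WordSetError(ValueError):
    """Base class for malformed word-set input."""


class LengthMismatchError(WordSetError):
    """Words of differing lengths in one set."""


class DuplicateWordError(WordSetError):
    """The same word listed twice."""


class AlphabetError(WordSetError):
    """A character outside the declared alphabet."""


@dataclass(frozen=True)
class WordSet:
    """A set Q of n distinct length-k words over an ordered alphabet.

    Parameters
    ----------
    words
        The words; any iterable of equal-length strings.
    alphabet
        Ordered alphabet; defaults to the purine/pyrimidine pair ``("r", "y")``.
    """

    words: frozenset[str]
    alphabet: tuple[str, ...] = RY_ALPHABET

    def __init__(self, words: Iterable[str], alphabet: Sequence[str] = RY_ALPHABET):
        words = list(words)
        if not words:
            raise WordSetError("a word set must contain at least one word")
        seen: set[str] = set()
        for w in words:
            if w in seen:
                raise DuplicateWordError(f"duplicate word: {w!r}")
            seen.add(w)
        k = len(words[0])
        if k == 0:
            raise WordSetError("words must be non-empty")
        for w in words:
            if len(w) != k:
                raise LengthMismatchError(
                    f"word {w!r} has length {len(w)}, expected {k}"
                )
            for c in w:
                if c not in alphabet:
                    raise AlphabetError(f"character {c!r} not in alphabet {alphabet}")
        object.__setattr__(self, "words", frozenset(seen))
        object.__setattr__(self, "alphabet", tuple(alphabet))

    @property
    def k(self) -> int:
        """Word length."""
        return len(next(iter(self.words)))

    @property
    def n(self) -> int:
        """Number of words."""
        return len(self.words)

    @property
    def sparsity(self):
        """Expected positions per sampled position, s = |A|^k / n."""
        from fractions import Fraction

        return Fraction(len(self.alphabet) ** self.k, self.n)

    def sorted_words(self) -> list[str]:
        return sorted(self.words)

    def word_indices(self) -> list[int]:
        """Words encoded as base-|A| integers (first letter most significant)."""
        pos = {c: i for i, c in enumerate(self.alphabet)}
        base = len(self.alphabet)
        out = []
        for w in self.words:
            v = 0
            for c in w:
                v = v * base + pos[c]
            out.append(v)
        return sorted(out)

    def __iter__(self):
        return iter(self.sorted_words())

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return self.n


def parse_word_set(
    lines: Iterable[str], alphabet: Sequence[str] = RY_ALPHABET
) -> WordSet:
    """Parse a plain-text word list: one word per line, ``#`` comments, blank
    lines ignored, case-insensitive.  Word length k is inferred from the first
    word."""
    words = []
    for line in lines:
        line = line.split("#", 1)[0].strip().lower()
        if line:
            words.append(line)
    if not words:
        raise WordSetError("no words found in input")
    return WordSet(words, alphabet=alphabet)


def format_word_set(ws: WordSet) -> str:
    """Canonical text form: sorted, lowercase, one word per line."""
    return "\n".join(ws.sorted_words()) + "\n"


def encode_dna_to_ry(seq: str) -> tuple[str, list[bool]]:
    """Encode DNA to the purine/pyrimidine alphabet.

    a/g -> r, c/t/u -> y, case-insensitive.  Any other character is masked:
    it appears as ``.`` in the output and its validity flag is False.  Masked
    positions are never fatal; sampling windows that overlap one are simply
    skipped downstream.

    Returns
    -------
    (encoded, valid)
        The encoded string and a per-position validity mask.
    """
    out = []
    valid = []
    for c in seq:
        if c in _PURINES:
            out.append("r")
            valid.append(True)
        elif c in _PYRIMIDINES:
            out.append("y")
            valid.append(True)
        else:
            out.append(MASK_CHAR)
            valid.append(False)
    return "".join(out), valid


def count_dinucleotide(ws: WordSet, pair: str) -> int:
    """Total count of (overlapping) occurrences of a 2-letter ``pair`` across
    all words of the set."""
    if len(pair) != 2 or any(c not in ws.alphabet for c in pair):
        raise AlphabetError(f"pair must be 2 letters over {ws.alphabet}: {pair!r}")
    total = 0
    for w in ws.words:
        total += sum(1 for i in range(len(w) - 1) if w[i : i + 2] == pair)
    return total


def reverse_words(ws: WordSet) -> WordSet:
    """The set of all words reversed."""
    return WordSet([w[::-1] for w in ws.words], alphabet=ws.alphabet)


def reverse_to_minimize_yr(ws: WordSet) -> WordSet:
    """Reverse every word in the set if that strictly reduces the total "yr"
    count; otherwise return the set unchanged (ties keep the original
    orientation).

    Reversal leaves the run-hitting probabilities unchanged, but sets with
    fewer yr dinucleotides are preferable for vertebrate DNA, where cg->tg/ca
    substitutions make yr sites mutate faster than the independent-letters
    model assumes.
    """
    if ws.alphabet != RY_ALPHABET:
        return ws
    rev = reverse_words(ws)
    if count_dinucleotide(rev, "yr") < count_dinucleotide(ws, "yr"):
        return rev
    return ws


def min_separation(ws: WordSet) -> int:
    """Smallest possible distance between two sampled positions.

    This is the smallest shift delta >= 1 at which some word w2 can start
    delta positions after some word w1 in one sequence, i.e. the suffix of w1
    after delta letters equals the prefix of w2 of length k - delta.  For
    delta >= k any concatenation works, so the result is at most k.
    """
    k = ws.k
    words = ws.sorted_words()
    for delta in range(1, k):
        for w1 in words:
            suffix = w1[delta:]
            for w2 in words:
                if w2.startswith(suffix):
                    return delta
    return k


def max_separation(ws: WordSet) -> float:
    """Largest possible distance between consecutive sampled positions over
    bi-infinite sequences; ``math.inf`` if some sequence avoids the set
    forever.

    Computed on the order-(k-1) de Bruijn graph whose edges are the k-mers
    *not* in Q: an infinite unsampled stretch exists iff that graph has a
    cycle; otherwise the answer is 1 + the longest path (in edges), i.e. one
    more than the longest possible run of consecutive unsampled positions.
    """
    k = ws.k
    g = nx.DiGraph()
    # k=1 collapses to a single node with self-loop edges per unsampled letter
    from itertools import product

    for tail in product(ws.alphabet, repeat=k):
        kmer = "".join(tail)
        if kmer in ws.words:
            continue
        g.add_edge(kmer[:-1], kmer[1:])
    if g.number_of_edges() == 0:
        return 1
    if not nx.is_directed_acyclic_graph(g):
        return math.inf
    return 1 + nx.dag_longest_path_length(g)


@dataclass(frozen=True)
class SeparationReport:
    """Polar / universal-hitting-set classification of a word set."""

    min_separation: int
    max_separation: float  # math.inf when the set is not universal

    @property
    def is_polar_at(self) -> int:
        """Guaranteed minimum spacing b between samples."""
        return self.min_separation

    @property
    def is_universal(self) -> bool:
        """True iff every sufficiently long sequence is sampled at least once."""
        return math.isfinite(self.max_separation)

    def to_dict(self) -> dict:
        mx = "inf" if not self.is_universal else int(self.max_separation)
        return {
            "min_separation": self.min_separation,
            "max_separation": mx,
            "is_polar_at": self.is_polar_at,
            "is_universal": self.is_universal,
        }


def separation_report(ws: WordSet) -> SeparationReport:
    return SeparationReport(min_separation(ws), max_separation(ws))
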