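import random

import pytest

from wordsample import WordSet


@pytest.fixture
def ry():
    return WordSet(["ry"])


@pytest.fixture
def rr():
    return WordSet(["rr"])


@pytest.fixture
def four_word_set():
    """The canonical 4-word, length-4 example set."""
    return WordSet(["rrry", "ryrr", "ryyr", "yyyr"])


def random_word_sets(n_sets: int, max_k: int, seed: int = 0):
    """Seeded random r/y word sets with k <= max_k, n <= 2^k."""
    rng = random.Random(seed)
    out = []
    for _ in range(n_sets):
        k = rng.randint(1, max_k)
        universe = ["".join(rng_choices) for rng_choices in _all_words(k)]
        n = rng.randint(1, min(len(universe), 16))
        out.append(WordSet(rng.sample(universe, n)))
    return out


def _all_words(k: int):
    from itertools import product

    return product("ry", repeat=k)
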