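"""Applying sampling schemes to sequences, and synthetic data generation.

This module is the bridge between theory and practice: it applies word sets
to real or simulated DNA (FASTA in, BED out), measures empirical sparsity,
run-hitting frequency and match specificity, and generates the iid and
substitution-mutated sequences that every Monte Carlo oracle runs on.

Coordinates are 0-based half-open throughout; a sampled position i means the
k-window [i, i + k).  Only the forward strand is considered.  Windows that
overlap a masked (non-ACGT) position are never sampled.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .words import RY_ALPHABET, WordSet

_RY_CODE = np.full(256, -1, dtype=np.int8)
for _c in b"agAG":
    _RY_CODE[_c] = 0  # r
for _c in b"ctuCTU":
    _RY_CODE[_c] = 1  # y

_DNA_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"acgt"):
    _DNA_CODE[_c] = _i
    _DNA_CODE[_c - 32] = _i  # uppercase


@dataclass(frozen=True)
class SampledPositions:
    """Positions selected by a sampling scheme in one named sequence."""

    name: str
    positions: np.ndarray  # 0-based start positions, strictly increasing
    k: int
    scheme: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    def gaps(self) -> np.ndarray:
        """Distances between consecutive sampled positions."""
        return np.diff(self.positions)

    def to_bed(self) -> str:
        """BED intervals [i, i + k), one per sampled position."""
        lines = [f"{self.name}\t{i}\t{i + self.k}" for i in self.positions.tolist()]
        return "\n".join(lines) + ("\n" if lines else "")


def write_bed(sampled: SampledPositions, path) -> None:
    Path(path).write_text(sampled.to_bed())


def read_bed(path, scheme: str = "") -> SampledPositions:
    """Read BED intervals written by :func:`write_bed` (single sequence,
    uniform interval length)."""
    starts, ends, names = [], [], set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        names.add(f[0])
        starts.append(int(f[1]))
        ends.append(int(f[2]))
    if len(names) > 1:
        raise ValueError(f"expected a single sequence, found {sorted(names)}")
    k = {e - s for s, e in zip(starts, ends)}
    if len(k) > 1:
        raise ValueError("intervals have mixed lengths")
    return SampledPositions(
        names.pop() if names else "",
        np.asarray(sorted(starts), dtype=np.int64),
        k.pop() if k else 0,
        scheme=scheme,
    )


@dataclass(frozen=True)
class SequencePair:
    """An ancestor sequence and a derivative produced by independent
    per-position substitutions (no indels)."""

    ancestor: str
    derived: str
    conserved: np.ndarray  # bool per position
    q: float
    seed: int | None

    def __post_init__(self):
        if len(self.ancestor) != len(self.derived):
            raise ValueError("sequences must have equal length")


def generate_iid_sequence(length: int, alphabet: str = "acgt", seed=None) -> str:
    """An iid uniform random sequence; deterministic given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(np.asarray(list(alphabet))[idx])


def mutate_sequence(seq: str, q: float, seed=None, alphabet: str = "acgt") -> SequencePair:
    """Each position is conserved with probability q; otherwise substituted
    by a uniformly chosen *different* letter."""
    if not 0 <= q <= 1:
        raise ValueError("need 0 <= q <= 1")
    rng = np.random.default_rng(seed)
    letters = {c: i for i, c in enumerate(alphabet)}
    idx = np.asarray([letters[c] for c in seq], dtype=np.int64)
    conserved = rng.random(len(seq)) < q
    offset = rng.integers(1, len(alphabet), size=len(seq))
    new_idx = np.where(conserved, idx, (idx + offset) % len(alphabet))
    derived = "".join(np.asarray(list(alphabet))[new_idx])
    return SequencePair(seq, derived, conserved, q, seed)


def _encode_for_wordset(seq: str, ws: WordSet) -> np.ndarray:
    """Sequence letters as word-set alphabet indices, -1 where masked.

    DNA is r/y-encoded when the word set uses the r/y alphabet; otherwise
    letters map directly onto the set's alphabet (case-sensitive), with
    anything else masked.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    if ws.alphabet == RY_ALPHABET:
        codes = _RY_CODE[raw].astype(np.int64)
        # r/y literals are themselves valid input
        codes[raw == ord("r")] = 0
        codes[raw == ord("y")] = 1
        return codes
    table = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(ws.alphabet):
        table[ord(c)] = i
    return table[raw]


def _window_codes(codes: np.ndarray, k: int, base: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-``base`` codes of all k-windows and their validity."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid = codes >= 0
    win_valid = np.ones(n, dtype=bool)
    win_code = np.zeros(n, dtype=np.int64)
    safe = np.where(valid, codes, 0)
    for off in range(k):
        win_valid &= valid[off : off + n]
        win_code = win_code * base + safe[off : off + n]
    return win_code, win_valid


def sample_positions(seq: str, ws: WordSet, name: str = "seq") -> SampledPositions:
    """Positions where a word of the set occurs (after encoding), excluding
    windows that touch a masked letter.  Membership is a table lookup."""
    codes = _encode_for_wordset(seq, ws)
    base = len(ws.alphabet)
    win_code, win_valid = _window_codes(codes, ws.k, base)
    table = np.zeros(base**ws.k, dtype=bool)
    table[np.asarray(ws.word_indices(), dtype=np.intp)] = True
    hit = win_valid & table[win_code]
    return SampledPositions(
        name,
        np.nonzero(hit)[0].astype(np.int64),
        ws.k,
        scheme=f"words:k={ws.k},n={ws.n}",
    )


def every_sth_positions(seq: str, s: int, k: int = 1, offset: int = 0,
                        name: str = "seq") -> SampledPositions:
    """Positional every-sth sampling (the scheme attaining the upper bound)."""
    if s < 1:
        raise ValueError("s must be >= 1")
    n = len(seq) - k + 1
    pos = np.arange(offset % s, n, s, dtype=np.int64)
    return SampledPositions(name, pos, k, scheme=f"every-{s}th")


def count_valid_windows(seq: str, ws: WordSet) -> int:
    codes = _encode_for_wordset(seq, ws)
    _, win_valid = _window_codes(codes, ws.k, len(ws.alphabet))
    return int(win_valid.sum())


def empirical_sparsity(seq: str, ws: WordSet) -> float:
    """Valid k-windows per sampled position; compare with s = |A|^k / n."""
    sampled = sample_positions(seq, ws)
    if len(sampled) == 0:
        raise ValueError("no positions sampled: sparsity undefined")
    return count_valid_windows(seq, ws) / len(sampled)


def empirical_run_hit_profile(seq: str, ws: WordSet, u: int) -> "HitProfileEstimate":
    """Empirical run-hitting frequencies on one sequence.

    For each run size x, disjoint blocks of x consecutive window-start
    positions are independent trials (iid sequence letters barely leak
    across block boundaries); the estimate is the fraction of blocks
    containing at least one sampled position, with binomial standard error.
    """
    sampled = sample_positions(seq, ws)
    nwin = len(seq) - ws.k + 1
    hit = np.zeros(nwin, dtype=bool)
    hit[sampled.positions] = True
    probs, errs = [], []
    for x in range(1, u + 1):
        nblocks = nwin // x
        blocks = hit[: nblocks * x].reshape(nblocks, x)
        p = blocks.any(axis=1).mean()
        probs.append(float(p))
        errs.append(float(np.sqrt(p * (1 - p) / nblocks)))
    return HitProfileEstimate(tuple(probs), tuple(errs))


@dataclass(frozen=True)
class HitProfileEstimate:
    probabilities: tuple
    stderr: tuple

    def h(self, x: int) -> float:
        return self.probabilities[x - 1]

    def se(self, x: int) -> float:
        return self.stderr[x - 1]


# ---------------------------------------------------------------------------
# match counting between two sequences


def _mmer_codes(seq: str, m: int) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _DNA_CODE[raw].astype(np.int64)
    return _window_codes(codes, m, 4)


def _sampled_mask(seq: str, sampler, nwin: int) -> np.ndarray:
    """Boolean per window start: is this position sampled?  ``sampler`` is a
    WordSet or a SampledPositions/array of positions."""
    mask = np.zeros(nwin, dtype=bool)
    if isinstance(sampler, WordSet):
        pos = sample_positions(seq, sampler).positions
    elif isinstance(sampler, SampledPositions):
        pos = sampler.positions
    else:
        pos = np.asarray(sampler, dtype=np.int64)
    pos = pos[pos < nwin]
    mask[pos] = True
    return mask


def count_sampled_matches(seq1: str, seq2: str, sampler, m: int) -> int:
    """Number of position pairs (i, j) with identical length-m substrings
    where position i of seq1 is sampled.  Sampling is decided by the first k
    letters of the match, which are identical in both sequences, so sampling
    one side suffices."""
    c1, v1 = _mmer_codes(seq1, m)
    c2, v2 = _mmer_codes(seq2, m)
    mask = _sampled_mask(seq1, sampler, len(c1)) & v1
    targets = np.sort(c2[v2])
    lo = np.searchsorted(targets, c1[mask], side="left")
    hi = np.searchsorted(targets, c1[mask], side="right")
    return int((hi - lo).sum())


def _anchor_pairs(c1, v1, c2, v2) -> tuple[np.ndarray, np.ndarray]:
    """All index pairs (i, j) with c1[i] == c2[j], both valid, vectorized."""
    order2 = np.argsort(c2[v2], kind="stable")
    idx2 = np.nonzero(v2)[0][order2]
    sorted2 = c2[idx2]
    i_all = np.nonzero(v1)[0]
    lo = np.searchsorted(sorted2, c1[i_all], side="left")
    hi = np.searchsorted(sorted2, c1[i_all], side="right")
    counts = hi - lo
    ii = np.repeat(i_all, counts)
    # within-group offsets 0..counts-1 for each i, then add lo
    total = int(counts.sum())
    if total == 0:
        return ii, np.empty(0, dtype=np.int64)
    steps = np.ones(total, dtype=np.int64)
    starts = np.cumsum(counts)[:-1]
    steps[0] = 0
    nonzero_lo = np.repeat(lo, counts)
    offs = np.arange(total, dtype=np.int64) - np.repeat(
        np.concatenate(([0], starts)), counts
    )
    jj = idx2[nonzero_lo + offs]
    return ii, jj


def _mem_runs(seq1: str, seq2: str, m: int):
    """Maximal exact matches of length >= m, as runs of consecutive anchor
    m-mer pairs along a diagonal.

    Returns (run_id boundaries' order, ii sorted) — internally used; a MEM
    corresponds to one maximal run of anchors (i, j), (i+1, j+1), ...
    """
    c1, v1 = _mmer_codes(seq1, m)
    c2, v2 = _mmer_codes(seq2, m)
    ii, jj = _anchor_pairs(c1, v1, c2, v2)
    if len(ii) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    diag = jj - ii
    order = np.lexsort((ii, diag))
    ii, diag = ii[order], diag[order]
    new_run = np.ones(len(ii), dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (ii[1:] != ii[:-1] + 1)
    run_id = np.cumsum(new_run) - 1
    return ii, run_id


def count_maximal_matches(seq1: str, seq2: str, m: int) -> int:
    """Number of maximal exact matches of length >= m between two sequences
    (forward strand, ungapped)."""
    _, run_id = _mem_runs(seq1, seq2, m)
    return int(run_id[-1] + 1) if len(run_id) else 0


def count_sampled_maximal_matches(seq1: str, seq2: str, sampler, m: int) -> int:
    """Number of maximal exact matches (length >= m) that contain at least
    one sampled length-m match start.  Dividing by
    :func:`count_maximal_matches` estimates the specificity fraction."""
    ii, run_id = _mem_runs(seq1, seq2, m)
    if len(ii) == 0:
        return 0
    nwin = len(seq1) - m + 1
    mask = _sampled_mask(seq1, sampler, nwin)
    hits = np.bincount(run_id, weights=mask[ii].astype(np.float64))
    return int((hits > 0).sum())


def sampled_maximal_match_fraction(seq1: str, seq2: str, sampler, m: int):
    """(sampled MEMs, total MEMs, fraction) in one pass."""
    ii, run_id = _mem_runs(seq1, seq2, m)
    if len(ii) == 0:
        return 0, 0, float("nan")
    total = int(run_id[-1] + 1)
    nwin = len(seq1) - m + 1
    mask = _sampled_mask(seq1, sampler, nwin)
    hits = np.bincount(run_id, weights=mask[ii].astype(np.float64))
    sampled = int((hits > 0).sum())
    return sampled, total, sampled / total


def _mem_oracle(seq1: str, seq2: str, m: int) -> set[tuple[int, int, int]]:
    """Quadratic-time maximal-exact-match enumeration: the small-case oracle
    for the anchored implementation.  Returns {(i, j, length)}."""
    out = set()
    for d in range(-(len(seq1) - 1), len(seq2)):
        i = max(0, -d)
        j = i + d
        run = 0
        while i + run <= len(seq1) and j + run <= len(seq2):
            inside = i + run < len(seq1) and j + run < len(seq2)
            if inside and seq1[i + run] == seq2[j + run] and seq1[i + run] in "acgt":
                run += 1
                continue
            if run >= m:
                out.add((i, j, run))
            i, j = i + run + 1, j + run + 1
            run = 0
            if not inside:
                break
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) records; transparently handles .gz."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)
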