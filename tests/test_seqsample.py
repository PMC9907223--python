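import math

import numpy as np
import pytest

from wordsample import (
    WordSet,
    count_maximal_matches,
    count_sampled_matches,
    count_sampled_maximal_matches,
    empirical_run_hit_profile,
    empirical_sparsity,
    every_sth_positions,
    generate_iid_sequence,
    max_separation,
    min_separation,
    mutate_sequence,
    run_hit_profile,
    sample_positions,
    sampled_maximal_match_fraction,
)
from wordsample.seqsample import (
    SampledPositions,
    _mem_oracle,
    read_bed,
    read_fasta,
    write_bed,
)


class TestGenerate:
    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            generate_iid_sequence(0)

    def test_deterministic(self):
        assert generate_iid_sequence(500, seed=3) == generate_iid_sequence(500, seed=3)
        assert generate_iid_sequence(500, seed=3) != generate_iid_sequence(500, seed=4)

    def test_uniform_letter_frequencies(self):
        L = 100_000
        seq = generate_iid_sequence(L, seed=8)
        sd = math.sqrt(0.25 * 0.75 / L)
        for c in "acgt":
            assert abs(seq.count(c) / L - 0.25) < 5 * sd


class TestMutate:
    def test_q_extremes(self):
        seq = generate_iid_sequence(300, seed=1)
        same = mutate_sequence(seq, 1.0, seed=2)
        assert same.derived == seq and same.conserved.all()
        diff = mutate_sequence(seq, 0.0, seed=2)
        assert not diff.conserved.any()
        assert all(a != b for a, b in zip(seq, diff.derived))

    def test_conserved_fraction(self):
        L, q = 100_000, 0.9
        pair = mutate_sequence(generate_iid_sequence(L, seed=5), q, seed=6)
        sd = math.sqrt(q * (1 - q) / L)
        assert abs(pair.conserved.mean() - q) < 5 * sd
        # conserved flag is truthful
        agree = np.frombuffer(pair.ancestor.encode(), dtype=np.uint8) == (
            np.frombuffer(pair.derived.encode(), dtype=np.uint8))
        assert (agree == pair.conserved).all()

    def test_q_validation(self):
        with pytest.raises(ValueError):
            mutate_sequence("acgt", 1.5)


class TestSamplePositions:
    def test_hand_encoded_example(self, ry):
        # agct encodes to rryy: windows rr, ry, yy -> only position 1 sampled
        assert sample_positions("agct", ry).positions.tolist() == [1]

    def test_homopolymer_avoidance(self, ry):
        assert len(sample_positions("aaaa", ry)) == 0

    def test_full_universe_samples_every_valid_window(self):
        ws = WordSet(["rr", "ry", "yr", "yy"])
        seq = generate_iid_sequence(100, seed=0)
        assert sample_positions(seq, ws).positions.tolist() == list(range(99))

    def test_masked_windows_skipped(self, ry):
        # acgnacg -> ryr.ryr; windows touching the mask are unsampled
        pos = sample_positions("acgnacg", ry).positions.tolist()
        assert pos == [0, 4]

    def test_ry_literal_input(self, ry):
        assert sample_positions("ryry", ry).positions.tolist() == [0, 2]

    def test_gap_bounds(self):
        ws = WordSet(["rr", "yy", "ry"])  # min sep 1, max sep 2
        seq = generate_iid_sequence(5000, seed=2)
        gaps = sample_positions(seq, ws).gaps()
        assert gaps.min() >= min_separation(ws)
        assert gaps.max() <= max_separation(ws)

    def test_min_separation_always_respected(self, four_word_set):
        seq = generate_iid_sequence(20_000, seed=9)
        gaps = sample_positions(seq, four_word_set).gaps()
        assert len(gaps) and gaps.min() >= min_separation(four_word_set)


class TestBed:
    def test_round_trip(self, tmp_path, ry):
        seq = generate_iid_sequence(300, seed=4)
        sampled = sample_positions(seq, ry, name="chrSim")
        path = tmp_path / "out.bed"
        write_bed(sampled, path)
        back = read_bed(path)
        assert back.name == "chrSim"
        assert back.k == ry.k
        assert np.array_equal(back.positions, sampled.positions)

    def test_bed_is_half_open_k_windows(self, ry):
        sp = SampledPositions("s", np.array([3, 7]), 2)
        assert sp.to_bed() == "s\t3\t5\ns\t7\t9\n"


class TestSparsity:
    def test_full_universe(self):
        ws = WordSet(["rr", "ry", "yr", "yy"])
        assert empirical_sparsity(generate_iid_sequence(1000, seed=1), ws) == 1.0

    def test_no_samples_is_an_error(self):
        with pytest.raises(ValueError):
            empirical_sparsity("cccccc", WordSet(["rr"]))

    def test_iid_sparsity_near_theoretical(self, ry):
        seq = generate_iid_sequence(100_000, seed=21)
        assert empirical_sparsity(seq, ry) == pytest.approx(4.0, rel=0.05)


class TestEmpiricalRunHits:
    def test_matches_theory_within_3se(self, four_word_set):
        seq = generate_iid_sequence(200_000, seed=17)
        prof = run_hit_profile(four_word_set, 5).as_floats()
        emp = empirical_run_hit_profile(seq, four_word_set, 5)
        for x in range(1, 6):
            assert abs(emp.h(x) - prof[x - 1]) <= 3 * emp.se(x)


class TestMatchCounting:
    def test_no_shared_mmers(self, ry):
        assert count_sampled_matches("acgtacgt", "gggggggg", ry, 4) == 0

    def test_identical_sequences_full_universe(self):
        ws = WordSet(["rr", "ry", "yr", "yy"])
        seq = generate_iid_sequence(200, seed=3)
        m = 6
        assert count_sampled_matches(seq, seq, ws, m) >= len(seq) - m + 1

    def test_poisson_expectation(self, ry):
        # two unrelated iid sequences: E[count] = L1*L2*(1/4)^m * density
        L, m = 30_000, 8
        counts = []
        for seed in range(4):
            s1 = generate_iid_sequence(L, seed=100 + seed)
            s2 = generate_iid_sequence(L, seed=200 + seed)
            counts.append(count_sampled_matches(s1, s2, ry, m))
        expected = L * L * 0.25**m * 0.25
        mean = np.mean(counts)
        sd = math.sqrt(expected / len(counts))  # Poisson-ish
        assert abs(mean - expected) < 3 * sd


class TestMaximalMatches:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_enumeration_matches_quadratic_oracle(self, seed, ry):
        s1 = generate_iid_sequence(250, seed=seed)
        s2 = generate_iid_sequence(250, seed=50 + seed)
        m = 3
        oracle = _mem_oracle(s1, s2, m)
        assert count_maximal_matches(s1, s2, m) == len(oracle)
        pos = set(sample_positions(s1, ry).positions.tolist())
        expect = sum(
            1
            for (i, j, L) in oracle
            if any(p in pos for p in range(i, i + L - m + 1))
        )
        assert count_sampled_maximal_matches(s1, s2, ry, m) == expect

    def test_full_universe_fraction_is_one(self):
        ws = WordSet(["rr", "ry", "yr", "yy"])
        s1 = generate_iid_sequence(2000, seed=5)
        s2 = generate_iid_sequence(2000, seed=6)
        _, _, frac = sampled_maximal_match_fraction(s1, s2, ws, 5)
        assert frac == 1.0

    def test_positional_sampler_accepted(self):
        s1 = generate_iid_sequence(5000, seed=7)
        s2 = generate_iid_sequence(5000, seed=8)
        pos = every_sth_positions(s1, 4, k=5).positions
        sampled, total, frac = sampled_maximal_match_fraction(s1, s2, pos, 5)
        assert 0 < sampled <= total


class TestFasta:
    def test_read_plain_and_gz(self, tmp_path):
        import gzip

        fa = ">s1 desc\nacgtacgt\nacgt\n>s2\nggcc\n"
        p = tmp_path / "x.fa"
        p.write_text(fa)
        recs = list(read_fasta(p))
        assert recs == [("s1", "acgtacgt" + "acgt"), ("s2", "ggcc")]
        pz = tmp_path / "x.fa.gz"
        with gzip.open(pz, "wt") as fh:
            fh.write(fa)
        assert list(read_fasta(pz)) == recs
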