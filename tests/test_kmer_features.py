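import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerlasso.kmer_features import (
    canonical,
    count_features,
    discriminative_scores,
    enumerate_features,
    revcomp,
    select_features,
)
from kmerlasso.sequence_io import LabeledSequence

from oracles import count_pattern_occurrences, exhaustive_canonical_patterns

dna = st.text(alphabet="ACGT", min_size=12, max_size=40)


def labeled(seqs):
    return [LabeledSequence(f"s{i}", s, 1 if i % 2 == 0 else -1)
            for i, s in enumerate(seqs)]


class TestEnumeration:
    def test_two_mers_collapse_to_ten(self):
        # 4 palindromic 2-mers + 6 reverse-complement pairs
        assert len(enumerate_features(2, 0)) == 10

    @pytest.mark.parametrize("k,max_run", [(2, 0), (3, 1), (4, 2), (5, 3), (5, 2)])
    def test_matches_exhaustive_oracle(self, k, max_run):
        space = enumerate_features(k, max_run)
        pats = set(space.pattern_strings)
        assert pats == exhaustive_canonical_patterns(k, max_run)
        assert len(space.patterns) == len(pats)  # no duplicates

    def test_k8_canonical_spot_checks(self):
        space = enumerate_features(8, 2)
        assert "AAAAAAAA" in space
        assert "TTTTTTTT" not in space  # non-canonical member of the pair

    def test_wildcard_runs_are_interior_and_contiguous(self):
        for p in enumerate_features(5, 3).pattern_strings:
            if "." in p:
                first, last = p.index("."), p.rindex(".")
                assert first > 0 and last < len(p) - 1
                assert set(p[first:last + 1]) == {"."}

    def test_patterns_are_canonical(self):
        for p in enumerate_features(4, 2).pattern_strings:
            assert p == canonical(p)

    def test_deterministic_order(self):
        a = enumerate_features(4, 1).pattern_strings
        b = enumerate_features(4, 1).pattern_strings
        assert a == b

    def test_run_touching_end_rejected(self):
        with pytest.raises(ValueError):
            enumerate_features(4, 3)


class TestCounting:
    def count_one(self, seq, pattern, k=8, max_run=2):
        space = enumerate_features(k, max_run)
        M = count_features([LabeledSequence("s", seq, 1)], space)
        return M.counts[0, space.index_of(pattern)]

    def test_homopolymer_exact(self):
        assert self.count_one("AAAAAAAAAA", "AAAAAAAA") == 3

    def test_wildcard_subsumes_base(self):
        assert self.count_one("AAAAAAAAAA", "AAA.AAAA") == 3

    def test_palindrome_counted_once_per_position(self):
        assert self.count_one("ACGTACGTACGT", "ACGTACGT") == 2

    def test_n_matches_nothing(self):
        assert self.count_one("AAAANAAAAAAAA", "AAAAAAAA") == 1
        # wildcard over the N must not rescue the window
        assert self.count_one("AAAANAAAAAAAA", "AAA.AAAA") == 1

    def test_too_short_sequence_raises(self):
        space = enumerate_features(8, 0)
        with pytest.raises(ValueError, match="shorter"):
            count_features([LabeledSequence("s", "ACGT", 1)], space)

    @settings(max_examples=25, deadline=None)
    @given(dna)
    def test_exact_feature_counts_sum_to_positions(self, seq):
        """Summed exact-pattern counts equal L-k+1 on N-free sequences."""
        k = 5
        space = enumerate_features(k, 0)
        M = count_features([LabeledSequence("s", seq, 1)], space)
        assert M.counts.sum() == len(seq) - k + 1

    @settings(max_examples=20, deadline=None)
    @given(dna)
    def test_strand_symmetry(self, seq):
        space = enumerate_features(4, 1)
        M1 = count_features([LabeledSequence("s", seq, 1)], space)
        M2 = count_features([LabeledSequence("s", revcomp(seq), 1)], space)
        assert (M1.counts != M2.counts).nnz == 0

    @settings(max_examples=10, deadline=None)
    @given(dna, st.integers(0, 200))
    def test_counts_match_scan_oracle(self, seq, pat_pick):
        space = enumerate_features(4, 1)
        M = count_features([LabeledSequence("s", seq, 1)], space)
        pat = space.patterns[pat_pick % len(space)].pattern
        assert M.counts[0, space.index_of(pat)] == count_pattern_occurrences(pat, seq)


class TestSelection:
    def test_cap_at_total_features_reranks_only(self):
        space = enumerate_features(2, 0)
        seqs = labeled(["ACACACAC", "GTGTGTGT", "AAAACCCC", "GGGGTTTT"])
        M = count_features(seqs, space)
        sub_space, reduced = select_features(M, n_top=10 ** 6)
        assert reduced.n_features == M.n_features
        assert set(sub_space.pattern_strings) == set(space.pattern_strings)

    def test_constant_feature_scores_zero_and_ranks_last(self):
        from conftest import make_matrix

        X = np.array([[3.0, 1.0], [3.0, 0.0], [3.0, 2.0], [3.0, 0.0]])
        M = make_matrix(X, [1, 1, -1, -1], names=["AA", "AC"])
        scores = discriminative_scores(M)
        assert scores[0] == 0.0 and scores[1] > 0.0
        _, reduced = select_features(M, n_top=2)
        assert reduced.space.pattern_strings == ["AC", "AA"]

    def test_n_top_must_be_positive(self):
        space = enumerate_features(2, 0)
        M = count_features(labeled(["ACACACAC", "GTGTGTGT"]), space)
        with pytest.raises(ValueError):
            select_features(M, n_top=0)

    def test_planted_consensus_ranks_high(self):
        from kmerlasso.synthetic import PlantSpec, generate, ppm_from_consensus

        cons = "TGACTCAT"
        seqs, _ = generate(80, 80, width=100,
                           plants=[PlantSpec("m", ppm_from_consensus(cons, 0.95),
                                             fraction=0.8)],
                           seed=11)
        space = enumerate_features(8, 2)
        M = count_features(seqs, space)
        sub, _ = select_features(M, n_top=50)
        assert canonical(cons) in sub
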