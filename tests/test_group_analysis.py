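import itertools

import numpy as np
import pytest

from kmerlasso.group_analysis import (
    benjamini_hochberg,
    build_group_pfm,
    call_significant,
    class_scores,
    empirical_pvalues,
    export_hit_windows,
    locate_hits,
    pfm_consensus,
    position_scores,
)
from kmerlasso.sequence_io import GenomicInterval, LabeledSequence
from kmerlasso.sgl_model import SGLFit

from conftest import make_groups, make_matrix
from oracles import bh_stepup


def make_fit(w, group_of, names):
    return SGLFit(w=np.asarray(w, dtype=float), lambda1=0.1, lambda2=0.1,
                  assignment=make_groups(group_of),
                  objective_trace=np.array([0.0]), converged=True, n_iter=1,
                  feature_names=names)


class TestClassScores:
    def test_zero_margin_scores_log2(self):
        """With w_g.x = 0 every example contributes log 2 to its class sum."""
        M = make_matrix(np.ones((6, 2)), [1, 1, 1, -1, -1, -1], names=["AA", "AC"])
        f = make_fit([0.0, 0.0], [1, 1], ["AA", "AC"])
        s_pos, s_neg, cls = class_scores(f, M, 1)
        assert s_pos == pytest.approx(3 * np.log(2))
        assert s_neg == pytest.approx(3 * np.log(2))
        assert cls is None  # all-zero group carries no class

    def test_positive_only_counts_give_positive_class(self):
        X = np.array([[2.0], [3.0], [0.0], [0.0]])
        M = make_matrix(X, [1, 1, -1, -1], names=["AA"])
        f = make_fit([1.0], [1], ["AA"])
        _, _, cls = class_scores(f, M, 1)
        assert cls == 1

    def test_loss_max_mode_uses_printed_rule(self):
        X = np.array([[2.0], [3.0], [0.0], [0.0]])
        M = make_matrix(X, [1, 1, -1, -1], names=["AA"])
        f = make_fit([1.0], [1], ["AA"])
        s_pos, s_neg, cls = class_scores(f, M, 1, mode="loss_max")
        # positive examples have small loss, negatives log2 each;
        # the printed rule associates with the larger (negative) sum
        assert s_pos < s_neg and cls == -1

    def test_unknown_group_raises(self):
        M = make_matrix(np.ones((2, 1)), [1, -1], names=["AA"])
        f = make_fit([1.0], [1], ["AA"])
        with pytest.raises(KeyError):
            class_scores(f, M, 5)


class TestEmpiricalP:
    def test_plus_one_correction_never_zero(self):
        p = empirical_pvalues(np.array([100.0]), np.arange(100.0))
        assert p[0] == pytest.approx(1 / 101)

    def test_full_separation_all_significant(self):
        obs = np.linspace(10, 20, 40)
        null = np.linspace(0, 5, 100)
        p = empirical_pvalues(obs, null)
        assert np.allclose(p, 1 / 101)
        q = benjamini_hochberg(p)
        assert (q <= 0.05).all()

    def test_super_uniform_under_exchangeability(self):
        rng = np.random.default_rng(0)
        for t in (0.01, 0.05, 0.1):
            hits = []
            for _ in range(50):
                pool = rng.normal(size=300)
                p = empirical_pvalues(pool[:150], pool[150:])
                hits.append((p <= t).mean())
            se = np.std(hits, ddof=1) / np.sqrt(len(hits))
            assert np.mean(hits) <= t + 3 * max(se, 1e-3) + 0.01

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([1.0]), np.array([]))


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.2, 0.9]))
        assert ((q <= 0.05) == np.array([True, True, False, False])).all()

    def test_matches_stepup_oracle_exhaustively(self):
        """BH rejections equal the brute-force step-up on all short grids."""
        grid = [0.004, 0.02, 0.04, 0.2, 0.6, 1.0]
        for m in (1, 2, 3):
            for p in itertools.product(grid, repeat=m):
                p = np.array(p)
                ours = benjamini_hochberg(p) <= 0.05
                assert (ours == bh_stepup(p, 0.05)).all(), p

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=8)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallSignificant:
    def test_separated_group_calls_all_positives(self):
        X = np.concatenate([np.full(40, 5.0), np.zeros(100)])[:, None]
        M = make_matrix(X, [1] * 40 + [-1] * 100, names=["AA"])
        f = make_fit([1.0], [1], ["AA"])
        rep = call_significant(f, M, 1, fdr=0.05, min_examples=25)
        assert rep.class_label == 1
        assert rep.n_significant == 40
        assert rep.eligible_for_motif

    def test_zero_group_reports_without_calls(self):
        M = make_matrix(np.ones((4, 1)), [1, 1, -1, -1], names=["AA"])
        f = make_fit([0.0], [1], ["AA"])
        rep = call_significant(f, M, 1)
        assert rep.class_label is None and rep.n_significant == 0

    def test_negative_class_group_mirrors_the_test(self):
        # flank-enriched k-mer with a negative fitted weight: strongly
        # negative activations mark negative-class membership
        X = np.concatenate([np.zeros(50), np.full(50, 4.0)])[:, None]
        M = make_matrix(X, [1] * 50 + [-1] * 50, names=["AA"])
        f = make_fit([-1.0], [1], ["AA"])
        rep = call_significant(f, M, 1)
        assert rep.class_label == -1
        assert rep.n_significant == 50


def seq_records(seqs, origins=None):
    out = []
    for i, s in enumerate(seqs):
        origin = origins[i] if origins else None
        out.append(LabeledSequence(f"e{i}", s, 1, origin=origin))
    return out


class TestLocateHits:
    def one_pattern_setup(self, seqs):
        names = ["ACGTACTA"]
        f = make_fit([1.0], [1], names)
        X = np.ones((len(seqs), 1))
        M = make_matrix(X, [1] * len(seqs), names=names)
        rep = call_significant  # placeholder, built manually below
        return f, M

    def manual_report(self, M):
        from kmerlasso.group_analysis import GroupReport

        n = M.n_examples
        rep = GroupReport(group_id=1, class_label=1, class_score_pos=0.0,
                          class_score_neg=0.0, activations=np.ones(n),
                          p_values=np.full(n, 0.001), q_values=np.full(n, 0.001),
                          class_example_idx=np.arange(n), n_significant=n,
                          eligible_for_motif=True)
        return rep

    def test_single_occurrence_located(self):
        pat = "ACGTACTA"
        seq = "T" * 40 + pat + "T" * 30
        recs = seq_records([seq])
        f, M = self.one_pattern_setup([seq])
        hits = locate_hits(f, M, 1, recs, self.manual_report(M))
        assert hits[0].position == 40
        assert hits[0].strand == "+"
        assert (hits[0].window_start, hits[0].window_end) == (40 + 4 - 25, 40 + 4 + 25)

    def test_leftmost_tie_break(self):
        pat = "ACGTACTA"
        seq = "T" * 10 + pat + "T" * 20 + pat + "T" * 30
        recs = seq_records([seq])
        f, M = self.one_pattern_setup([seq])
        hits = locate_hits(f, M, 1, recs, self.manual_report(M))
        assert hits[0].position == 10

    def test_window_clipped_at_edge(self):
        pat = "ACGTACTA"
        seq = pat + "T" * 60
        recs = seq_records([seq])
        f, M = self.one_pattern_setup([seq])
        hits = locate_hits(f, M, 1, recs, self.manual_report(M))
        assert hits[0].window_start == 0
        assert hits[0].window_end == 29  # center 4 + 25

    def test_no_match_skips_with_empty_result(self):
        seq = "T" * 60
        recs = seq_records([seq])
        f, M = self.one_pattern_setup([seq])
        assert locate_hits(f, M, 1, recs, self.manual_report(M)) == []

    def test_position_scores_consistent_with_counting(self):
        """Summing indicator matches over positions equals the count."""
        from kmerlasso.kmer_features import count_features, enumerate_features

        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        space = enumerate_features(8, 2)
        Mc = count_features([LabeledSequence("s", seq, 1)], space)
        pat = "AC.TACTA"
        f = make_fit([1.0], [1], [pat])
        scores, _ = position_scores(f, 1, seq)
        assert scores.sum() == Mc.counts[0, space.index_of(pat)]


class TestExportAndPfm:
    def test_export_counts_and_clipping_tag(self, tmp_path):
        pat = "ACGTACTA"
        seqs = [pat + "T" * 60, "T" * 40 + pat + "T" * 20]
        recs = seq_records(seqs, origins=[GenomicInterval("chr1", 100, 168),
                                          GenomicInterval("chr1", 500, 568)])
        f = make_fit([1.0], [1], [pat])
        M = make_matrix(np.ones((2, 1)), [1, 1], names=[pat])
        rep = TestLocateHits().manual_report(M)
        hits = locate_hits(f, M, 1, recs, rep)
        fa, bed = tmp_path / "h.fa", tmp_path / "h.bed"
        export_hit_windows(hits, recs, fa, bed)
        fa_lines = fa.read_text().strip().split("\n")
        assert sum(1 for ln in fa_lines if ln.startswith(">")) == 2
        assert "len=" in fa_lines[0]  # clipped first window
        bed_rows = bed.read_text().strip().split("\n")
        assert len(bed_rows) == 2
        chrom, start, end = bed_rows[1].split("\t")[:3]
        # right edge clips at the 68-base window (500 + 68 = 568)
        assert (chrom, int(start), int(end)) == ("chr1", 500 + 40 + 4 - 25, 568)

    def test_pfm_of_identical_kmers_is_indicator(self):
        pat = "ACGTACTA"
        seqs = [("T" * 10 + pat + "T" * 30) for _ in range(30)]
        recs = [LabeledSequence(f"e{i}", s, 1) for i, s in enumerate(seqs)]
        f = make_fit([1.0], [1], [pat])
        M = make_matrix(np.ones((30, 1)), [1] * 30, names=[pat])
        rep = TestLocateHits().manual_report(M)
        hits = locate_hits(f, M, 1, recs, rep)
        pfm = build_group_pfm(hits, recs, k=8, min_examples=25)
        assert (pfm.sum(axis=1) == 30).all()
        assert pfm_consensus(pfm) == pat
        assert (pfm.max(axis=1) == 30).all()

    def test_pfm_requires_min_examples(self):
        pat = "ACGTACTA"
        recs = [LabeledSequence("e0", "T" * 10 + pat + "T" * 10, 1)]
        f = make_fit([1.0], [1], [pat])
        M = make_matrix(np.ones((1, 1)), [1], names=[pat])
        rep = TestLocateHits().manual_report(M)
        hits = locate_hits(f, M, 1, recs, rep)
        with pytest.raises(ValueError):
            build_group_pfm(hits, recs, k=8, min_examples=25)
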