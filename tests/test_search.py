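"""Local alignment scores, E-value statistics, and the all-vs-all search."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genomepair import (
    KarlinAltschulParams,
    NUCLEOTIDE_SCHEME,
    PROTEIN_SCHEME,
    SimParams,
    all_vs_all,
    local_align,
    simulate_pair,
)
from genomepair.search import (
    SearchError,
    calibrate_gumbel,
    search_both,
    ungapped_lambda_k,
)
from oracles import sw_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ARNDCQEGHILKMFPSTWYV"


def _protein_score(x, y):
    return BLOSUM62[x, y]


class TestLocalAlign:
    def test_self_alignment_equals_diagonal_sum(self):
        hit = local_align("MKV", "MKV", PROTEIN_SCHEME)
        expected = sum(BLOSUM62[c, c] for c in "MKV")
        assert hit.raw_score == expected
        assert hit.q_span == (0, 3) and hit.s_span == (0, 3)

    def test_all_negative_scores_give_no_hit(self):
        # BLOSUM62 A-vs-W is negative everywhere in this pair
        assert local_align("AAAA", "WWWW", PROTEIN_SCHEME) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(SearchError):
            local_align("", "MKV", PROTEIN_SCHEME)

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(SearchError):
            local_align("ACGT", "ACGU", NUCLEOTIDE_SCHEME)

    def test_planted_exact_match_recovered(self):
        rng = np.random.default_rng(42)
        word = "".join(rng.choice(list(AA), 20))
        # W-vs-C scores are strictly negative, so the optimal local
        # alignment can never extend past the planted word
        a = "W" * 30 + word + "W" * 30
        b = "C" * 25 + word + "C" * 25
        # brute-force: the planted word is the only shared 20-mer
        shared = {a[i:i + 20] for i in range(len(a) - 19)} & {
            b[j:j + 20] for j in range(len(b) - 19)}
        assert shared == {word}
        hit = local_align(a, b, PROTEIN_SCHEME)
        assert hit.q_span == (30, 50)
        assert hit.s_span == (25, 45)
        assert hit.pident_local == 100.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_dp_oracle_protein(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), rng.integers(5, 31)))
        b = "".join(rng.choice(list(AA), rng.integers(5, 31)))
        hit = local_align(a, b, PROTEIN_SCHEME)
        ref = sw_score(a, b, _protein_score, 11, 1)
        assert (hit.raw_score if hit else 0) == ref

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_dp_oracle_nucleotide(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(5, 31)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(5, 31)))
        hit = local_align(a, b, NUCLEOTIDE_SCHEME)
        ref = sw_score(a, b, lambda x, y: 2 if x == y else -3, 5, 2)
        assert (hit.raw_score if hit else 0) == ref

    def test_score_symmetry(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list(AA), 40))
        b = "".join(rng.choice(list(AA), 35))
        ha = local_align(a, b, PROTEIN_SCHEME)
        hb = local_align(b, a, PROTEIN_SCHEME)
        assert ha.raw_score == hb.raw_score


class TestKarlinAltschul:
    def test_evalue_strictly_decreasing_in_score(self):
        ka = KarlinAltschulParams(0.267, 0.041, 300, 100_000)
        evs = [ka.evalue(s) for s in range(10, 200, 10)]
        assert all(x > y for x, y in zip(evs, evs[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(SearchError):
            KarlinAltschulParams(-0.1, 0.041)

    def test_ungapped_lambda_solves_fixed_point(self):
        lam, _ = ungapped_lambda_k(NUCLEOTIDE_SCHEME)
        # independent check of sum p_i p_j exp(lam s_ij) = 1 at p = 1/4
        total = 4 * (1 / 16) * math.exp(2 * lam) + 12 * (1 / 16) * math.exp(-3 * lam)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_gumbel_calibration_recovers_plausible_lambda(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list(AA), 120)) for _ in range(12)]
        lam, k = calibrate_gumbel(seqs, seqs, PROTEIN_SCHEME, n_samples=80,
                                  rng=np.random.default_rng(1))
        assert 0.1 < lam < 0.6
        assert k > 0


class TestAllVsAll:
    def test_identical_singleton_maximal_self_score(self):
        seq = "MKVLAWRT"
        hits = all_vs_all({"x": seq}, {"y": seq}, PROTEIN_SCHEME, e_report=10)
        assert len(hits) == 1
        assert hits[0].raw_score == sum(BLOSUM62[c, c] for c in seq)

    def test_zero_e_report_empty(self):
        assert all_vs_all({"x": "MKV"}, {"y": "MKV"}, PROTEIN_SCHEME,
                          e_report=0) == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SearchError, match="duplicate"):
            all_vs_all([("x", "MKV")], [("y", "MKV"), ("y", "MKVL")],
                       PROTEIN_SCHEME)
        with pytest.raises(SearchError, match="duplicate"):
            search_both([("x", "MKV"), ("x", "MKV")], [("y", "MKV")],
                        PROTEIN_SCHEME)

    def test_hits_sorted_per_query(self, small_pair):
        A, B, _ = small_pair
        hits = all_vs_all(dict(list(A.proteins().items())[:10]),
                          dict(list(B.proteins().items())[:20]),
                          PROTEIN_SCHEME, e_report=1e-3, details=False)
        for h1, h2 in zip(hits, hits[1:]):
            if h1.qid == h2.qid:
                assert (h1.evalue, -h1.bit_score, h1.sid) <= (
                    h2.evalue, -h2.bit_score, h2.sid)

    def test_true_orthologs_all_found_at_strict_cutoff(self):
        A, B, truth = simulate_pair(
            SimParams(n_genes=50, gene_len_mean=150, gene_len_sd=40,
                      subst_per_site=0.1, p_dup=0, p_del=0, p_split=0,
                      p_hgt=0, n_inversions=0, n_rna=0, seed=13)
        )
        hits = all_vs_all(A.proteins(), B.proteins(), PROTEIN_SCHEME,
                          e_report=1e-8, details=False)
        hit_pairs = {(h.qid, h.sid) for h in hits}
        assert truth.ortholog_map <= hit_pairs

    def test_search_both_consistent_with_single_direction(self, small_pair):
        A, B, _ = small_pair
        sub_a = dict(list(A.proteins().items())[:8])
        sub_b = dict(list(B.proteins().items())[:8])
        ab, ba = search_both(sub_a, sub_b, PROTEIN_SCHEME, e_report=1e-4,
                             details=False)
        ab_direct = all_vs_all(sub_a, sub_b, PROTEIN_SCHEME, e_report=1e-4,
                               details=False)
        assert [(h.qid, h.sid, h.raw_score, h.evalue) for h in ab] == [
            (h.qid, h.sid, h.raw_score, h.evalue) for h in ab_direct]
        # raw scores are direction-symmetric
        ab_scores = {(h.qid, h.sid): h.raw_score for h in ab}
        for h in ba:
            if (h.sid, h.qid) in ab_scores:
                assert h.raw_score == ab_scores[(h.sid, h.qid)]
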