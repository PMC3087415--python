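"""One-to-one matching, global-alignment validation, binning, partition."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from genomepair import (
    GenomeComparison,
    PROTEIN_SCHEME,
    SimParams,
    bin_pairs,
    one_to_one_match,
    partition,
    simulate_pair,
    validate_pairs,
)
from genomepair.orthologs import OrthologError, OrthologPair, global_align_stats
from genomepair.search import LocalHit
from oracles import enumerate_greedy_matching, nw_score

AA = "ARNDCQEGHILKMFPSTWYV"


def _hit(qid, sid, evalue, bit=100.0):
    return LocalHit(qid=qid, sid=sid, raw_score=int(bit), bit_score=bit,
                    evalue=evalue, q_span=(0, 1), s_span=(0, 1),
                    alphabet="protein")


class TestOneToOneMatch:
    def test_identical_proteomes_pair_everything(self):
        hits = [_hit(f"a{i}", f"b{i}", 1e-50) for i in range(5)]
        back = [_hit(f"b{i}", f"a{i}", 1e-50) for i in range(5)]
        got = one_to_one_match(hits, back, 1e-8)
        assert {(a, b) for a, b, *_ in got} == {
            (f"a{i}", f"b{i}") for i in range(5)}

    def test_partner_consumed_by_better_hit(self):
        # a1's best hit is b1, but b1's best hit is a2 at a lower evalue:
        # b1 must pair with a2, and a1 falls through to its next admissible
        # partner b2.
        hits_ab = [
            _hit("a1", "b1", 1e-40, bit=120),
            _hit("a1", "b2", 1e-20, bit=80),
            _hit("a2", "b1", 1e-60, bit=150),
            _hit("a3", "b3", 1e-10, bit=60),
        ]
        hits_ba = []
        got = one_to_one_match(hits_ab, hits_ba, 1e-8)
        assert ("a2", "b1") in {(a, b) for a, b, *_ in got}
        assert ("a1", "b2") in {(a, b) for a, b, *_ in got}
        # oracle: direct transcription of the rule
        weighted = [(h.qid, h.sid, h.evalue, h.bit_score) for h in hits_ab]
        assert [(a, b) for a, b, *_ in got] == enumerate_greedy_matching(
            weighted, 1e-8)

    def test_second_best_never_reuses_partner(self):
        hits = [
            _hit("a1", "b1", 1e-90),
            _hit("a2", "b1", 1e-50),
            _hit("a2", "b2", 1e-30),
        ]
        got = {(a, b) for a, b, *_ in one_to_one_match(hits, [], 1e-8)}
        assert got == {("a1", "b1"), ("a2", "b2")}

    def test_cutoff_excludes_weak_pairs(self):
        hits = [_hit("a1", "b1", 1e-5)]
        assert one_to_one_match(hits, [], 1e-8) == []
        assert len(one_to_one_match(hits, [], 1e-4)) == 1

    def test_empty_tables_empty_matching(self):
        assert one_to_one_match([], [], 1e-8) == []

    def test_best_direction_kept(self):
        ab = [_hit("a1", "b1", 1e-20, bit=90)]
        ba = [_hit("b1", "a1", 1e-30, bit=95)]
        got = one_to_one_match(ab, ba, 1e-8)
        assert got[0][2] == 1e-30  # the better direction's evalue

    def test_mutual_mode_requires_reciprocity(self):
        ab = [_hit("a1", "b1", 1e-40), _hit("a2", "b1", 1e-60)]
        got = one_to_one_match(ab, [], 1e-8, mode="mutual")
        # b1's best is a2; a1's best is b1 but not reciprocated
        assert {(a, b) for a, b, *_ in got} == {("a2", "b1")}


class TestValidatePairs:
    def test_identical_sequences_full_identity(self):
        seqs = {"x": "MKVLAWRTQ"}
        out = validate_pairs([("x", "x", 1e-50, 100.0)], seqs, seqs,
                             PROTEIN_SCHEME)
        p = out[0]
        assert p.global_identity == 100.0
        assert p.global_similarity == 100.0
        assert p.aln_len == 9

    def test_unrelated_random_pair_dropped(self):
        rng = np.random.default_rng(17)
        a = "".join(rng.choice(list("AGPSTV"), 100))
        b = "".join(rng.choice(list("DEKNRQ"), 100))
        log = []
        out = validate_pairs([("u", "v", 1e-9, 10.0)], {"u": a}, {"v": b},
                             PROTEIN_SCHEME, min_identity=10, log=log)
        assert out == [] and len(log) == 1
        # cross-check the underlying global score against the DP oracle
        blosum = substitution_matrices.load("BLOSUM62")
        ref = nw_score(a, b, lambda x, y: blosum[x, y], 11, 1)
        from genomepair.search import make_aligner

        assert make_aligner(PROTEIN_SCHEME, "global").score(a, b) == ref

    def test_identity_never_exceeds_similarity(self, fitted_small):
        *_, res = fitted_small
        for p in res.partition.pairs:
            assert 0 <= p.global_identity <= p.global_similarity <= 100

    def test_missing_sequence_raises(self):
        with pytest.raises(OrthologError, match="zz"):
            validate_pairs([("zz", "v", 1e-9, 1.0)], {}, {"v": "MKV"},
                           PROTEIN_SCHEME)

    @pytest.mark.parametrize("seed", range(3))
    def test_global_score_matches_dp_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list(AA), rng.integers(5, 25)))
        b = "".join(rng.choice(list(AA), rng.integers(5, 25)))
        blosum = substitution_matrices.load("BLOSUM62")
        ref = nw_score(a, b, lambda x, y: blosum[x, y], 11, 1)
        from genomepair.search import make_aligner

        assert make_aligner(PROTEIN_SCHEME, "global").score(a, b) == ref


class TestBinPairs:
    def _pair(self, ev, sim):
        return OrthologPair("a", "b", ev, 100.0, sim, sim, 100)

    def test_identical_pairs_all_in_strongest_band(self):
        pairs = [self._pair(1e-120, 100.0) for _ in range(4)]
        df = bin_pairs(pairs)
        strongest = df[df.band == "<=1e-100"].iloc[0]
        assert strongest.fraction_pct == 100.0
        assert df[df.band == "similarity==100"].iloc[0].fraction_pct == 100.0

    def test_fractions_sum_to_100_over_disjoint_bands(self):
        pairs = [self._pair(ev, 50.0) for ev in
                 (1e-150, 1e-80, 1e-40, 1e-10, 1e-9)]
        df = bin_pairs(pairs)
        disjoint = df[df.band != "similarity==100"]
        assert disjoint.fraction_pct.sum() == pytest.approx(100.0, abs=0.3)

    def test_band_mass_shifts_with_divergence(self):
        def strongest_fraction(subst, seed=21):
            # band <=1e-100 is only reachable by realistic-length proteins
            A, B, _ = simulate_pair(
                SimParams(n_genes=25, gene_len_mean=300, gene_len_sd=60,
                          subst_per_site=subst, p_dup=0, p_del=0, p_split=0,
                          p_hgt=0, n_inversions=0, n_rna=0, seed=seed))
            res = GenomeComparison(A, B).fit()
            df = res.bins()
            return df[df.band == "<=1e-100"].iloc[0].fraction_pct

        assert strongest_fraction(0.05) > strongest_fraction(0.5)


class TestPartition:
    def test_identical_genomes_no_uniques(self):
        A, B, truth = simulate_pair(
            SimParams(n_genes=20, subst_per_site=0.0, p_dup=0, p_del=0,
                      p_split=0, p_hgt=0, n_inversions=0, seed=2))
        res = GenomeComparison(A, B).fit()
        assert res.partition.unique_a == []
        assert res.partition.unique_b == []
        assert len(res.partition.pairs) == 20

    def test_accounting_invariant(self, fitted_small):
        A, B, _, res = fitted_small
        part = res.partition
        assert len(part.pairs) + len(part.unique_a) == len(
            A.cds_features(comparable_only=True))
        assert len(part.pairs) + len(part.unique_b) == len(
            B.cds_features(comparable_only=True))

    def test_unknown_pair_id_rejected(self, small_pair):
        A, B, _ = small_pair
        bogus = OrthologPair("nope", "nope2", 1e-50, 10, 50, 60, 10)
        with pytest.raises(OrthologError):
            partition(A, B, [bogus])

    def test_unique_sets_explained_by_truth_events(self, fitted_small):
        A, B, truth, res = fitted_small
        for lineage, uniq in (("A", res.partition.unique_a),
                              ("B", res.partition.unique_b)):
            expected = truth.expected_unique(lineage)
            for tag in uniq:
                assert tag in expected, f"unexplained unique gene {tag}"

    def test_one_to_one_asserted(self, fitted_small):
        *_, res = fitted_small
        res.partition.assert_one_to_one()  # must not raise


class TestDirectionSymmetryAndCutoff:
    def test_swapping_genomes_transposes_pairs(self, small_pair, fitted_small):
        A, B, _ = small_pair
        *_, res = fitted_small
        res_swapped = GenomeComparison(B, A).fit()
        fwd = {(p.id_a, p.id_b) for p in res.partition.pairs}
        rev = {(p.id_b, p.id_a) for p in res_swapped.partition.pairs}
        assert fwd == rev

    def test_tightening_cutoff_never_adds_pairs(self, small_pair, fitted_small):
        from genomepair import RunConfig

        A, B, _ = small_pair
        *_, res = fitted_small
        strict = GenomeComparison(A, B, RunConfig(e_cutoff=1e-25)).fit()
        loose_pairs = {(p.id_a, p.id_b) for p in res.partition.pairs}
        strict_pairs = {(p.id_a, p.id_b) for p in strict.partition.pairs}
        assert strict_pairs <= loose_pairs
        assert len(strict_pairs) < len(loose_pairs)  # diverged pair: strictly


def test_global_alignment_stats_count_gap_columns():
    ident, sim, aln_len = global_align_stats("MKVW", "MKW", PROTEIN_SCHEME)
    assert aln_len == 4  # one gap column
    assert ident == pytest.approx(75.0)
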