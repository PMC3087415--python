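"""Simulator determinism, conservation laws, and event statistics."""

import numpy as np
import pytest
from scipy import stats

from genomepair import SimParams, simulate_pair
from genomepair.synthetic import SimulationError, expected_gene_gc


def _cds_count(g):
    return len(g.cds_features())


def _event_counts(truth, lineage):
    out = {"duplication": 0, "deletion": 0, "split": 0, "lateral_transfer": 0}
    for lin, tag, ev in truth.events:
        if lin == lineage and ev in out:
            out[ev] += 1
    out["split"] //= 2  # two fragments per split event
    return out


class TestValidation:
    def test_probability_sum_rejected(self):
        with pytest.raises(SimulationError):
            SimParams(p_dup=0.5, p_del=0.5, p_split=0.2).validate()

    def test_negative_probability_rejected(self):
        with pytest.raises(SimulationError):
            SimParams(p_dup=-0.1).validate()

    def test_zero_genes_rejected(self):
        with pytest.raises(SimulationError):
            simulate_pair(SimParams(n_genes=0))


class TestDeterminism:
    def test_identical_params_identical_output(self):
        p1 = SimParams(n_genes=30, gene_len_mean=90, seed=11)
        p2 = SimParams(n_genes=30, gene_len_mean=90, seed=11)
        A1, B1, t1 = simulate_pair(p1)
        A2, B2, t2 = simulate_pair(p2)
        assert A1.seq == A2.seq and B1.seq == B2.seq
        assert [(f.locus_tag, f.start, f.end, f.strand) for f in A1.features] == [
            (f.locus_tag, f.start, f.end, f.strand) for f in A2.features
        ]
        assert t1.ortholog_map == t2.ortholog_map
        assert t1.events == t2.events

    def test_different_seed_differs(self):
        A1, _, _ = simulate_pair(SimParams(n_genes=30, seed=1))
        A2, _, _ = simulate_pair(SimParams(n_genes=30, seed=2))
        assert A1.seq != A2.seq


class TestDegenerateConditions:
    def test_no_divergence_gives_identical_twins(self):
        p = SimParams(
            n_genes=25, subst_per_site=0.0, p_dup=0, p_del=0, p_split=0,
            p_hgt=0, n_inversions=0, n_rna=0, seed=3,
        )
        A, B, truth = simulate_pair(p)
        assert _cds_count(A) == _cds_count(B) == 25
        # identity pairing of all genes, same proteins
        assert len(truth.ortholog_map) == 25
        prot_a, prot_b = A.proteins(), B.proteins()
        for a, b in truth.ortholog_map:
            assert prot_a[a] == prot_b[b]

    def test_certain_deletion_empties_both_lineages(self):
        p = SimParams(n_genes=10, p_dup=0, p_del=1.0, p_split=0, p_hgt=0,
                      n_inversions=0, seed=5)
        A, B, truth = simulate_pair(p)
        assert _cds_count(A) == 0 and _cds_count(B) == 0
        for lineage in ("A", "B"):
            assert len(truth.events_of(lineage, "deletion")) == 10


class TestConservation:
    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_gene_count_balance(self, seed):
        p = SimParams(n_genes=120, gene_len_mean=100, gene_len_sd=30, seed=seed)
        A, B, truth = simulate_pair(p)
        for g, lineage in ((A, "A"), (B, "B")):
            ev = _event_counts(truth, lineage)
            expected = (
                p.n_genes - ev["deletion"] + ev["duplication"] + ev["split"]
                + ev["lateral_transfer"]
            )
            assert _cds_count(g) == expected

    def test_inversions_preserve_gene_content(self, small_pair):
        A, B, truth = small_pair
        tags_b = {f.locus_tag for f in B.features}
        inv = {tag for lin, tag, ev in truth.events
               if ev == "inversion_member"}
        assert inv  # the fixture plants inversions
        assert inv <= tags_b

    def test_every_truth_tag_exists(self, small_pair):
        A, B, truth = small_pair
        tags = {f.locus_tag for f in A.features} | {f.locus_tag for f in B.features}
        for a, b in truth.ortholog_map:
            assert a in tags and b in tags


class TestEventStatistics:
    def test_realized_counts_within_binomial_bounds(self):
        # pooled over both lineages and three replicates; 99.9% bands since
        # eight count cells are checked simultaneously at fixed seeds
        base = dict(n_genes=200, subst_per_site=0.2, p_dup=0.05, p_del=0.05,
                    p_split=0.02, p_hgt=0.05, n_inversions=2)
        totals = {"duplication": 0, "deletion": 0, "split": 0,
                  "lateral_transfer": 0}
        n_draws = 0
        for seed in (7, 8, 9):
            _, _, truth = simulate_pair(SimParams(seed=seed, **base))
            for lineage in ("A", "B"):
                ev = _event_counts(truth, lineage)
                for kind in totals:
                    totals[kind] += ev[kind]
                n_draws += base["n_genes"]
        for kind, prob in (("duplication", 0.05), ("deletion", 0.05),
                           ("split", 0.02), ("lateral_transfer", 0.05)):
            lo = stats.binom.ppf(0.0005, n_draws, prob)
            hi = stats.binom.ppf(0.9995, n_draws, prob)
            assert lo <= totals[kind] <= hi, (kind, totals[kind], lo, hi)

    def test_substitution_rate_reflected_in_divergence(self):
        lo = simulate_pair(SimParams(n_genes=30, subst_per_site=0.02, p_dup=0,
                                     p_del=0, p_split=0, p_hgt=0, seed=4))
        hi = simulate_pair(SimParams(n_genes=30, subst_per_site=0.6, p_dup=0,
                                     p_del=0, p_split=0, p_hgt=0, seed=4))

        def mean_identity(sim):
            A, B, truth = sim
            pa, pb = A.proteins(), B.proteins()
            idents = []
            for a, b in truth.ortholog_map:
                if a in pa and b in pb and len(pa[a]) == len(pb[b]):
                    x, y = pa[a], pb[b]
                    idents.append(sum(c == d for c, d in zip(x, y)) / len(x))
            return np.mean(idents)

        assert mean_identity(lo) > 0.95 > mean_identity(hi)

    def test_lateral_genes_are_gc_shifted(self):
        p = SimParams(n_genes=80, p_hgt=0.3, p_dup=0, p_del=0, p_split=0,
                      gene_len_mean=200, seed=6)
        A, _, truth = simulate_pair(p)
        from genomepair.records import gene_gc_stats

        hgt = {tag for lin, tag, ev in truth.events
               if lin == "A" and ev == "lateral_transfer"}
        gcs = {f.locus_tag: gene_gc_stats(f, A.seq)[0] for f in A.cds_features()}
        hgt_gc = np.mean([gcs[t] for t in hgt])
        host_gc = np.mean([v for t, v in gcs.items() if t not in hgt])
        # realized shift close to the configured overall-GC offset
        assert hgt_gc - host_gc == pytest.approx(p.hgt_gc_shift, abs=0.04)
        assert abs(host_gc - expected_gene_gc(p.gc3)) < 0.02


def test_split_fragments_are_adjacent_same_strand(small_pair):
    A, B, truth = small_pair
    for g, lineage in ((A, "A"), (B, "B")):
        frags = [tag for lin, tag, ev in truth.events
                 if lin == lineage and ev == "split"]
        order = [f.locus_tag for f in g.features]
        by_anc = {}
        for t in frags:
            by_anc.setdefault(truth.ancestor_ids[t], []).append(t)
        for anc, pair in by_anc.items():
            assert len(pair) == 2
            i, j = sorted(order.index(t) for t in pair)
            assert j == i + 1  # adjacent
            f1, f2 = g.features[i], g.features[j]
            assert f1.strand == f2.strand
            assert f2.start - f1.end <= 10  # single-base frameshift gap
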