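"""One-to-one ortholog mapping between two gene complements.

Two-step procedure: (1) bidirectional best-hit matching on local-alignment
E-values, with the constraint that each sequence is used at most once —
implemented as a deterministic global greedy matching over the union of hits
from both search directions, accepted in order of ascending E-value (ties:
descending bit score, then lexicographic id pair); (2) validation of each
candidate pair by full-length global (Needleman–Wunsch) alignment, keeping
pairs with at least ``min_identity`` percent identical columns.

A strict mutual-best-hit mode is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GenomeRecord
from .search import LocalHit, ScoringScheme, _matrix_for, make_aligner


class OrthologError(ValueError):
    pass


@dataclass
class OrthologPair:
    """A validated one-to-one ortholog pair.

    ``global_identity``/``global_similarity`` are percentages over all
    alignment columns including gap columns; a "similar" column is one whose
    substitution-matrix entry is positive.
    """

    id_a: str
    id_b: str
    evalue: float
    bit_score: float
    global_identity: float
    global_similarity: float
    aln_len: int


@dataclass
class GenomePartition:
    """Shared/unique partition of two gene complements."""

    pairs: list[OrthologPair] = field(default_factory=list)
    unique_a: list[str] = field(default_factory=list)
    unique_b: list[str] = field(default_factory=list)
    rna_pairs: list[OrthologPair] = field(default_factory=list)
    rna_unique_a: list[str] = field(default_factory=list)
    rna_unique_b: list[str] = field(default_factory=list)

    @property
    def pair_map_ab(self) -> dict[str, str]:
        return {p.id_a: p.id_b for p in self.pairs}

    def assert_one_to_one(self) -> None:
        for pairs in (self.pairs, self.rna_pairs):
            a_tags = [p.id_a for p in pairs]
            b_tags = [p.id_b for p in pairs]
            if len(set(a_tags)) != len(a_tags) or len(set(b_tags)) != len(b_tags):
                raise OrthologError("one-to-one violation: a locus tag is reused")


def one_to_one_match(
    hits_ab: list[LocalHit],
    hits_ba: list[LocalHit],
    e_cutoff: float,
    mode: str = "greedy",
) -> list[tuple[str, str, float, float]]:
    """Match genes one-to-one on bidirectional hits.

    Returns ``(id_a, id_b, evalue, bit_score)`` tuples. In the default
    greedy mode the union of hit pairs from both directions is sorted by
    ascending E-value (keeping, per unordered pair, the better direction)
    and accepted greedily while both partners are unused; second- and
    third-best hits never create a pair once a partner is consumed. In
    ``mode="mutual"`` only reciprocal best hits are accepted.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for h in hits_ab:
        key = (h.qid, h.sid)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bit_score) < (cur[0], -cur[1]):
            best[key] = (h.evalue, h.bit_score)
    for h in hits_ba:
        key = (h.sid, h.qid)  # flip back to (a, b)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bit_score) < (cur[0], -cur[1]):
            best[key] = (h.evalue, h.bit_score)

    candidates = [
        (ev, -bit, a, b)
        for (a, b), (ev, bit) in best.items()
        if ev <= e_cutoff
    ]
    candidates.sort()

    if mode == "mutual":
        best_partner_a: dict[str, tuple] = {}
        best_partner_b: dict[str, tuple] = {}
        for ev, nbit, a, b in candidates:
            if a not in best_partner_a or (ev, nbit, b) < best_partner_a[a][:3]:
                best_partner_a[a] = (ev, nbit, b)
            if b not in best_partner_b or (ev, nbit, a) < best_partner_b[b][:3]:
                best_partner_b[b] = (ev, nbit, a)
        out = []
        for a, (ev, nbit, b) in sorted(best_partner_a.items()):
            if best_partner_b.get(b, (None, None, None))[2] == a:
                out.append((a, b, ev, -nbit))
        return out
    if mode != "greedy":
        raise OrthologError(f"unknown matching mode {mode!r}")

    used_a: set[str] = set()
    used_b: set[str] = set()
    matches: list[tuple[str, str, float, float]] = []
    for ev, nbit, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        matches.append((a, b, ev, -nbit))
    return matches


def global_align_stats(
    a: str, b: str, scheme: ScoringScheme
) -> tuple[float, float, int]:
    """(identity %, similarity %, alignment length) of the optimal global
    alignment with end gaps penalized.

    Gap columns count in the denominator of both percentages.
    """
    aligner = make_aligner(scheme, "global")
    aln = next(iter(aligner.align(a, b)))
    matrix = _matrix_for(scheme)
    qa, sa = str(aln[0]), str(aln[1])
    ident = similar = 0
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
        if matrix[x, y] > 0:
            similar += 1
    aln_len = len(qa)
    return (100.0 * ident / aln_len, 100.0 * similar / aln_len, aln_len)


def validate_pairs(
    matches: list[tuple[str, str, float, float]],
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    scheme: ScoringScheme,
    min_identity: float = 10.0,
    log: list | None = None,
) -> list[OrthologPair]:
    """Validate candidate pairs by full-length global alignment.

    Pairs whose percent identity falls below ``min_identity`` are dropped
    (and appended to ``log`` when given).
    """
    out: list[OrthologPair] = []
    for a, b, ev, bit in matches:
        if a not in seqs_a:
            raise OrthologError(f"no sequence for id {a!r} on side A")
        if b not in seqs_b:
            raise OrthologError(f"no sequence for id {b!r} on side B")
        ident, sim, aln_len = global_align_stats(seqs_a[a], seqs_b[b], scheme)
        if ident < min_identity:
            if log is not None:
                log.append((a, b, ident))
            continue
        out.append(
            OrthologPair(
                id_a=a, id_b=b, evalue=ev, bit_score=bit,
                global_identity=ident, global_similarity=sim, aln_len=aln_len,
            )
        )
    return out


#: E-value band edges, strongest first.
EVALUE_BANDS = (
    ("<=1e-100", 0.0, 1e-100),
    ("(1e-100,1e-50]", 1e-100, 1e-50),
    ("(1e-50,1e-25]", 1e-50, 1e-25),
    ("(1e-25,1e-8]", 1e-25, 1e-8),
)


def bin_pairs(pairs: list[OrthologPair]) -> pd.DataFrame:
    """Distribution of validated pairs over E-value bands.

    Returns one row per band with the fraction of pairs and the min/max
    global similarity within the band, plus a final row for the fraction of
    pairs with similarity exactly 100.
    """
    n = len(pairs)
    rows = []
    for name, lo, hi in EVALUE_BANDS:
        sel = [p for p in pairs if lo < p.evalue <= hi] if lo > 0 else [
            p for p in pairs if p.evalue <= hi
        ]
        sims = [p.global_similarity for p in sel]
        rows.append(
            {
                "band": name,
                "n_pairs": len(sel),
                "fraction_pct": round(100.0 * len(sel) / n, 1) if n else 0.0,
                "min_similarity": round(min(sims), 1) if sims else np.nan,
                "max_similarity": round(max(sims), 1) if sims else np.nan,
            }
        )
    full = [p for p in pairs if p.global_similarity >= 100.0]
    rows.append(
        {
            "band": "similarity==100",
            "n_pairs": len(full),
            "fraction_pct": round(100.0 * len(full) / n, 1) if n else 0.0,
            "min_similarity": 100.0 if full else np.nan,
            "max_similarity": 100.0 if full else np.nan,
        }
    )
    return pd.DataFrame(rows)


def partition(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    pairs: list[OrthologPair],
    rna_pairs: list[OrthologPair] | None = None,
) -> GenomePartition:
    """Partition both gene complements into shared and unique sets.

    Unique lists contain the comparable CDS with no validated partner; RNA
    genes are partitioned separately from nucleotide-mode pairs. CDS flagged
    with internal stops are excluded from the accounting (they never entered
    protein comparison).
    """
    rna_pairs = rna_pairs or []
    cds_a = {f.locus_tag for f in genome_a.cds_features(comparable_only=True)}
    cds_b = {f.locus_tag for f in genome_b.cds_features(comparable_only=True)}
    for p in pairs:
        if p.id_a not in cds_a:
            raise OrthologError(f"pair references unknown CDS {p.id_a!r} in A")
        if p.id_b not in cds_b:
            raise OrthologError(f"pair references unknown CDS {p.id_b!r} in B")
    rna_a = {f.locus_tag for f in genome_a.rna_features()}
    rna_b = {f.locus_tag for f in genome_b.rna_features()}
    for p in rna_pairs:
        if p.id_a not in rna_a or p.id_b not in rna_b:
            raise OrthologError(
                f"RNA pair ({p.id_a}, {p.id_b}) references unknown feature"
            )
    paired_a = {p.id_a for p in pairs}
    paired_b = {p.id_b for p in pairs}
    rpaired_a = {p.id_a for p in rna_pairs}
    rpaired_b = {p.id_b for p in rna_pairs}

    def ordered(genome, keep):
        return [f.locus_tag for f in genome.features if f.locus_tag in keep]

    part = GenomePartition(
        pairs=pairs,
        unique_a=ordered(genome_a, cds_a - paired_a),
        unique_b=ordered(genome_b, cds_b - paired_b),
        rna_pairs=rna_pairs,
        rna_unique_a=ordered(genome_a, rna_a - rpaired_a),
        rna_unique_b=ordered(genome_b, rna_b - rpaired_b),
    )
    part.assert_one_to_one()
    return part


def pairs_to_frame(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a, "id_b": p.id_b, "evalue": p.evalue,
                "bitscore": round(p.bit_score, 1),
                "global_identity": round(p.global_identity, 2),
                "global_similarity": round(p.global_similarity, 2),
                "aln_len": p.aln_len,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "evalue", "bitscore", "global_identity",
                 "global_similarity", "aln_len"],
    )
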