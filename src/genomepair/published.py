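"""Published reference values for the *Methanothermobacter* genome pair and
a runner that recomputes them from locally provided GenBank files.

The genomes are *M. marburgensis* (chromosome CP001710 / NC_014408, plasmid
NC_014409) and *M. thermautotrophicus* ΔH (NC_000916). The constants below
are the published comparison statistics; :func:`reproduce_published_comparison`
recomputes the same quantities with this package so the two can be compared.
The GenBank files are not bundled (they are megabase-scale) and must be
supplied by the caller.
"""

from __future__ import annotations

from pathlib import Path

from . import io as gio
from .model import GenomeComparison, RunConfig
from .records import count_features, gc_content
from .search import NUCLEOTIDE_SCHEME
from .orthologs import global_align_stats

#: Published genome-comparison statistics for the real pair
#: (A = M. marburgensis, B = M. thermautotrophicus).
EXPECTED = {
    "chromosome_bp_a": 1_639_135,
    "chromosome_bp_b": 1_751_377,
    "gc_molpct_a": 48.64,
    "gc_molpct_b": 49.54,
    "n_cds_a": 1752,
    "n_cds_b": 1873,
    "cds_in_common": 1607,
    "cds_not_in_common_total": 411,
    "cds_not_in_common_a": 145,
    "cds_not_in_common_b": 266,
    "fewer_common_at_1e_25": 40,
    "rna_in_common": 39,
    "rna_not_in_common": 1,
    "n_trna_a": 40,
    "n_trna_b": 39,
    "s16_identity_pct": 98.7,
    "s16_differing_positions": 20,
    "origin_fractions_a": {  # percent of unique CDS in M. marburgensis
        "split": 15, "deletion": 30, "duplication": 30, "lateral_transfer": 24,
    },
}


def reproduce_published_comparison(
    path_a: str | Path, path_b: str | Path, config: RunConfig | None = None
) -> dict:
    """Run the full comparison on the real genome pair and return the
    computed analogues of :data:`EXPECTED`.

    Parameters
    ----------
    path_a, path_b : path
        GenBank files for the *M. marburgensis* chromosome (CP001710) and
        the *M. thermautotrophicus* chromosome (NC_000916).
    """
    A = gio.read_genome(path_a, "genbank")
    B = gio.read_genome(path_b, "genbank")
    config = config or RunConfig()
    res = GenomeComparison(A, B, config).fit()
    strict = GenomeComparison(
        A, B, RunConfig(e_cutoff=1e-25, min_identity=config.min_identity)
    ).fit()

    out = {
        "chromosome_bp_a": len(A.seq),
        "chromosome_bp_b": len(B.seq),
        "gc_molpct_a": gc_content(A),
        "gc_molpct_b": gc_content(B),
        "n_cds_a": count_features(A, "CDS"),
        "n_cds_b": count_features(B, "CDS"),
        "cds_in_common": len(res.partition.pairs),
        "cds_not_in_common_a": len(res.partition.unique_a),
        "cds_not_in_common_b": len(res.partition.unique_b),
        "cds_not_in_common_total": (
            len(res.partition.unique_a) + len(res.partition.unique_b)
        ),
        "fewer_common_at_1e_25": (
            len(res.partition.pairs) - len(strict.partition.pairs)
        ),
        "rna_in_common": len(res.partition.rna_pairs),
        "rna_not_in_common": (
            len(res.partition.rna_unique_a) + len(res.partition.rna_unique_b)
        ),
        "n_trna_a": count_features(A, "tRNA"),
        "n_trna_b": count_features(B, "tRNA"),
        "origin_fractions_a": res.origin_summary("A").fractions,
    }

    s16 = _best_16s_identity(A, B)
    if s16 is not None:
        out["s16_identity_pct"], out["s16_differing_positions"] = s16
    return out


def _best_16s_identity(A, B):
    """Identity of the best-matching 16S rRNA pair (nucleotide global mode)."""
    def s16(g):
        return [
            f for f in g.rna_features()
            if f.ftype == "rRNA" and "16S" in (f.product or "")
        ]

    fa, fb = s16(A), s16(B)
    if not fa or not fb:
        return None
    best = None
    for x in fa:
        for y in fb:
            ident, _sim, aln_len = global_align_stats(
                x.nucleotide_seq(A.seq), y.nucleotide_seq(B.seq),
                NUCLEOTIDE_SCHEME,
            )
            diffs = round(aln_len * (100.0 - ident) / 100.0)
            if best is None or ident > best[0]:
                best = (round(ident, 1), diffs)
    return best
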