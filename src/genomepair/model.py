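"""Model/results interface for the two-genome comparison.

:class:`GenomeComparison` holds the two annotated genomes and a
:class:`RunConfig`; :meth:`GenomeComparison.fit` executes the full pipeline
(search -> one-to-one match -> global validation -> partition -> synteny ->
origin classification) and returns a :class:`ComparisonResults` carrying the
ortholog pairs, the shared/unique partition, synteny points, origin labels
and a ``summary()`` report table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from . import orthologs, origins, search, synteny
from .origins import ClassifierParams
from .records import GenomeRecord, count_features, gc_content
from .search import NUCLEOTIDE_SCHEME, PROTEIN_SCHEME, ScoringScheme

logger = logging.getLogger("genomepair")


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of one comparison run."""

    e_cutoff: float = 1e-8
    min_identity: float = 10.0  # percent, full-length global alignment
    relaxed_e: float = 1e-4  # classifier evidence cutoff
    match_mode: str = "greedy"  # or "mutual" (strict reciprocal best hit)
    protein_scheme: ScoringScheme = PROTEIN_SCHEME
    nucleotide_scheme: ScoringScheme = NUCLEOTIDE_SCHEME
    window_bp: int = 10_000
    min_count: int = 5
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    seed: int = 0

    def __post_init__(self):
        if self.e_cutoff <= 0 or self.relaxed_e <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must lie in [0, 100]")


class GenomeComparison:
    """Two annotated genomes plus the comparison parameters.

    Parameters
    ----------
    genome_a, genome_b : GenomeRecord
        The two replicons to compare.
    config : RunConfig, optional
    """

    def __init__(self, genome_a: GenomeRecord, genome_b: GenomeRecord,
                 config: RunConfig | None = None):
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, path_a, path_b, format: str | None = None,
                   config: RunConfig | None = None) -> "GenomeComparison":
        return cls(gio.read_genome(path_a, format), gio.read_genome(path_b, format),
                   config)

    def fit(self) -> "ComparisonResults":
        cfg = self.config
        A, B = self.genome_a, self.genome_b
        prot_a = A.proteins()
        prot_b = B.proteins()
        rna_a = A.rna_seqs()
        rna_b = B.rna_seqs()
        e_report = max(cfg.e_cutoff, cfg.relaxed_e, cfg.classifier.relaxed_e)

        logger.info("search: %d vs %d proteins, e_report=%g",
                    len(prot_a), len(prot_b), e_report)
        hits_ab, hits_ba = search.search_both(
            prot_a, prot_b, cfg.protein_scheme, e_report=e_report
        )
        matches = orthologs.one_to_one_match(
            hits_ab, hits_ba, cfg.e_cutoff, mode=cfg.match_mode
        )
        dropped: list = []
        pairs = orthologs.validate_pairs(
            matches, prot_a, prot_b, cfg.protein_scheme,
            min_identity=cfg.min_identity, log=dropped,
        )
        logger.info("match: %d candidates, %d validated (%d dropped <%g%% identity)",
                    len(matches), len(pairs), len(dropped), cfg.min_identity)

        rna_pairs: list = []
        if rna_a and rna_b:
            rhits_ab, rhits_ba = search.search_both(
                rna_a, rna_b, cfg.nucleotide_scheme, e_report=cfg.e_cutoff
            )
            rmatches = orthologs.one_to_one_match(
                rhits_ab, rhits_ba, cfg.e_cutoff, mode=cfg.match_mode
            )
            rna_pairs = orthologs.validate_pairs(
                rmatches, rna_a, rna_b, cfg.nucleotide_scheme,
                min_identity=cfg.min_identity,
            )
        part = orthologs.partition(A, B, pairs, rna_pairs)
        logger.info("partition: %d CDS pairs, %d unique in A, %d unique in B",
                    len(part.pairs), len(part.unique_a), len(part.unique_b))

        points = synteny.dot_points(part, A, B)

        # origin classification needs intra-genome hits for the unique sets
        relaxed = cfg.classifier.relaxed_e
        hits_ab_relaxed = [h for h in hits_ab if h.evalue <= relaxed]
        hits_ba_relaxed = [h for h in hits_ba if h.evalue <= relaxed]
        intra_a = _intra_hits(part.unique_a, prot_a, cfg)
        intra_b = _intra_hits(part.unique_b, prot_b, cfg)
        labels_a = origins.classify_unique(
            part.unique_a, A, B, hits_ab_relaxed, intra_a, pairs,
            cfg.classifier, x_side="a",
        )
        labels_b = origins.classify_unique(
            part.unique_b, B, A, hits_ba_relaxed, intra_b, pairs,
            cfg.classifier, x_side="b",
        )
        return ComparisonResults(
            model=self, partition=part, points=points,
            hits_ab=hits_ab, hits_ba=hits_ba,
            origin_labels={"A": labels_a, "B": labels_b},
            dropped_pairs=dropped,
        )


def _intra_hits(unique_tags, proteome, cfg: RunConfig):
    if not unique_tags:
        return []
    queries = {t: proteome[t] for t in unique_tags if t in proteome}
    return search.all_vs_all(
        queries, proteome, cfg.protein_scheme,
        e_report=cfg.classifier.strict_e, details=False,
    ) if queries else []


class ComparisonResults:
    """Fitted comparison: ortholog map, partition, synteny, origin calls."""

    def __init__(self, model, partition, points, hits_ab, hits_ba,
                 origin_labels, dropped_pairs):
        self.model = model
        self.config = model.config
        self.partition = partition
        self.points = points
        self.hits_ab = hits_ab
        self.hits_ba = hits_ba
        self.origin_labels = origin_labels
        self.dropped_pairs = dropped_pairs

    # -- derived tables -------------------------------------------------
    @property
    def pairs(self) -> pd.DataFrame:
        return orthologs.pairs_to_frame(self.partition.pairs)

    def bins(self) -> pd.DataFrame:
        """E-value band distribution of the validated pairs."""
        return orthologs.bin_pairs(self.partition.pairs)

    def origin_summary(self, genome: str = "A") -> origins.OriginSummary:
        return origins.summarize_origins(self.origin_labels[genome])

    def unique_regions(self, genome: str = "A", window_bp: int | None = None,
                       min_count: int | None = None):
        g = self.model.genome_a if genome == "A" else self.model.genome_b
        uniq = set(
            self.partition.unique_a if genome == "A" else self.partition.unique_b
        )
        feats = [f for f in g.features if f.locus_tag in uniq]
        return synteny.unique_regions(
            feats,
            window_bp if window_bp is not None else self.config.window_bp,
            min_count if min_count is not None else self.config.min_count,
            genome=genome,
        )

    def summary_report(self) -> pd.DataFrame:
        """Per-genome comparison report (size, G+C, shared/unique counts)."""
        rows = []
        part = self.partition
        for name, g, uniq, runiq in (
            ("A", self.model.genome_a, part.unique_a, part.rna_unique_a),
            ("B", self.model.genome_b, part.unique_b, part.rna_unique_b),
        ):
            n_cds = len(g.cds_features(comparable_only=True))
            rows.append(
                {
                    "genome": name,
                    "record_id": g.record_id,
                    "organism": g.organism,
                    "size_bp": len(g.seq),
                    "gc_molpct": gc_content(g),
                    "n_cds": n_cds,
                    "cds_in_common": len(part.pairs),
                    "cds_not_in_common": len(uniq),
                    "n_trna": count_features(g, "tRNA"),
                    "n_rrna": count_features(g, "rRNA"),
                    "rna_in_common": len(part.rna_pairs),
                    "rna_not_in_common": len(runiq),
                }
            )
        df = pd.DataFrame(rows)
        for _, r in df.iterrows():
            assert r.cds_in_common + r.cds_not_in_common == r.n_cds, (
                "report arithmetic violated"
            )
        return df

    def summary(self) -> str:
        """Human-readable report in the style of a fit summary."""
        rep = self.summary_report()
        lines = ["Two-genome comparison", "=" * 60]
        lines.append(
            f"E-value cutoff: {self.config.e_cutoff:g}   "
            f"min identity: {self.config.min_identity:g}%   "
            f"matching: {self.config.match_mode}"
        )
        lines.append("-" * 60)
        for _, r in rep.iterrows():
            lines.append(
                f"Genome {r.genome} ({r.record_id}): {r.size_bp:,} bp, "
                f"G+C {r.gc_molpct:.2f} mol%, {r.n_cds} CDS"
            )
        r0 = rep.iloc[0]
        lines.append(
            f"CDS in common: {r0.cds_in_common}   "
            f"not in common: {rep.iloc[0].cds_not_in_common} (A) / "
            f"{rep.iloc[1].cds_not_in_common} (B)"
        )
        lines.append(
            f"RNA in common: {r0.rna_in_common}   "
            f"not in common: {rep.iloc[0].rna_not_in_common} (A) / "
            f"{rep.iloc[1].rna_not_in_common} (B)"
        )
        lines.append("-" * 60)
        for genome in ("A", "B"):
            s = self.origin_summary(genome)
            if s.n_total:
                parts = ", ".join(
                    f"{lab} {s.fractions[lab]:.1f}%" for lab in origins.LABELS
                    if s.counts[lab]
                )
                lines.append(f"Origins of unique CDS in {genome}: {parts}")
        n_anti = sum(1 for p in self.points if p.orientation == "antiparallel")
        lines.append(
            f"Synteny: {len(self.points)} ortholog points, {n_anti} antiparallel"
        )
        return "\n".join(lines)

    def audit_catalogue(self, entries) -> pd.DataFrame:
        return audit_catalogue(entries, self.partition,
                               self.model.genome_a, self.model.genome_b)

    def to_dir(self, outdir) -> None:
        """Write all tabular artifacts as TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        orthologs.pairs_to_frame(self.partition.rna_pairs).to_csv(
            outdir / "rna_pairs.tsv", sep="\t", index=False)
        pd.DataFrame({"locus_tag": self.partition.unique_a}).to_csv(
            outdir / "unique_a.tsv", sep="\t", index=False)
        pd.DataFrame({"locus_tag": self.partition.unique_b}).to_csv(
            outdir / "unique_b.tsv", sep="\t", index=False)
        self.bins().to_csv(outdir / "bins.tsv", sep="\t", index=False)
        search.hits_to_frame(self.hits_ab).to_csv(
            outdir / "hits_ab.tsv", sep="\t", index=False)
        search.hits_to_frame(self.hits_ba).to_csv(
            outdir / "hits_ba.tsv", sep="\t", index=False)
        synteny.points_to_frame(self.points).to_csv(
            outdir / "synteny_points.tsv", sep="\t", index=False)
        for genome in ("A", "B"):
            origins.labels_to_frame(self.origin_labels[genome]).to_csv(
                outdir / f"origins_{genome.lower()}.tsv", sep="\t", index=False)
            origins.summary_to_frame(self.origin_summary(genome)).to_csv(
                outdir / f"origin_summary_{genome.lower()}.tsv", sep="\t",
                index=False)
        self.summary_report().to_csv(outdir / "report.tsv", sep="\t", index=False)


def run_pipeline(config: RunConfig, genome_a: GenomeRecord,
                 genome_b: GenomeRecord, outdir=None) -> ComparisonResults:
    """Execute the full pipeline; optionally write all artifacts to outdir."""
    res = GenomeComparison(genome_a, genome_b, config).fit()
    if outdir is not None:
        res.to_dir(outdir)
    return res


# ---------------------------------------------------------------------------
# Catalogue audit


@dataclass
class CatalogueEntry:
    """A curated functional-catalogue row: a gene (pair) expected in the map."""

    category: str
    locus_a: str | None
    locus_b: str | None
    expected_pairing: bool = True

    def __post_init__(self):
        if not self.locus_a and not self.locus_b:
            raise ValueError("catalogue entry needs at least one locus tag")


def load_catalogue(path=None) -> list[CatalogueEntry]:
    """Load a catalogue TSV (category, locus_a, locus_b, expected_pairing).

    Without a path, loads the packaged catalogue of methanogenesis and
    energy-conservation genes of *M. marburgensis* (MTBMA_c tags) and
    *M. thermautotrophicus* (MTH tags).
    """
    if path is None:
        path = Path(__file__).parent / "data" / "catalogue.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = []
    for _, r in df.iterrows():
        entries.append(
            CatalogueEntry(
                category=str(r["category"]),
                locus_a=None if pd.isna(r["locus_a"]) else str(r["locus_a"]),
                locus_b=None if pd.isna(r["locus_b"]) else str(r["locus_b"]),
                expected_pairing=bool(r["expected_pairing"]),
            )
        )
    return entries


def audit_catalogue(entries, partition, genome_a: GenomeRecord,
                    genome_b: GenomeRecord) -> pd.DataFrame:
    """Check a curated gene catalogue against the computed ortholog map.

    Statuses: ``paired`` (the two tags form a computed pair), ``unpaired``
    (both present but not paired together), ``single_present`` /
    ``single_absent`` (one-sided entries), ``missing_locus`` (a listed tag
    is absent from its genome's annotation).
    """
    tags_a = {f.locus_tag for f in genome_a.features}
    tags_b = {f.locus_tag for f in genome_b.features}
    pair_ab = {p.id_a: p.id_b for p in partition.pairs}
    pair_ab.update({p.id_a: p.id_b for p in partition.rna_pairs})
    rows = []
    for e in entries:
        a_found = e.locus_a in tags_a if e.locus_a else None
        b_found = e.locus_b in tags_b if e.locus_b else None
        if e.locus_a and e.locus_b:
            if not a_found or not b_found:
                status = "missing_locus"
            elif pair_ab.get(e.locus_a) == e.locus_b:
                status = "paired"
            else:
                status = "unpaired"
            mismatch = (status == "paired") != e.expected_pairing
        else:
            present = a_found if e.locus_a else b_found
            status = "single_present" if present else "missing_locus"
            mismatch = not present
        rows.append(
            {
                "category": e.category,
                "locus_a": e.locus_a or "",
                "locus_b": e.locus_b or "",
                "expected_pairing": e.expected_pairing,
                "status": status,
                "mismatch": mismatch,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "locus_a", "locus_b", "expected_pairing",
                       "status", "mismatch"],
    )
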