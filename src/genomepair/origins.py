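"""Origin classification of lineage-specific (non-shared) CDS.

Each CDS without a one-to-one partner is traced to one of four event
classes — frameshift gene split, gene deletion in the partner lineage,
gene duplication, or lateral gene transfer — by a fixed-precedence rule
set over relaxed-cutoff homology hits and gene composition:

1. *split*: the CDS and an adjacent same-strand CDS (within ``gap_max`` bp)
   hit the same single partner CDS on essentially non-overlapping subject
   segments whose union covers at least ``cov_min`` of the partner; the
   neighbour is either itself unique or already paired with that partner
   (after one fragment of a split wins the one-to-one match, the other is
   left unique).
2. *duplication*: the CDS has an intra-genome homolog at the strict cutoff
   whose own ortholog exists — it is the extra copy.
3. *lateral_transfer*: no partner-genome homolog at the relaxed cutoff and
   the gene is a composition outlier (|z| >= ``z_min`` on gene GC or GC3
   against the genome-wide gene distribution).
4. *deletion*: no partner-genome homolog at the relaxed cutoff and typical
   composition — interpreted as loss in the partner lineage.
5. *unclassified* otherwise.

Rules are applied in this order; the first that fires wins, which makes the
labels independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .orthologs import OrthologPair
from .records import GenomeRecord, gene_gc_stats
from .search import LocalHit


@dataclass(frozen=True)
class ClassifierParams:
    strict_e: float = 1e-8
    relaxed_e: float = 1e-4
    gap_max: int = 300  # max intergenic distance for split adjacency (bp)
    cov_min: float = 0.6  # min combined subject coverage of a split pair
    overlap_max: float = 0.2  # max fractional overlap of the two subject spans
    z_min: float = 2.5  # composition outlier threshold (gene GC / GC3)


@dataclass
class OriginLabel:
    locus_tag: str
    label: str  # split | duplication | lateral_transfer | deletion | unclassified
    evidence: str = ""


@dataclass
class OriginSummary:
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


LABELS = ("split", "duplication", "lateral_transfer", "deletion", "unclassified")


def _gc_zscores(genome: GenomeRecord) -> dict[str, tuple[float, float]]:
    """Per-CDS (z_GC, z_GC3) against the genome-wide gene distribution."""
    tags, gcs, gc3s = [], [], []
    for f in genome.cds_features():
        gc, gc3 = gene_gc_stats(f, genome.seq)
        tags.append(f.locus_tag)
        gcs.append(gc)
        gc3s.append(gc3 if gc3 is not None else np.nan)
    gcs = np.asarray(gcs)
    gc3s = np.asarray(gc3s)

    def z(v):
        mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return np.zeros_like(v)
        return (v - mu) / sd

    zg, zg3 = z(gcs), z(gc3s)
    return {t: (float(a), float(b)) for t, a, b in zip(tags, zg, zg3)}


def _span_union_coverage(span1, span2, subject_len):
    s1, e1 = span1
    s2, e2 = span2
    inter = max(0, min(e1, e2) - max(s1, s2))
    union = (e1 - s1) + (e2 - s2) - inter
    shorter = min(e1 - s1, e2 - s2)
    overlap_frac = inter / shorter if shorter > 0 else 1.0
    return union / subject_len, overlap_frac


def classify_unique(
    unique_tags: list[str],
    genome_x: GenomeRecord,
    genome_y: GenomeRecord,
    hits_xy: list[LocalHit],
    intra_hits_x: list[LocalHit],
    pairs: list[OrthologPair],
    params: ClassifierParams = ClassifierParams(),
    x_side: str = "a",
) -> list[OriginLabel]:
    """Label every unique CDS of genome X (see module docstring for rules).

    ``hits_xy`` are X-vs-Y local hits at (or below) the relaxed cutoff;
    ``intra_hits_x`` are X-vs-X hits (self-hits ignored); ``pairs`` is the
    validated ortholog pair list, with ``x_side`` naming which side of each
    pair belongs to genome X.
    """
    unique_set = set(unique_tags)
    y_len = {f.locus_tag: len(f.translation or "") for f in genome_y.cds_features()}
    paired_x = {(p.id_a if x_side == "a" else p.id_b) for p in pairs}
    partner_of_x = {
        (p.id_a if x_side == "a" else p.id_b): (p.id_b if x_side == "a" else p.id_a)
        for p in pairs
    }

    hits_by_query: dict[str, list[LocalHit]] = {}
    for h in hits_xy:
        if h.evalue <= params.relaxed_e:
            hits_by_query.setdefault(h.qid, []).append(h)

    intra_by_query: dict[str, list[LocalHit]] = {}
    for h in intra_hits_x:
        if h.qid != h.sid and h.evalue <= params.strict_e:
            intra_by_query.setdefault(h.qid, []).append(h)

    cds_order = [f for f in genome_x.features if f.ftype == "CDS"]
    index_of = {f.locus_tag: i for i, f in enumerate(cds_order)}
    zscores = _gc_zscores(genome_x)

    labels: list[OriginLabel] = []
    for tag in unique_tags:
        label, evidence = _classify_one(
            tag, unique_set, cds_order, index_of, hits_by_query, intra_by_query,
            paired_x, partner_of_x, y_len, zscores, params,
        )
        labels.append(OriginLabel(locus_tag=tag, label=label, evidence=evidence))
    return labels


def _classify_one(
    tag, unique_set, cds_order, index_of, hits_by_query, intra_by_query,
    paired_x, partner_of_x, y_len, zscores, params,
):
    # rule 1: frameshift gene split
    i = index_of.get(tag)
    if i is not None:
        feat = cds_order[i]
        my_hits = {h.sid: h for h in hits_by_query.get(tag, [])}
        for j in (i - 1, i + 1):
            if not 0 <= j < len(cds_order):
                continue
            nb = cds_order[j]
            if nb.strand != feat.strand:
                continue
            gap = max(nb.start, feat.start) - min(nb.end, feat.end)
            if gap > params.gap_max:
                continue
            nb_ok = nb.locus_tag in unique_set or nb.locus_tag in paired_x
            if not nb_ok:
                continue
            nb_hits = {h.sid: h for h in hits_by_query.get(nb.locus_tag, [])}
            if nb.locus_tag in partner_of_x:
                # the neighbour already pairs with the intact partner gene
                nb_hits = {
                    s: h for s, h in nb_hits.items()
                    if s == partner_of_x[nb.locus_tag]
                }
            shared = set(my_hits) & set(nb_hits)
            for sid in sorted(shared):
                slen = y_len.get(sid, 0)
                if slen <= 0:
                    continue
                cov, overlap = _span_union_coverage(
                    my_hits[sid].s_span, nb_hits[sid].s_span, slen
                )
                if overlap <= params.overlap_max and cov >= params.cov_min:
                    return "split", (
                        f"neighbour={nb.locus_tag};partner={sid};"
                        f"coverage={cov:.2f};overlap={overlap:.2f};gap={gap}"
                    )

    # rule 2: duplication (extra copy of a gene that still has its ortholog)
    for h in sorted(intra_by_query.get(tag, []), key=lambda h: (h.evalue, h.sid)):
        if h.sid in paired_x:
            return "duplication", (
                f"paralog={h.sid};paralog_partner={partner_of_x[h.sid]};"
                f"evalue={h.evalue:.2e}"
            )

    has_partner_homolog = bool(hits_by_query.get(tag))
    z_gc, z_gc3 = zscores.get(tag, (0.0, 0.0))
    is_outlier = abs(z_gc) >= params.z_min or abs(z_gc3) >= params.z_min

    # rules 3/4: no homolog in the partner genome at the relaxed cutoff
    if not has_partner_homolog:
        if is_outlier:
            return "lateral_transfer", f"z_gc={z_gc:.2f};z_gc3={z_gc3:.2f};no_partner_hit"
        return "deletion", f"z_gc={z_gc:.2f};z_gc3={z_gc3:.2f};no_partner_hit"

    best = min(hits_by_query[tag], key=lambda h: (h.evalue, h.sid))
    return "unclassified", (
        f"partner_hit={best.sid};evalue={best.evalue:.2e};"
        f"z_gc={z_gc:.2f};z_gc3={z_gc3:.2f}"
    )


def summarize_origins(labels: list[OriginLabel]) -> OriginSummary:
    """Counts and percentages per origin class (split fragments count per CDS)."""
    counts = {lab: 0 for lab in LABELS}
    for l in labels:
        counts[l.label] += 1
    n = sum(counts.values())
    fractions = {
        lab: (round(100.0 * c / n, 1) if n else 0.0) for lab, c in counts.items()
    }
    return OriginSummary(counts=counts, fractions=fractions)


def labels_to_frame(labels: list[OriginLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"locus_tag": l.locus_tag, "label": l.label, "evidence": l.evidence}
         for l in labels],
        columns=["locus_tag", "label", "evidence"],
    )


def summary_to_frame(summary: OriginSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": lab, "count": summary.counts.get(lab, 0),
          "fraction_pct": summary.fractions.get(lab, 0.0)} for lab in LABELS],
        columns=["label", "count", "fraction_pct"],
    )
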