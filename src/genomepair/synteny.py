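"""Synteny dot plot, origin rotation, and unique-CDS hotspot detection.

Synteny here is derived from the computed ortholog map (one point per
ortholog pair at the feature midpoints), not from raw nucleotide anchoring;
a point is *colinear* when the paired features lie on the same strand and
*antiparallel* when an inversion has flipped one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from Bio.Seq import Seq

from .orthologs import GenomePartition
from .records import Feature, GenomeRecord, GenomeValidationError


@dataclass
class SyntenyPoint:
    x: float  # midpoint of the A feature (bp)
    y: float  # midpoint of the B feature (bp)
    orientation: str  # "colinear" | "antiparallel"
    id_a: str = ""
    id_b: str = ""


@dataclass
class UniqueRegion:
    genome: str  # "A" or "B"
    start: int
    end: int
    n_unique: int
    members: tuple[str, ...] = ()


def rotate_origin(g: GenomeRecord, anchor_locus: str) -> GenomeRecord:
    """Rotate a circular replicon so the anchor CDS starts at position 0.

    Strands are preserved; a feature that would span the new origin raises.
    Composition of rotations equals a single rotation (group property).
    """
    if not g.circular:
        raise GenomeValidationError(f"{g.record_id}: cannot rotate a linear genome")
    anchor = g.feature_by_tag(anchor_locus)  # KeyError if absent
    shift = anchor.start
    length = len(g.seq)
    new_seq = g.seq[shift:] + g.seq[:shift]
    new_features = []
    for f in g.features:
        ns = (f.start - shift) % length
        ne = ns + (f.end - f.start)
        if ne > length:
            raise GenomeValidationError(
                f"{g.record_id}/{f.locus_tag}: feature would span the origin "
                f"after rotation to {anchor_locus}"
            )
        new_features.append(replace(f, start=ns, end=ne))
    new_features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return GenomeRecord(
        record_id=g.record_id, organism=g.organism, circular=True,
        seq=new_seq, features=new_features,
    )


def dot_points(
    part: GenomePartition, A: GenomeRecord, B: GenomeRecord,
    include_rna: bool = False,
) -> list[SyntenyPoint]:
    """One synteny point per ortholog pair at the feature midpoints."""
    points: list[SyntenyPoint] = []
    pair_sets = [part.pairs] + ([part.rna_pairs] if include_rna else [])
    feats_a = {f.locus_tag: f for f in A.features}
    feats_b = {f.locus_tag: f for f in B.features}
    for pairs in pair_sets:
        for p in pairs:
            fa, fb = feats_a[p.id_a], feats_b[p.id_b]
            orient = "colinear" if fa.strand == fb.strand else "antiparallel"
            points.append(
                SyntenyPoint(x=fa.midpoint, y=fb.midpoint, orientation=orient,
                             id_a=p.id_a, id_b=p.id_b)
            )
    return points


def unique_regions(
    unique_features: list[Feature],
    window_bp: int,
    min_count: int,
    genome: str = "A",
) -> list[UniqueRegion]:
    """Runs of unique CDS whose midpoints lie within ``window_bp`` of the
    previous member; runs with at least ``min_count`` members are reported.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    feats = sorted(unique_features, key=lambda f: f.midpoint)
    regions: list[UniqueRegion] = []
    run: list[Feature] = []

    def flush():
        if len(run) >= min_count:
            regions.append(
                UniqueRegion(
                    genome=genome,
                    start=min(f.start for f in run),
                    end=max(f.end for f in run),
                    n_unique=len(run),
                    members=tuple(f.locus_tag for f in run),
                )
            )

    for f in feats:
        if run and f.midpoint - run[-1].midpoint > window_bp:
            flush()
            run = []
        run.append(f)
    if run:
        flush()
    return regions


def reverse_complement_genome(g: GenomeRecord) -> GenomeRecord:
    """Reverse-complement a record, flipping all feature coordinates/strands."""
    length = len(g.seq)
    new_features = [
        replace(
            f,
            start=length - f.end,
            end=length - f.start,
            strand="-" if f.strand == "+" else "+",
        )
        for f in g.features
    ]
    new_features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return GenomeRecord(
        record_id=g.record_id, organism=g.organism, circular=g.circular,
        seq=str(Seq(g.seq).reverse_complement()), features=new_features,
    )


def points_to_frame(points: list[SyntenyPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"x": p.x, "y": p.y, "orientation": p.orientation,
             "id_a": p.id_a, "id_b": p.id_b}
            for p in points
        ],
        columns=["x", "y", "orientation", "id_a", "id_b"],
    )


def regions_to_frame(regions: list[UniqueRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"genome": r.genome, "start": r.start + 1, "end": r.end,
             "n_unique": r.n_unique, "members": ",".join(r.members)}
            for r in regions
        ],
        columns=["genome", "start", "end", "n_unique", "members"],
    )


def plot_dot(points: list[SyntenyPoint], path, regions=None, title=""):
    """Static dot plot (colinear red, antiparallel blue); optional region bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for orient, color in (("colinear", "tab:red"), ("antiparallel", "tab:blue")):
        xs = [p.x for p in points if p.orientation == orient]
        ys = [p.y for p in points if p.orientation == orient]
        ax.scatter(xs, ys, s=4, c=color, label=orient)
    if regions:
        for r in regions:
            if r.genome == "A":
                ax.axvspan(r.start, r.end, color="0.85", zorder=0)
            else:
                ax.axhspan(r.start, r.end, color="0.85", zorder=0)
    ax.set_xlabel("genome A position (bp)")
    ax.set_ylabel("genome B position (bp)")
    ax.legend(loc="best", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
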