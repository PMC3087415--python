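"""Annotated replicon records and per-replicon summary statistics.

Coordinates are 0-based half-open throughout the library; conversion to the
1-based inclusive convention happens only at the file-format boundary
(:mod:`genomepair.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "other_RNA")
RNA_TYPES = ("tRNA", "rRNA", "other_RNA")

#: NCBI translation table used for bacterial/archaeal CDS.
TRANSLATION_TABLE = 11


class GenomeValidationError(ValueError):
    """A record or feature violates the coordinate/annotation contract."""


@dataclass
class Feature:
    """One typed gene feature on a replicon.

    Attributes
    ----------
    locus_tag : str
        Stable per-genome identifier (unique within a record).
    ftype : str
        One of ``CDS``, ``tRNA``, ``rRNA``, ``other_RNA``.
    start, end : int
        0-based half-open interval on the forward strand.
    strand : str
        ``'+'`` or ``'-'``.
    product : str
        Free-text functional annotation.
    translation : str or None
        Amino-acid sequence for CDS features (no trailing stop).
    has_internal_stop : bool
        Set when software translation finds an in-frame stop; such CDS are
        excluded from protein-level comparison.
    """

    locus_tag: str
    ftype: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str | None = None
    has_internal_stop: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeValidationError(
                f"{self.locus_tag}: unknown feature type {self.ftype!r}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def is_rna(self) -> bool:
        return self.ftype in RNA_TYPES

    def nucleotide_seq(self, genome_seq: str) -> str:
        """Spliced-out gene sequence in reading orientation."""
        sub = genome_seq[self.start : self.end]
        if self.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclass
class GenomeRecord:
    """An annotated replicon: sequence plus an ordered feature list."""

    record_id: str
    organism: str
    circular: bool
    seq: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.seq) == 0:
            raise GenomeValidationError(f"{self.record_id}: empty sequence")
        length = len(self.seq)
        seen: set[str] = set()
        prev_start = -1
        for f in self.features:
            if f.end > length:
                raise GenomeValidationError(
                    f"{self.record_id}/{f.locus_tag}: feature end {f.end} exceeds "
                    f"sequence length {length}"
                )
            if f.locus_tag in seen:
                raise GenomeValidationError(
                    f"{self.record_id}: duplicate locus_tag {f.locus_tag}"
                )
            seen.add(f.locus_tag)
            if f.start < prev_start:
                raise GenomeValidationError(
                    f"{self.record_id}: features not sorted by start "
                    f"(at {f.locus_tag})"
                )
            prev_start = f.start

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_tag(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"{self.record_id}: no feature with locus_tag {locus_tag!r}")

    def cds_features(self, comparable_only: bool = False) -> list[Feature]:
        feats = [f for f in self.features if f.ftype == "CDS"]
        if comparable_only:
            feats = [f for f in feats if not f.has_internal_stop]
        return feats

    def rna_features(self) -> list[Feature]:
        return [f for f in self.features if f.is_rna]

    def proteins(self, comparable_only: bool = True) -> dict[str, str]:
        """locus_tag -> amino-acid sequence for (comparable) CDS."""
        out: dict[str, str] = {}
        for f in self.cds_features(comparable_only=comparable_only):
            if f.translation:
                out[f.locus_tag] = f.translation
        return out

    def rna_seqs(self) -> dict[str, str]:
        """locus_tag -> nucleotide sequence for RNA genes."""
        return {f.locus_tag: f.nucleotide_seq(self.seq) for f in self.rna_features()}

    def copy(self) -> "GenomeRecord":
        return GenomeRecord(
            record_id=self.record_id,
            organism=self.organism,
            circular=self.circular,
            seq=self.seq,
            features=[replace(f) for f in self.features],
        )


def translate_cds(nt_seq: str) -> tuple[str, bool]:
    """Translate a CDS with the bacterial/archaeal code (table 11).

    Returns ``(protein, has_internal_stop)``; the trailing stop (if any) is
    stripped and does not count as internal.
    """
    aa = str(Seq(nt_seq[: len(nt_seq) - len(nt_seq) % 3]).translate(
        table=TRANSLATION_TABLE
    ))
    if aa.endswith("*"):
        aa = aa[:-1]
    internal = "*" in aa
    return aa.replace("*", "X") if internal else aa, internal


def gc_content(g: GenomeRecord | str) -> float:
    """G+C mol% of a replicon sequence, to 2 decimals.

    ``N`` (and any other ambiguity code) is excluded from the denominator.
    """
    seq = g.seq if isinstance(g, GenomeRecord) else g
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise GenomeValidationError("G+C content undefined: no unambiguous bases")
    return round(100.0 * gc / atgc, 2)


def count_features(g: GenomeRecord, ftype: str) -> int:
    """Exact count of features of one type."""
    if ftype not in FEATURE_TYPES:
        raise GenomeValidationError(f"unknown feature type {ftype!r}")
    return sum(1 for f in g.features if f.ftype == ftype)


def gene_gc_stats(f: Feature, genome_seq: str) -> tuple[float, float | None]:
    """(GC fraction, GC3 fraction) of one gene; GC3 only for CDS."""
    nt = f.nucleotide_seq(genome_seq).upper()
    gc = sum(1 for c in nt if c in "GC") / len(nt)
    gc3 = None
    if f.ftype == "CDS":
        third = nt[2::3]
        if third:
            gc3 = sum(1 for c in third if c in "GC") / len(third)
    return gc, gc3
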