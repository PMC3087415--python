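"""Readers/writers for GenBank and GFF3+FASTA annotated genomes.

External files use the standard 1-based inclusive coordinates; everything is
converted to the library's 0-based half-open convention on read and back on
write. Features spanning the origin of a circular replicon are rejected —
the comparisons implemented here do not depend on wrap handling.
"""

from __future__ import annotations

import io as _io
import urllib.parse
from pathlib import Path

import gffutils
from Bio import SeqIO

from .records import (
    Feature,
    GenomeRecord,
    GenomeValidationError,
    count_features,
    gc_content,
    translate_cds,
)


class GenomeParseError(ValueError):
    """Input file is malformed under the named standard."""


_GENBANK_TYPE_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "other_RNA",
    "tmRNA": "other_RNA",
    "misc_RNA": "other_RNA",
}

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "other_RNA",
    "tmRNA": "other_RNA",
    "transcript": "other_RNA",
}


def read_genome(path: str | Path, format: str | None = None) -> GenomeRecord:
    """Read one annotated replicon.

    Parameters
    ----------
    path : path
        GenBank flat file, or a GFF3 file (annotation with an embedded
        ``##FASTA`` section, or with a sibling ``.fna``/``.fasta``/``.fa``).
    format : {"genbank", "gff3+fasta"}, optional
        Autodetected from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
            format = "genbank"
        elif suffix in (".gff", ".gff3"):
            format = "gff3+fasta"
        else:
            raise GenomeParseError(f"cannot infer format from suffix {suffix!r}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "gff3+fasta":
        return _read_gff3_fasta(path)
    raise GenomeParseError(f"unknown format {format!r}")


def _span_of_location(location, length: int, tag: str):
    """Overall 0-based span of a (possibly compound) Biopython location."""
    parts = location.parts
    starts = [int(p.start) for p in parts]
    if any(starts[i] > starts[i + 1] for i in range(len(starts) - 1)):
        raise GenomeValidationError(
            f"feature {tag}: location spans the circular origin; "
            "rotate the record before annotation instead"
        )
    return int(location.start), int(location.end)


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise GenomeParseError(f"{path}: not a valid GenBank file: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no GenBank records found")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise GenomeParseError(f"{path}: record {rec.id} has no usable sequence")
    circular = rec.annotations.get("topology", "linear") == "circular"
    organism = rec.annotations.get("organism", "")
    features: list[Feature] = []
    counter = 0
    for gbf in rec.features:
        ftype = _GENBANK_TYPE_MAP.get(gbf.type)
        if ftype is None:
            continue
        counter += 1
        tag = gbf.qualifiers.get("locus_tag", [f"{rec.id}_f{counter:05d}"])[0]
        if gbf.location is None:
            raise GenomeParseError(f"{path}: feature {tag} has no location")
        start, end = _span_of_location(gbf.location, len(seq), tag)
        strand = "-" if gbf.location.strand == -1 else "+"
        product = gbf.qualifiers.get("product", [""])[0]
        translation = None
        internal = False
        if ftype == "CDS":
            if gbf.qualifiers.get("pseudo") is not None or "pseudogene" in gbf.qualifiers:
                internal = True  # annotated pseudogene: keep out of protein comparison
            if "translation" in gbf.qualifiers:
                translation = gbf.qualifiers["translation"][0].rstrip("*")
            else:
                nt = str(gbf.extract(rec.seq))
                translation, stop_found = translate_cds(nt)
                internal = internal or stop_found
        features.append(
            Feature(
                locus_tag=tag,
                ftype=ftype,
                start=start,
                end=end,
                strand=strand,
                product=product,
                translation=translation,
                has_internal_stop=internal,
            )
        )
    features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return GenomeRecord(
        record_id=rec.id, organism=organism, circular=circular, seq=seq,
        features=features,
    )


def _split_gff_fasta(path: Path) -> tuple[str, str | None]:
    text = path.read_text()
    if "##FASTA" in text:
        gff_part, fasta_part = text.split("##FASTA", 1)
        return gff_part, fasta_part.lstrip("\n")
    return text, None


def _read_gff3_fasta(path: Path) -> GenomeRecord:
    gff_text, fasta_text = _split_gff_fasta(path)
    if fasta_text is None:
        for suffix in (".fna", ".fasta", ".fa"):
            sib = path.with_suffix(suffix)
            if sib.exists():
                fasta_text = sib.read_text()
                break
        else:
            raise GenomeParseError(
                f"{path}: no ##FASTA section and no sibling FASTA file"
            )
    seq_records = list(SeqIO.parse(_io.StringIO(fasta_text), "fasta"))
    if not seq_records:
        raise GenomeParseError(f"{path}: FASTA section/file contains no sequences")
    rec = seq_records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise GenomeParseError(f"{path}: empty sequence for {rec.id}")

    circular = "circular=true" in gff_text.lower()
    organism = ""
    for line in gff_text.splitlines():
        if line.startswith("#!organism"):
            organism = line.split(None, 1)[1].strip()
    try:
        db = gffutils.create_db(
            gff_text, dbfn=":memory:", from_string=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise GenomeParseError(f"{path}: GFF3 parse failure: {exc}") from exc

    features: list[Feature] = []
    for gf in db.all_features():
        ftype = _GFF_TYPE_MAP.get(gf.featuretype)
        if ftype is None:
            continue
        if gf.seqid != rec.id:
            continue
        tag = (gf.attributes.get("locus_tag") or gf.attributes.get("ID") or [gf.id])[0]
        start = gf.start - 1  # GFF3 is 1-based inclusive
        end = gf.end
        if end > len(seq):
            raise GenomeValidationError(
                f"{path}: feature {tag} end {end} exceeds sequence length {len(seq)}"
            )
        strand = "-" if gf.strand == "-" else "+"
        product = urllib.parse.unquote((gf.attributes.get("product") or [""])[0])
        translation = None
        internal = False
        if ftype == "CDS":
            feat = Feature(tag, "CDS", start, end, strand, product)
            translation, internal = translate_cds(feat.nucleotide_seq(seq))
            feat.translation, feat.has_internal_stop = translation, internal
            features.append(feat)
        else:
            features.append(Feature(tag, ftype, start, end, strand, product))
    features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return GenomeRecord(
        record_id=rec.id, organism=organism, circular=circular, seq=seq,
        features=features,
    )


_GFF_REVERSE_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other_RNA": "ncRNA"}


def write_genome(g: GenomeRecord, path: str | Path, include_fasta: bool = True) -> None:
    """Write a record as GFF3 (1-based inclusive) with an embedded ##FASTA."""
    path = Path(path)
    lines = [
        "##gff-version 3",
        f"##sequence-region {g.record_id} 1 {len(g.seq)}",
    ]
    if g.organism:
        lines.append(f"#!organism {g.organism}")
    if g.circular:
        lines.append(f"# {g.record_id} circular=true")
    for f in g.features:
        attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
        if f.product:
            attrs += f";product={urllib.parse.quote(f.product, safe=' ')}"
        phase = "0" if f.ftype == "CDS" else "."
        lines.append(
            "\t".join(
                [
                    g.record_id,
                    "genomepair",
                    _GFF_REVERSE_TYPE[f.ftype],
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    phase,
                    attrs,
                ]
            )
        )
    if include_fasta:
        lines.append("##FASTA")
        lines.append(f">{g.record_id}")
        for i in range(0, len(g.seq), 70):
            lines.append(g.seq[i : i + 70])
    path.write_text("\n".join(lines) + "\n")


def summary_table(genomes: list[GenomeRecord]):
    """Per-replicon summary statistics (size, G+C, feature counts)."""
    import pandas as pd

    rows = []
    for g in genomes:
        rows.append(
            {
                "record_id": g.record_id,
                "length_bp": len(g.seq),
                "gc_molpct": gc_content(g),
                "n_cds": count_features(g, "CDS"),
                "n_trna": count_features(g, "tRNA"),
                "n_rrna": count_features(g, "rRNA"),
                "n_other_rna": count_features(g, "other_RNA"),
            }
        )
    return pd.DataFrame(rows)
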