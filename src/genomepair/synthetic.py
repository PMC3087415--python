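"""Divergent genome-pair simulator with ground-truth ortholog map.

Two annotated replicons are evolved independently from a common ancestor:
per-site amino-acid substitutions drawn from a BLOSUM62-derived exchange
process, then at most one structural event per gene per lineage (tandem
duplication, deletion, frameshift gene-split, or a compositionally shifted
lateral insertion), and finally whole-block inversions. The returned
:class:`TruthTable` records the one-to-one ortholog map and a per-gene event
log, so every downstream stage of the comparison pipeline can be scored
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .records import Feature, GenomeRecord

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Robinson–Robinson amino-acid background frequencies (order AA_ORDER).
AA_FREQS = np.array(
    [
        0.07805, 0.05129, 0.04487, 0.05364, 0.01925, 0.04264, 0.06295, 0.07377,
        0.02199, 0.05142, 0.09019, 0.05744, 0.02243, 0.03856, 0.05203, 0.07120,
        0.05841, 0.01330, 0.03216, 0.06441,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

#: Ungapped Karlin–Altschul lambda for BLOSUM62 — used only to turn the score
#: matrix into exchange probabilities q_ij = p_i p_j exp(lambda * s_ij).
_UNGAPPED_LAMBDA = 0.3176


class SimulationError(ValueError):
    pass


@dataclass
class SimParams:
    """Study conditions for one simulated genome pair.

    Event probabilities are per ancestral gene per lineage and mutually
    exclusive; ``subst_per_site`` is the expected number of amino-acid
    substitution events per site per lineage.
    """

    n_genes: int = 300
    gene_len_mean: float = 270.0  # amino acids; typical archaeal CDS
    gene_len_sd: float = 100.0
    subst_per_site: float = 0.2
    p_dup: float = 0.05
    p_del: float = 0.05
    p_split: float = 0.02
    p_hgt: float = 0.05
    n_inversions: int = 2
    inv_len_range: tuple[int, int] = (3, 12)  # genes per inverted block
    hgt_gc_shift: float = 0.12  # added to the GC3 target of lateral genes
    gc3: float = 0.5  # genome-wide third-position GC target
    spacer_len: int = 120  # mean intergenic spacer (nt)
    n_rna: int = 4  # slow-evolving tRNA-like genes, always orthologous
    rna_len: int = 80
    rna_subst_factor: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        probs = (self.p_dup, self.p_del, self.p_split, self.p_hgt)
        if any(p < 0 or p > 1 for p in probs):
            raise SimulationError("event probabilities must lie in [0, 1]")
        if sum(probs) > 1:
            raise SimulationError(
                f"p_dup+p_del+p_split+p_hgt = {sum(probs):.3f} exceeds 1"
            )
        if self.n_genes < 1:
            raise SimulationError("n_genes must be >= 1")
        if not 0 < self.gc3 < 1:
            raise SimulationError("gc3 must lie in (0, 1)")


@dataclass
class TruthTable:
    """Ground truth for a simulated pair.

    ``ortholog_map`` holds the one-to-one pairs of ancestral genes present in
    both lineages: intact-vs-intact pairs, plus — for a gene split in exactly
    one lineage — the intact copy paired with the longer fragment. ``events``
    rows are ``(lineage, locus_tag, event)``; deletion events carry the
    ancestral gene id since no tag exists in the affected lineage.
    ``ancestor_ids`` maps every simulated gene tag to its ancestral gene
    (lateral genes map to their own tag).
    """

    ortholog_map: set[tuple[str, str]] = field(default_factory=set)
    events: list[tuple[str, str, str]] = field(default_factory=list)
    ancestor_ids: dict[str, str] = field(default_factory=dict)

    def events_of(self, lineage: str, kind: str | None = None) -> list[tuple[str, str, str]]:
        return [
            e for e in self.events
            if e[0] == lineage and (kind is None or e[2] == kind)
        ]

    def expected_unique(self, lineage: str) -> dict[str, str]:
        """tag -> causal event for genes expected to lack a one-to-one partner.

        For lineage X these are X's duplication copies, split fragments and
        lateral genes, plus the X genes whose partner was deleted or split in
        the other lineage (for a split, the intact partner usually still pairs
        with one fragment; both fragments and the intact gene are listed here
        under ``split``/``split_partner`` so callers can reason about them).
        """
        other = "B" if lineage == "A" else "A"
        out: dict[str, str] = {}
        for lin, tag, ev in self.events:
            if lin == lineage and ev in ("duplication", "split", "lateral_transfer"):
                out[tag] = ev
        lost = {tag for lin, tag, ev in self.events if lin == other and ev == "deletion"}
        split_anc = {
            self.ancestor_ids.get(tag, tag)
            for lin, tag, ev in self.events
            if lin == other and ev == "split"
        }
        for tag, anc in self.ancestor_ids.items():
            if not tag.startswith("G" + lineage):
                continue
            if anc in lost:
                out.setdefault(tag, "deletion_in_partner")
            elif anc in split_anc:
                out.setdefault(tag, "split_partner")
        return out

    def to_frames(self):
        import pandas as pd

        omap = pd.DataFrame(sorted(self.ortholog_map), columns=["locus_tag_a", "locus_tag_b"])
        ev = pd.DataFrame(self.events, columns=["lineage", "locus_tag", "event"])
        anc = pd.DataFrame(
            sorted(self.ancestor_ids.items()), columns=["locus_tag", "ancestor_id"]
        )
        return omap, ev, anc


def _substitution_kernel() -> np.ndarray:
    """P(j | i, one substitution event) from BLOSUM62 target frequencies."""
    blosum = substitution_matrices.load("BLOSUM62")
    s = np.array(
        [[blosum[a, b] for b in AA_ORDER] for a in AA_ORDER], dtype=float
    )
    q = AA_FREQS[None, :] * np.exp(_UNGAPPED_LAMBDA * s)
    np.fill_diagonal(q, 0.0)  # an event always changes the residue
    return q / q.sum(axis=1, keepdims=True)


_KERNEL = _substitution_kernel()

_FORWARD_TABLE = CodonTable.unambiguous_dna_by_id[11].forward_table
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in _FORWARD_TABLE.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODONS_BY_AA.values():
    codons.sort()
_STOP_CODONS = sorted(CodonTable.unambiguous_dna_by_id[11].stop_codons)


def _sample_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(20, size=length, p=AA_FREQS)


def _evolve_protein(rng: np.random.Generator, aa: np.ndarray, rate: float) -> np.ndarray:
    out = aa.copy()
    n_events = rng.poisson(rate, size=len(aa))
    for i in np.nonzero(n_events)[0]:
        for _ in range(n_events[i]):
            out[i] = rng.choice(20, p=_KERNEL[out[i]])
    return out


def _back_translate(rng: np.random.Generator, aa: np.ndarray, gc3: float) -> str:
    codons = []
    for idx in aa:
        options = _CODONS_BY_AA[AA_ORDER[idx]]
        w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in options])
        codons.append(options[rng.choice(len(options), p=w / w.sum())])
    return "".join(codons)


_CODON_GC = {
    aa: np.array([sum(1 for b in c if b in "GC") for c in codons])
    for aa, codons in _CODONS_BY_AA.items()
}


def expected_gene_gc(gc3: float) -> float:
    """Mean codon GC fraction of background proteins under the gc3 bias."""
    total = 0.0
    for i, aa in enumerate(AA_ORDER):
        codons = _CODONS_BY_AA[aa]
        w = np.array([gc3 if c[2] in "GC" else 1.0 - gc3 for c in codons])
        w = w / w.sum()
        total += AA_FREQS[i] * float(w @ _CODON_GC[aa]) / 3.0
    return total


def _back_translate_target_gc(
    rng: np.random.Generator, aa: np.ndarray, target_gc: float
) -> str:
    """Back-translate with the maximum-entropy codon bias whose expected
    overall GC equals ``target_gc`` (clipped to what synonymous choice can
    reach for this amino-acid sequence); beta is solved by bisection.
    """

    def mean_gc(beta: float) -> float:
        tot = 0.0
        for idx in aa:
            gcs = _CODON_GC[AA_ORDER[idx]]
            w = np.exp(beta * gcs)
            tot += float(w @ gcs) / w.sum()
        return tot / (3 * len(aa))

    lo, hi = -8.0, 8.0
    target = float(np.clip(target_gc, mean_gc(lo) + 1e-4, mean_gc(hi) - 1e-4))
    for _ in range(40):
        mid = (lo + hi) / 2
        if mean_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    beta = (lo + hi) / 2
    codons = []
    for idx in aa:
        options = _CODONS_BY_AA[AA_ORDER[idx]]
        w = np.exp(beta * _CODON_GC[AA_ORDER[idx]])
        codons.append(options[rng.choice(len(options), p=w / w.sum())])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p)])


def _gene_length(rng: np.random.Generator, p: SimParams) -> int:
    return max(30, int(round(rng.normal(p.gene_len_mean, p.gene_len_sd))))


def simulate_pair(p: SimParams) -> tuple[GenomeRecord, GenomeRecord, TruthTable]:
    """Simulate two genomes diverged from a common ancestor.

    Returns genome A, genome B, and the :class:`TruthTable`. Deterministic:
    identical parameters (including seed) give byte-identical output.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    truth = TruthTable()

    # --- ancestor: protein genes plus a few slow RNA genes interleaved
    ancestor: list[dict] = []
    for i in range(p.n_genes):
        ancestor.append(
            {
                "anc_id": f"anc{i:04d}",
                "kind": "CDS",
                "aa": _sample_protein(rng, _gene_length(rng, p)),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    rna_positions = (
        np.linspace(0, p.n_genes - 1, p.n_rna).astype(int) if p.n_rna else []
    )
    rna_nt = {
        int(pos): _random_dna(rng, p.rna_len) for pos in rna_positions
    }

    lineage_specs = []
    for lineage in ("A", "B"):
        genes = _evolve_lineage(rng, p, ancestor, rna_nt, lineage, truth)
        lineage_specs.append(genes)
    genes_a, genes_b = lineage_specs

    genes_b = _apply_inversions(rng, p, genes_b, truth, lineage="B")

    # one-to-one map: ancestral genes structurally intact in both lineages;
    # a gene split in exactly one lineage pairs the intact copy with the
    # longer fragment (the shorter fragment is the expected unique CDS)
    surv_a = {g["anc_id"]: g["tag"] for g in genes_a if g["origin"] == "ancestral"}
    surv_b = {g["anc_id"]: g["tag"] for g in genes_b if g["origin"] == "ancestral"}
    frags_a = _fragments_by_ancestor(genes_a)
    frags_b = _fragments_by_ancestor(genes_b)
    for anc_id, tag_a in surv_a.items():
        if anc_id in surv_b:
            truth.ortholog_map.add((tag_a, surv_b[anc_id]))
        elif anc_id in frags_b:
            truth.ortholog_map.add((tag_a, frags_b[anc_id]))
    for anc_id, tag_b in surv_b.items():
        if anc_id not in surv_a and anc_id in frags_a:
            truth.ortholog_map.add((frags_a[anc_id], tag_b))

    genome_a = _assemble(rng, p, genes_a, "simA", "Simulated lineage A")
    genome_b = _assemble(rng, p, genes_b, "simB", "Simulated lineage B")
    return genome_a, genome_b, truth


def _fragments_by_ancestor(genes) -> dict[str, str]:
    """ancestor id -> tag of the longer split fragment (ties: first placed)."""
    best: dict[str, tuple[int, int, str]] = {}
    for order, g in enumerate(genes):
        if g["origin"] != "split":
            continue
        key = g["anc_id"]
        cand = (-len(g["aa"]), order, g["tag"])
        if key not in best or cand < best[key]:
            best[key] = cand
    return {anc: tag for anc, (_, _, tag) in best.items()}


def _evolve_lineage(rng, p: SimParams, ancestor, rna_nt, lineage: str, truth: TruthTable):
    """Apply substitutions then at most one structural event per gene."""
    genes: list[dict] = []
    counter = [0]

    def new_tag() -> str:
        counter[0] += 1
        return f"G{lineage}_{counter[0]:05d}"

    for pos, anc in enumerate(ancestor):
        # slow RNA genes ride along in front of their anchor position
        if pos in rna_nt:
            nt = rna_nt[pos]
            sub_rate = p.subst_per_site * p.rna_subst_factor
            evolved = _point_mutate(rng, nt, sub_rate)
            tag = new_tag()
            genes.append(
                {"tag": tag, "anc_id": f"rna{pos:04d}", "kind": "tRNA",
                 "nt": evolved, "strand": "+", "origin": "ancestral"}
            )
            truth.ancestor_ids[tag] = f"rna{pos:04d}"

        aa = _evolve_protein(rng, anc["aa"], p.subst_per_site)
        u = rng.random()
        cum_dup = p.p_dup
        cum_del = cum_dup + p.p_del
        cum_split = cum_del + p.p_split
        cum_hgt = cum_split + p.p_hgt

        if u < cum_dup:
            tag = new_tag()
            genes.append({"tag": tag, "anc_id": anc["anc_id"], "kind": "CDS",
                          "aa": aa, "strand": anc["strand"], "origin": "ancestral"})
            truth.ancestor_ids[tag] = anc["anc_id"]
            copy_aa = _evolve_protein(rng, aa, p.subst_per_site)  # extra divergence
            ctag = new_tag()
            genes.append({"tag": ctag, "anc_id": anc["anc_id"], "kind": "CDS",
                          "aa": copy_aa, "strand": anc["strand"], "origin": "duplication"})
            truth.ancestor_ids[ctag] = anc["anc_id"]
            truth.events.append((lineage, ctag, "duplication"))
        elif u < cum_del:
            truth.events.append((lineage, anc["anc_id"], "deletion"))
        elif u < cum_split:
            # frameshift in the middle 60%: both fragments stay detectable
            cut = int(round(len(aa) * rng.uniform(0.2, 0.8)))
            cut = min(max(cut, 10), len(aa) - 10) if len(aa) >= 20 else len(aa) // 2
            for frag in (aa[:cut], aa[cut:]):
                tag = new_tag()
                genes.append({"tag": tag, "anc_id": anc["anc_id"], "kind": "CDS",
                              "aa": frag, "strand": anc["strand"], "origin": "split",
                              "split_gap": 1})
                truth.ancestor_ids[tag] = anc["anc_id"]
                truth.events.append((lineage, tag, "split"))
        elif u < cum_hgt:
            tag = new_tag()
            genes.append({"tag": tag, "anc_id": anc["anc_id"], "kind": "CDS",
                          "aa": aa, "strand": anc["strand"], "origin": "ancestral"})
            truth.ancestor_ids[tag] = anc["anc_id"]
            htag = new_tag()
            hgt_aa = _sample_protein(rng, _gene_length(rng, p))
            genes.append({"tag": htag, "anc_id": htag, "kind": "CDS",
                          "aa": hgt_aa,
                          "strand": "+" if rng.random() < 0.5 else "-",
                          "origin": "lateral_transfer"})
            truth.ancestor_ids[htag] = htag
            truth.events.append((lineage, htag, "lateral_transfer"))
        else:
            tag = new_tag()
            genes.append({"tag": tag, "anc_id": anc["anc_id"], "kind": "CDS",
                          "aa": aa, "strand": anc["strand"], "origin": "ancestral"})
            truth.ancestor_ids[tag] = anc["anc_id"]
    return genes


def _point_mutate(rng, nt: str, rate: float) -> str:
    bases = "ACGT"
    out = list(nt)
    for i in np.nonzero(rng.random(len(nt)) < rate)[0]:
        choices = [b for b in bases if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _apply_inversions(rng, p: SimParams, genes, truth: TruthTable, lineage: str):
    """Reverse-complement n random non-overlapping gene blocks (order+strand)."""
    n = len(genes)
    lo, hi = p.inv_len_range
    occupied = np.zeros(n, dtype=bool)
    for _ in range(p.n_inversions):
        size = int(rng.integers(lo, hi + 1))
        if size >= n:
            continue
        for _attempt in range(50):
            start = int(rng.integers(0, n - size))
            if not occupied[start : start + size].any():
                break
        else:
            continue
        occupied[start : start + size] = True
        block = genes[start : start + size][::-1]
        for g in block:
            g["strand"] = "-" if g["strand"] == "+" else "+"
            truth.events.append((lineage, g["tag"], "inversion_member"))
        genes[start : start + size] = block
    return genes


def _assemble(rng, p: SimParams, genes, record_id: str, organism: str) -> GenomeRecord:
    """Back-translate and concatenate genes with random spacers."""
    from Bio.Seq import Seq

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def add_spacer(length: int | None = None):
        nonlocal pos
        if length is None:
            length = int(rng.integers(max(10, p.spacer_len // 2), p.spacer_len * 3 // 2 + 1))
        sp = _random_dna(rng, length, gc=p.gc3)
        parts.append(sp)
        pos += length

    add_spacer()
    prev_split_anc = None
    for g in genes:
        if g["kind"] == "CDS":
            if g["origin"] == "lateral_transfer":
                # composition outlier: overall gene GC offset by hgt_gc_shift
                target = expected_gene_gc(p.gc3) + p.hgt_gc_shift
                nt = _back_translate_target_gc(rng, g["aa"], target)
            else:
                nt = _back_translate(rng, g["aa"], p.gc3)
            stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
            nt = nt + stop
            aa_str = "".join(AA_ORDER[i] for i in g["aa"])
        else:
            nt = g["nt"]
            aa_str = None
        if g["strand"] == "-":
            placed = str(Seq(nt).reverse_complement())
        else:
            placed = nt
        # split fragments sit 1 bp apart (the frameshifting inserted base)
        if g["origin"] == "split" and prev_split_anc == g["anc_id"]:
            pass  # spacer already emitted as the single frameshift base
        start = pos
        parts.append(placed)
        pos += len(placed)
        features.append(
            Feature(
                locus_tag=g["tag"],
                ftype=g["kind"],
                start=start,
                end=pos,
                strand=g["strand"],
                product=f"simulated {g['origin']} gene",
                translation=aa_str,
            )
        )
        if g["origin"] == "split" and prev_split_anc != g["anc_id"]:
            prev_split_anc = g["anc_id"]
            add_spacer(1)  # the inserted frameshift base
        else:
            prev_split_anc = None
            add_spacer()
    seq = "".join(parts)
    features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
    return GenomeRecord(
        record_id=record_id, organism=organism, circular=True, seq=seq,
        features=features,
    )


def write_truth(truth: TruthTable, outdir) -> None:
    """Write ortholog_map.tsv, events.tsv and ancestors.tsv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    omap, ev, anc = truth.to_frames()
    omap.to_csv(outdir / "ortholog_map.tsv", sep="\t", index=False)
    ev.to_csv(outdir / "events.tsv", sep="\t", index=False)
    anc.to_csv(outdir / "ancestors.tsv", sep="\t", index=False)
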