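# genomepair

Comparative analysis of a pair of closely related prokaryotic genomes, built
around the questions raised by the two hydrogenotrophic methanogens
*Methanothermobacter marburgensis* and *Methanothermobacter
thermautotrophicus*: which protein- and RNA-coding genes do the two genomes
share, how is gene order conserved, and what events — frameshift gene
splitting, gene deletion, gene duplication, lateral gene transfer — explain
the genes found in only one of them?

The package is aimed at microbial comparative genomicists who want a fully
scripted, deterministic re-run of this classic two-genome analysis, either
on real annotated genomes (GenBank or GFF3+FASTA) or on simulated genome
pairs with known ground truth.

## The method

**Ortholog mapping** is the two-step procedure used for closely related
genome pairs:

1. *Bidirectional best-hit matching.* All-vs-all optimal local
   (Smith–Waterman) alignment of the two protein complements under BLOSUM62
   with affine gaps (open 11, extend 1). Raw scores *S* become bit scores
   and expectation values via Karlin–Altschul statistics,

   S′ = (λS − ln K) / ln 2,  E = m·n·2^(−S′),

   with the standard gapped constants (λ = 0.267, K = 0.041 for protein;
   λ = 0.625, K = 0.41 for the +2/−3, 5/2 nucleotide scheme). Candidate
   pairs with E < 10⁻⁸ are matched one-to-one: the union of hits from both
   search directions is sorted by ascending E-value and accepted greedily,
   so each sequence is used at most once and second-best hits never create
   pairs. RNA genes (tRNA, rRNA) are matched the same way in nucleotide
   mode.
2. *Global validation.* Each candidate pair is re-aligned end-to-end
   (Needleman–Wunsch, end gaps penalized); pairs with < 10 % identical
   columns are dropped. The percentage of columns with a positive
   substitution score is reported as the similarity score.

The validated pairs partition each genome into *shared* and *unique* CDS.
**Synteny** is drawn directly from the pair map (one dot per pair at the
feature midpoints; colinear vs antiparallel by strand agreement), with
origin rotation to a chosen anchor gene and windowed detection of regions
enriched in unique CDS. Each unique CDS is then **traced to an origin
event** by a fixed-precedence rule set: frameshift split (two adjacent
same-strand CDS covering complementary parts of one partner gene), extra
duplication copy (intra-genome paralog whose ortholog exists), lateral
transfer (no partner homolog and outlying gene GC/GC3 composition), or
deletion in the partner lineage (no partner homolog, typical composition).

A **genome-pair simulator** evolves two annotated replicons from a common
ancestor (BLOSUM62-derived residue exchange process, tunable event
probabilities, block inversions, compositionally shifted lateral genes) and
records the true ortholog map and event log, so every pipeline stage can be
scored offline.

## Worked example

```python
from genomepair import GenomeComparison, SimParams, simulate_pair

A, B, truth = simulate_pair(SimParams(n_genes=60, gene_len_mean=120,
                                      gene_len_sd=40, seed=7))
res = GenomeComparison(A, B).fit()
print(res.summary())
```

```
Two-genome comparison
============================================================
E-value cutoff: 1e-08   min identity: 10%   matching: greedy
------------------------------------------------------------
Genome A (simA): 31,611 bp, G+C 49.33 mol%, 66 CDS
Genome B (simB): 32,898 bp, G+C 49.54 mol%, 68 CDS
CDS in common: 57   not in common: 9 (A) / 11 (B)
RNA in common: 4   not in common: 0 (A) / 0 (B)
------------------------------------------------------------
Origins of unique CDS in A: split 11.1%, duplication 66.7%, lateral_transfer 11.1%, deletion 11.1%
Origins of unique CDS in B: split 9.1%, duplication 27.3%, lateral_transfer 45.5%, deletion 18.2%
Synteny: 57 ortholog points, 9 antiparallel
```

Of the 60 ancestral genes, 57 survive as one-to-one pairs; the 9 + 11
lineage-specific CDS are each assigned an origin (here dominated by the
planted duplications and deletions), and 9 pairs fall in the two inverted
blocks the simulator planted. `res.pairs`, `res.bins()`,
`res.unique_regions()` and `res.to_dir("out/")` expose the full tables;
`res.audit_catalogue(load_catalogue())` checks the packaged ~200-gene
methanogenesis/energy-conservation catalogue (MTBMA_c/MTH locus tags)
against a computed map of the real genome pair.

The same pipeline is available from the shell:

```bash
genomepair simulate --n-genes 300 --seed 1 --out sim/
genomepair compare --a sim/genome_a.gff3 --b sim/genome_b.gff3 --out cmp/
genomepair classify --a A.gbk --b B.gbk --out origins/
genomepair audit --a CP001710.gbk --b NC_000916.gbk --out audit.tsv
```

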