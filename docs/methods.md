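# Methods

This note documents the models, algorithms and numerical choices behind
`genomepair`, and what the simulation-based tests do and do not establish
about real data.

## Alignment and E-value statistics

All pairwise alignment is exact dynamic programming (Biopython's
`PairwiseAligner`); there is no heuristic seeding, so the all-vs-all search
reports every hit above the cutoff. The gap model is the common affine
convention: a gap of length L costs `gap_open + L*gap_extend`. Defaults are
BLOSUM62 with open 11 / extend 1 for proteins and +2/−3 with open 5 /
extend 2 for nucleotides, the parameterization whose cutoff behaviour the
E < 10⁻⁸ ortholog criterion presupposes.

Raw local scores are converted with Karlin–Altschul statistics,
`bits = (λS − ln K)/ln 2` and `E = m·n·2^(−bits)`. λ and K are fixed
constants in the scoring scheme: the published gapped values λ = 0.267,
K = 0.041 (BLOSUM62 11/1) and λ = 0.625, K = 0.41 (+2/−3, 5/2). For
non-default matrices `ungapped_lambda_k` solves the ungapped fixed point
Σ pᵢpⱼe^{λsᵢⱼ} = 1 (scipy brentq), and `calibrate_gumbel` offers an
empirical mode: optimal local scores of shuffled sequence pairs are fitted
to a Gumbel law by method of moments (λ = π/(σ√6), K from the location
parameter). Effective lengths carry no edge correction: the query length
times the total residue count of the other gene complement, mirroring a
database search. Exact E-value magnitudes are therefore not comparable to
any particular search engine's output; cutoff-based counts are.

## One-to-one matching

"Bidirectional best hit with each sequence used once" is implemented as a
global greedy matching: the union of hits from both directions (per
unordered pair, the direction with the smaller E-value) is sorted by
ascending E-value, ties broken by descending bit score then lexicographic
id pair, and accepted while both partners are unused. This makes runs fully
reproducible and honours the uniqueness constraint exactly; a strict
reciprocal-best-hit mode (`match_mode="mutual"`) is available for
sensitivity analysis. Tightening the E cutoff can only remove pairs
(the greedy decisions on the surviving prefix are unchanged), which the
tests assert.

Candidate pairs are validated by full-length Needleman–Wunsch alignment
with end gaps penalized. Identity and similarity are percentages of *all*
alignment columns including gap columns; a "similar" column is one whose
substitution-matrix entry is positive. This definition is recorded here
because the similarity score of a validated pair has no universal
convention; it is what the E-value/similarity band table (`bin_pairs`)
reports. Within-genome paralogs are never consulted during matching.

## Origin classification

Each unique (non-shared) CDS receives exactly one label by fixed-precedence
rules (split → duplication → lateral transfer → deletion → unclassified),
evaluated per gene so input order cannot matter:

- **split**: the gene and an adjacent same-strand CDS within `gap_max`
  (default 300 bp) hit the same partner CDS (relaxed cutoff, default 10⁻⁴)
  on subject segments overlapping by at most 20 % of the shorter span, with
  union coverage ≥ `cov_min` (default 0.6). The neighbour may be unique
  *or* already paired with that partner — after a frameshift, the
  one-to-one matcher typically pairs the intact gene with the longer
  fragment, leaving only the shorter fragment unique.
- **duplication**: an intra-genome paralog at the strict cutoff whose own
  ortholog exists (the gene is the extra copy).
- **lateral transfer**: no partner-genome hit at the relaxed cutoff and
  |z| ≥ `z_min` (default 2.5) for gene GC or GC3 against the genome-wide
  gene distribution. Gene-wise GC/GC3 z-scores were chosen over full
  codon-usage likelihoods: they are deterministic, desk-scale, and
  sufficient for composition shifts of the size simulated.
- **deletion**: no partner-genome hit, typical composition — interpreted as
  loss in the partner lineage, so the label is assigned to the lineage that
  retains the gene.

Split fragments shorter than roughly 20 residues can fall below the relaxed
E cutoff and are then misread as deletions; this is the classifier's main
failure mode and is visible in the per-class recall on simulations with
short genes.

## The simulator

`simulate_pair` evolves two lineages independently from a common ancestor
of `n_genes` protein-coding genes whose residues are drawn i.i.d. from the
Robinson–Robinson background. Substitutions follow a BLOSUM62-derived
exchange process: the number of events per site is Poisson(`subst_per_site`)
and each event draws the replacement from P(j|i) ∝ pⱼ·e^{λsᵢⱼ} (j ≠ i,
ungapped λ = 0.3176) — the conditional of the Karlin–Altschul target
frequencies. Each gene then experiences at most one structural event per
lineage (mutually exclusive draw), which keeps every truth label
unambiguous:

- *duplication*: a tandem copy with one extra round of substitution noise;
- *deletion*: the gene is removed from that lineage;
- *split*: a frameshift placed uniformly in the middle 60 % of the gene
  (so both fragments stay detectable) yields two adjacent CDS separated by
  the single inserted base;
- *lateral insertion*: a brand-new gene with no homolog anywhere, whose
  back-translation is GC-shifted (below).

Finally `n_inversions` non-overlapping gene blocks are reverse-complemented
in lineage B (order reversed, strands flipped). Genomes are assembled as
back-translated CDS separated by random spacers (mean `spacer_len`);
synonymous codons are chosen with a third-position GC weight `gc3`, the
genome-wide codon-bias dial that makes GC-based outlier detection
meaningful. Lateral genes instead use a maximum-entropy codon distribution
whose expected *overall* gene GC equals the host background plus
`hgt_gc_shift` (per-gene tilt solved by bisection), because the parameter
is defined as an offset on the gene's GC content, not on GC3 alone.

The truth map contains one pair per ancestral gene present in both
lineages; when a gene is split in exactly one lineage the intact copy is
paired with the longer fragment and the shorter fragment is the expected
unique CDS. A handful of slow-evolving tRNA-like nucleotide genes
(`n_rna`, default 4; 0.1× the protein rate) ride along to exercise the
RNA-level matching path; they undergo no structural events.

Defaults are chosen as realistic study conditions for a closely related
archaeal genome pair: 300 genes of 270 ± 100 amino acids, 0.2 substitutions
per site per lineage, per-gene event probabilities 0.05/0.05/0.02/0.05
(duplication/deletion/split/lateral), two inversions of 3–12 genes, 120 bp
spacers, +0.12 GC shift for lateral genes. With probabilities zero and no
divergence the two lineages have identical gene complements and proteins
(nucleotide sequences still differ in synonymous positions and spacers,
which are drawn per lineage).

What the simulator does *not* emulate: realistic phylogenetic codon models,
rate variation across genes and sites, RNA secondary-structure constraints,
pseudogenes, overlapping genes, mobile elements, and amelioration of
transferred genes. Passing the recovery tests therefore shows the pipeline
is correct under clean, single-event histories with compositionally crisp
transfers; on real genomes the origin fractions are method-sensitive and
should be read as approximate.

## Synteny

Synteny is derived from the computed ortholog map, not from raw nucleotide
anchoring: one dot per validated pair at the feature midpoints, colinear
when strands agree and antiparallel otherwise. `rotate_origin` rotates a
circular replicon so a chosen anchor CDS starts at coordinate 0 (features
that would span the new origin raise instead of wrapping — the comparisons
implemented here never need wrap handling). Unique-CDS hotspots are runs of
unique genes whose midpoints lie within `window_bp` (default 10 kb) of the
previous member, reported at `min_count` ≥ 5; the defaults are set so that
clustering on the scale seen in 1.6–1.75 Mb archaeal chromosomes is
detectable, and both are exposed as options.

## Problem sizes and determinism

Everything is deterministic given the configuration: a single seeded
generator drives the simulator, and search, matching and classification are
seed-free with fully specified tie-breaks (the test suite asserts
byte-identical artifacts across reruns). The bundled tests and the
acceptance script run the recovery studies at 300 genes with the default
gene-length distribution and 2–5 replicate seeds — sizes chosen to exercise
every event type with non-trivial counts while keeping the exact all-vs-all
search (~10⁵ alignments per pair) tractable on one core.

## Known limitations

- E-values use fixed λ/K; no composition-based statistics or length edge
  correction, so absolute significances differ from production search
  tools.
- The origin rules operationalize the four published event categories; the
  original tracing procedure is not public, so on real data the class
  fractions are checked for ordering, not exact values.
- Features spanning the circular origin are rejected rather than wrapped.
- Low-complexity masking is off by default; only a simple tandem-repeat
  shuffle calibration is provided rather than SEG-style masking.
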