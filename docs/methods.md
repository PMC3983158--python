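# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the famevo pipeline.

## Scope and design

The pipeline reproduces the classical gene-family survey workflow on
annotated genomes: similarity-based identification with conserved-motif
confirmation, structural statistics, distance-based phylogenetics with
bootstrap, duplicate calling and classification, counting-based Ka/Ks
with molecular-clock dating, and expression clustering. All stages are
deterministic given their seeds, and all stochastic validation runs on a
synthetic-genome generator with recorded ground truth.

## Identification

Proteome records are screened by exact Smith–Waterman local alignment
(BLOSUM62, affine gaps: open −11, extend −1; a gap of length k costs
open + (k−1)·extend) against one or more seed queries, computed by
Biopython's `PairwiseAligner`. A candidate passes at `min_score ≥ 100`.
This default was calibrated on the local-alignment score distribution of
simulated decoy proteins (uniform amino-acid composition, 300 residues)
against family queries: decoy scores cluster near 30–50 with a 99.9th
percentile below ~70, while true family members score several hundred,
so the threshold sits in a wide empty margin. It is a package default,
not a universal constant — real proteomes with compositional bias may
need recalibration.

Domain confirmation uses a consensus-scan surrogate for a profile-domain
test: a candidate is confirmed when at least `required = 2` of the four
catalytic motifs (`EMPVGYVQIP`, `TTEGCLVA`, `DAMGMNM`, `GTVGGGT`) occur
with at most one mismatch each. Requiring only a subset reflects the
observed biology of the family, where individual members have lost
single motifs while remaining functional homologs. Isoform deduplication
keeps the longest protein per locus (ties broken lexicographically by
mRNA id); naming ranks confirmed genes by natural chromosome order
(chr2 before chr10) then start position.

## Motif architecture and logos

Motif scanning is exhaustive Hamming-window matching; with motifs of
length 7–10 and at most one mismatch this is exact and fast, and the
downstream use is presence/absence only. Sequence-logo conservation per
alignment column is I = log₂20 + Σₐ pₐ log₂ pₐ bits (gaps excluded from
the proportions, no small-sample correction); all validation fixtures
have column depth ≥ 10, where the uncorrected estimator is adequate. An
all-gap column is an error rather than silently zero.

## Gene structure

Intron counts come directly from annotation exon chains (count = exons −
1), not from spliced re-alignment of CDS to genome — annotations are
inputs in every supported scenario and the result is identical. Exons
are stored in ascending coordinate order on both strands; biological
order is derived on demand.

## Phylogeny

- **Alignment.** Progressive alignment along a guide tree built by
  neighbor joining on k-mer distances (k = 3, d = 1 − shared distinct
  k-mers / smaller set size). Profiles are aligned by global affine-gap
  dynamic programming over expected column–column BLOSUM62 scores
  (column residue frequencies with gaps excluded); traceback prefers
  diagonal over up over left. With two sequences this reduces exactly to
  pairwise global alignment, and gap-stripping always recovers the
  inputs.
- **Distances.** Uncorrected p-distance with pairwise deletion: for each
  pair, only columns where both rows are ungapped count. No substitution
  model correction is applied to protein distances; model-corrected
  distances are out of scope.
- **NJ.** Saitou–Nei agglomeration on the Q criterion with deterministic
  smallest-(i,j) tie-breaks. Branch lengths use the standard limb-length
  formulas; negative estimates are clamped to zero with the deficit
  moved to the sibling edge so displayed lengths stay non-negative while
  path lengths are preserved where possible. On additive matrices the
  reconstruction is exact (topology and branch lengths), which the test
  suite verifies over 200 random trees of 5–12 leaves.
- **Bootstrap.** Columns are resampled with replacement; each replicate
  rebuilds distances and the NJ tree; support of an internal edge is the
  percentage of valid replicates whose tree contains the same leaf
  bipartition. A replicate in which some pair shares no ungapped columns
  is dropped and counted. Supports are reported unfiltered.
- **Rooting and groups.** The root is placed on the edge separating a
  monophyletic outgroup from the rest (error otherwise); group reports
  flag per-label monophyly and list maximal label-pure clades.

## Duplications

The calling rule is the published 80/80 convention read strictly:
coverage = aligned columns / length of the longer gene > 0.8 **and**
identity = matches / aligned columns > 0.8, evaluated on global
Needleman–Wunsch alignments of the CDS nucleotide sequences (match +2,
mismatch −3, gap open −5, extend −2, end gaps penalized). Nucleotide
global alignment makes "coverage of the longer gene" well defined. Each
qualifying unordered pair is one event; mutually similar multi-member
clusters are annotated with a connected-component id so per-pair counts
and cluster structure are both visible.

Tandem vs segmental is **this package's operationalization**, since the
distinction is conventionally stated but rarely parameterized: tandem
iff same chromosome, gap ≤ 50 kb, and ≤ 1 intervening annotated gene;
everything else segmental. Both parameters are exposed in configuration
and on the CLI.

## Ka/Ks and dating

The estimator is classical Nei–Gojobori counting:

- **Sites.** Each codon's 9 single-nucleotide neighbors contribute 1/3
  weight to synonymous (s) or nonsynonymous (n) sites; mutations to stop
  codons are excluded, so codons with stop neighbors contribute fewer
  than 3 sites. S and N are averaged over the two sequences.
- **Differences.** Per codon column, synonymous/nonsynonymous change
  counts are averaged over all minimal mutational pathways with equal
  weights; pathways traversing a stop are discarded, and a column whose
  every pathway hits a stop is excluded entirely and flagged.
- **Correction.** pS = Σsd/S and pN = Σnd/N are Jukes–Cantor corrected,
  d = −¾ ln(1 − 4p/3); p ≥ 3/4 is flagged saturated, and Ka/Ks is
  undefined (flagged) when Ks = 0.
- **Codon alignment.** Built by back-translating the global protein
  alignment onto the CDS; protein gap columns are removed and codon
  columns with ambiguity codes or stops are dropped with a count.
- **Interpretation.** Ka/Ks > 1 positive selection, = 1 (±10⁻⁶) neutral,
  < 1 purifying.
- **Dating.** T = Ks / (2λ), reported in Mya. The bundled clock table
  carries λ = 6.5×10⁻⁹ (Zea mays), 9.1×10⁻⁹ (Populus trichocarpa) and
  6.1×10⁻⁹ (Glycine max) synonymous substitutions per site per year;
  pairs from species without a table entry are left undated rather than
  dated with a borrowed rate.

The test suite checks the site and difference counts against exhaustive
genetic-code enumeration for all 61 sense codons and 500 random codon
pairs, and the whole estimator against Biopython's independent NG86
implementation on simulated pairs.

## Expression

Values are log₂(v + 1) transformed; gene–gene distance is 1 − Pearson
correlation (centered by default; the uncentered variant is available as
an option since legacy clustering tools default to it). Average-linkage
agglomeration uses deterministic smallest-index tie-breaks and matches a
brute-force oracle exactly on small instances. Duplicate-pair divergence
is the Pearson correlation of the two profiles with a divergence
threshold of 0.5 — an explicit operationalization of "strongly
divergent" expression chosen so that the flag is testable; it is
configurable.

## Synthetic genomes

The generator emulates the study conditions at desk scale. Defaults: 5
chromosomes of 1 Mb; a 6-member family descending from one 300-residue
ancestral protein carrying all four catalytic motifs at fixed scaffold
offsets; two planted duplicate pairs (one tandem, one segmental) at
ω = 0.2 with target Ks 0.2 and 0.3 — inside the 0.15–0.3 band typical of
recent plant paralogs; two singleton members at background divergence
Ks = 1.2 (background ω = 0.5) so that non-duplicate family pairs fall
safely below the 80% identity rule (~0.73 observed); 6 decoy genes of
uniform amino-acid composition, rejection-screened so no catalytic motif
matches even at one mismatch; 3 introns per gene (intron lengths 100–
1000 bp); tandem partners 2–20 kb apart with no intervening gene;
expression drawn from two mean profiles (linear 9→1 and its reverse)
with Gaussian noise σ = 0.5 truncated at zero.

Codon evolution is an accept/reject scheme indexed by ω: uniform
single-nucleotide proposals; synonymous proposals always accepted;
nonsynonymous proposals accepted with probability ω, except inside motif
codons where they are always rejected (strong purifying selection on
catalytic residues — this is also what keeps motif-based confirmation at
full recall); stop-creating proposals rejected. Evolution stops when the
accepted synonymous event count reaches target_Ks × S(ancestor), with S
the Nei–Gojobori synonymous site count — tying the simulator to the
estimator's definition of a site. Realized event counts are recorded as
ground truth; because sites can be hit repeatedly, the realized
event-based Ks is what the estimator should recover (median relative
error ~4% at 500 codons in the validation runs).

What the generator does **not** emulate: codon-usage bias, indels,
recombination, alternative splicing, transposon-rich intergenic space,
compositional heterogeneity between genes. Passing tests therefore
demonstrate the correctness of the algorithms under clean, known-truth
conditions, not robustness to every artifact of real genome annotation.

## Numerical and procedural choices

- Strict inequalities in the 80/80 rule (a pair at exactly 80% identity
  is not called).
- All tie-breaks (NJ Q-matrix, traceback, linkage) are deterministic and
  documented above; two runs with one configuration and seed produce
  byte-identical output bundles, which the test suite asserts by hashing.
- GFF3 coordinates are 1-based inclusive externally; all internal
  arithmetic is 0-based half-open, converted only at the I/O boundary.
- Validation problem sizes (200 trees for NJ recovery, 100 codon-pair
  replicates at 500 codons, 20 synthetic genomes for duplication
  calling, 1000 linkage instances, 100–1000 bootstrap replicates) were
  chosen to make the checked proportions statistically meaningful while
  keeping the whole validation suite fast enough to run on every change.

## Known limitations

- Identification operates on provided proteomes; six-frame genome
  translation search (finding unannotated members) is out of scope.
- Protein distances are uncorrected p-distances; for deep divergences a
  model-corrected distance would be preferable.
- The Nei–Gojobori variant here (proportions + Jukes–Cantor) is the
  classical default; maximum-likelihood codon models (GY94/YN00) will
  differ in the second decimal on real data and are out of scope.
- The tandem definition and the expression-divergence threshold are
  explicit package conventions; results on real data shift with these
  choices, which is why both are configurable and logged.
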