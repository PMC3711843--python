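# Methods

`markermine` models the marker-design workflow used for paleopolyploid crop
species such as *Brassica rapa*: transcriptome contigs assembled per line
are compared with a reference set of coding sequences (gene models) whose
paralog-family structure is known, single-nucleotide and microsatellite
polymorphisms are mined from the comparisons, and SNPs are filtered into
KASP-style assay targets that can be scored on a recombinant inbred line
(RIL) population. This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic data do and do
not emulate.

## Homolog grouping

Each contig is aligned to candidate gene models with a Smith–Waterman
local aligner (Biopython `PairwiseAligner`; match +2, mismatch −3, gap
open −7, gap extend −2) after an exact k-mer pre-screen (default k = 15,
≥ 2 shared seeds; both knobs are configurable down to near-exhaustive
search). A contig is homologous to a gene when some local alignment
reaches **≥ 80% identity over ≥ 100 aligned columns**; identity is
matches / aligned columns with gap columns included in the denominator and
N never counting as a match — a deliberately conservative definition,
since "percent identity" is otherwise ambiguous. Each contig is assigned
to its single best gene (highest identity, then longest alignment, then
lexicographically smallest gene id), which makes assignment a function of
the input set, independent of ordering. Whether the identity rule should
be applied per-hit or per-contig-coverage is underdetermined; per-hit is
implemented and reported as such.

## SNP calling and filtering

Variants are read off mismatching columns of the gene/contig alignment
(the whole-sequence-comparison route, not read mapping). A pair is only
compared when its alignment identity is **≥ 90%**; columns within 5 bp of
an alignment gap are never called, because indel-adjacent columns are
usually alignment artifacts. The comparison is asymmetric: read depth
applies to the contig line, the reference gene model is treated as fully
supported. Sites are retained at **depth ≥ 7 and quality ≥ 40**, both
boundaries inclusive. The alignment route has no native consensus
quality, so when no quality column is supplied a deterministic stand-in
`q = min(60, 10 + 5·depth)` is used and labelled *imputed* in all output;
with it, the depth criterion is the binding one.

## The three-criteria marker filter

A retained SNP becomes a marker candidate when a 101 bp window can be
excised with the variable base at position 51, and it is accepted when

1. **Flank conservation** — all 100 flank columns are strictly identical
   between the two lines: no substitution, no gap, no N. "Strict" is the
   testable reading of conserved flanks; a single flank edit can abolish
   primer binding.
2. **Junction freedom** — the reference-frame window occurs as one
   contiguous block on the gene's genomic (intron-bearing) copy. A window
   that instead maps as two pieces separated by intervening bases spans an
   exon–intron junction and is rejected; a window mapping neither way is
   rejected as having no genomic hit. A junction exactly at a window edge
   does not reject.
3. **Depth** — the depth/quality filter above at the SNP base.

All three booleans are evaluated for every candidate, so the accepted set
is identical under any criterion order; only the funnel's intermediate
counts (reported in the order flank → junction → depth) depend on it.

For genes with two or three paralogs, a segregating column is classified
before design: *allelic SNP* (exactly one paralog differs between lines,
all others line-invariant), *PSV* (paralog-specific variation: fixed
difference between paralogs, identical across lines) or *conflict* (two or
more paralogs segregate — unusable). An allelic SNP in a multi-copy gene
is accepted only when **every sibling paralog** is discriminated by at
least one PSV (or inter-paralog indel) within the 50 bp flanks, so that
locus-specific primers can anchor on the target copy. The flanks keep the
target paralog's own bases at PSV positions — they are the discriminators
— while residual variable positions get IUPAC degeneracy codes. Requiring
discrimination against *every* sibling (not just one) is this package's
reading of "locus-specific"; a strict both-flanks mode is available as a
flag. The exact rule for which residual variants receive degeneracy codes
is a labelled convention: any non-discriminating sibling-line variant
observed inside the window.

Accepted markers are emitted as `50 bp [ref/alt] 50 bp` bracket sequences
with per-base A/T/G/C depth at the tagged position. With a single total
depth track, the tagged (alternate) base carries the full depth and the
other three zero.

## SSR detection and comparison

Perfect microsatellites of unit length 1–6 are detected as maximal tandem
runs with class minima **10, 6, 5, 5, 5, 5** (mono- through
hexanucleotide). Runs are truncated to whole units; a run whose unit is a
power of a shorter unit is reported once at the shortest unit; motifs are
canonicalised to the lexicographically least rotation (not
reverse-complement-folded, since transcripts have a defined strand); runs
of N break repeats. Two qualifying SSRs separated by ≤ 100 bp are
additionally labelled one *complex* locus (the tool default for the
interruption distance). An SSR is polymorphic between lines only when the
motifs agree, the repeat counts differ, and the 50 bp flanks on *both*
sides are exactly identical; loci with shorter available flanks are
excluded and counted. Flank identity is evaluated on the contig frame,
anchored through the homolog assignment.

## Two-point linkage utilities

Genotypes are A/B/H/missing; only individuals homozygous at both markers
are informative. R̂ = recombinants/informative (capped at 0.5),
LOD = k·log₁₀(R̂/0.5) + (n−k)·log₁₀((1−R̂)/0.5) at k = round(R̂·n), and
linkage groups are connected components of the marker graph with edges at
LOD > 6.0. Segregation distortion is a 1-df chi-square against 1:1 with
default α = 0.01 and an optional Bonferroni correction; fewer than 20
informative calls flags the result low-power instead of failing. Map
distances use Kosambi, d = 25·ln((1+2r)/(1−2r)) cM.

**RIL correction.** The classical selfed-RIL limit is R = 2r/(1+2r). At
F7 the observed fraction is systematically below that limit (about 8%
relatively at small r), and inverting the F∞ formula leaves a bias of the
same size — enough to push recovery of r = 0.01 outside a 10% tolerance
once sampling discreteness is added. `estimate_rf` therefore inverts the
**exact finite-generation two-locus selfing recursion** (the 4×4
haplotype-pair Markov chain iterated from the F1, conditioned on
homozygosity at both loci) when the generation is known, via a cached
monotone interpolation grid; the F∞ closed form remains the fallback when
it is not. Within-group marker orders, when requested, come from greedy
nearest-neighbour seriation of two-point distances and are labelled
approximate — multipoint ordering is out of scope.

## The synthetic-data generator

The generator emulates the features the pipeline exercises: gene families
of one to three paralogs (~1% fixed inter-paralog divergence, with every
paralog pair guaranteed at least one discriminating PSV so reference
sequences are never identical), line alleles at ~0.5% allelic divergence,
SSR loci planted at reserved anchors with per-line repeat counts,
intron-bearing genomic copies, one partial contig per gene with per-base
depth (Poisson, mean 20, by default), and F7 RIL genotypes produced by
explicit meiosis simulation under a Haldane (no-interference) crossover
process with selfing after F1. Defaults: 600–1200 bp coding sequences,
0–2 introns of 80–250 bp, contig coverage 0.9. All randomness flows from
one integer seed; identical config + seed reproduces every output file
byte-for-byte.

Conventions that keep the planted truth exactly decidable:

* **Clean-flank mode** spaces planted SNPs ≥ 102 bp apart, keeps them
  ≥ 50 bp from coding ends, and never places them on PSV columns — so each
  marker criterion is independently decidable and a contig is always
  strictly closest to its own paralog. The mode refuses SNP rates above
  1/102 per base rather than silently violating spacing.
* **Junction well-definedness** — introns keep a 60 bp exon floor and
  never begin or end with the base that would extend the adjacent exon.
  Without this, an intron whose first base coincides with the next coding
  base makes the insertion point formally ambiguous and no exact oracle
  exists. Real internal exons are not a handful of bases, so nothing of
  biological interest is lost.
* **SSR anchors** are guarded so the detected repeat count equals the
  planted count exactly, and SSR host genes receive no SNPs, which keeps
  coordinate bookkeeping linear.

`compute_expected_markers` evaluates the full acceptance rule directly on
the planted records; the test suite additionally re-derives SNPs, PSVs,
junctions and contig placements from the raw sequences alone and checks
both routes agree exactly.

What the generator does **not** emulate: sequencing error, assembly
artifacts (chimeric or misassembled contigs), alignment-scale structural
variation between lines, UTR sequence, allelic depth imbalance, and
real linkage disequilibrium structure. Passing tests therefore show the
pipeline's logic is exact on its stated model, not that the thresholds are
optimal for any particular real data set.

## Problem sizes

The default verification study is 200 gene families (120 single-copy, 50
two-paralog, 30 three-paralog; 310 sequences, ~0.3 Mb of coding sequence)
with one derived line at full contig coverage — large enough that every
copy class, criterion and rejection path is exercised hundreds of times,
and small enough that the whole suite runs in well under a minute per
stage on one CPU. Linkage checks use 93–500 individuals and up to 2,000
loci; recombination-fraction recovery uses 100 replicate populations per
planted value.

## Read QC

Raw-read filtering mirrors the fastx-toolkit semantics: a read is removed
when *strictly more than* 30% of its bases (on the full, untrimmed
length) fall below Phred 20 — a read at exactly 30% is kept, following
the prose reading of the rule — and survivors then lose a fixed 31-base
low-quality tail. Reads not longer than the trim length are dropped and
counted separately, and a pairing pass drops reads whose mate failed.
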