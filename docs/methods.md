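# Methods

## Scope and model

This package analyses the transcripts made by plant RNA polymerase IV
(Pol IV) and RDR2 — the double-stranded precursors of 24-nt heterochromatic
siRNAs — from aligned sequencing reads. The experimental logic it encodes:
remove Dicer processing (`dcl2 dcl3 dcl4`) so precursors accumulate, then
attribute RNAs to Pol IV/RDR2 by their loss in `nrpd1` or `rdr2`. All
coordinates are 0-based half-open (BED convention); GFF3 input is shifted
on read. A read counts toward a region when it overlaps it by at least one
base, once per region; RPM uses the library's declared total mapped reads
so subsetted files stay interpretable.

## Differential locus calling

Windows (default 300 bp, non-overlapping; the final partial window is
kept) are tested by pooling replicate counts per genotype and forming the
2x2 table (window count, library-size remainder) x (control, mutant),
evaluated with a two-sided Fisher exact test. A window is significant when
the RPM fold change is >= 4, P < 0.01 and control expression >= 1 RPM;
significant windows merge at gap 0 into loci. Fold changes carry a
symmetric 0.5-RPM pseudocount on both sides, so an empty window has fold
exactly 1 and fold is always finite. Raw P-values are thresholded, not
FDR-adjusted — the selection rule is a plain P < 0.01 cut — though a
Benjamini-Hochberg option exists. The exact test is deterministic and
well calibrated at the low counts typical of siRNA windows; the suite
verifies it against an explicit hypergeometric summation to 1e-10 and
checks its error rate on a no-effect simulation.

Fisher on pooled counts ignores biological replicate dispersion, so its
P-values are anti-conservative relative to a dispersion-aware model
(e.g. a negative-binomial GLM); the calling rule compensates by requiring
a large fold change and minimum expression, and the empirical null check
(significant fraction <= 2 alpha at dispersion 0.1) bounds the practical
consequence at this design's depths.

## Transcript assembly

Reads of all control replicates inside the called precursor regions are
merged whenever the gap to the next read is <= 60 nt (a gap of exactly 60
joins). Each merged transcript is then flagged by four predicates —
length > 60 nt, combined expression > 1 RPM (summed reads over summed
library sizes, not the mean of per-library RPMs), fold >= 4 versus the
Pol IV mutant with the same pseudocount convention, and overlap with a
siRNA locus — and only transcripts passing all four are emitted by
default. The filters are a pure conjunction, so their order is
immaterial; assembly is order-independent in the read input. Transcripts
are strandless (precursors derive from both strands); the 5' end is
reported as the Watson-strand start.

## Metagene profiles

Profiles align regions at the start or end anchor (the end anchor is the
last covered base, `end - 1`) and average a per-base signal over regions
longer than 200 bp, out to 1 kb of flank. For minus-strand regions the
window is reflected so positive offsets always point into the body;
planted precursor loci are strandless and unaffected. A/T composition is
(#A + #T)/(#A + #T + #G + #C) per offset, with ambiguity codes excluded
from both numerator and denominator. Nucleosome occupancy is the fraction
of regions whose call set covers that genomic position, with no
smoothing. Positions whose window runs off a chromosome drop out of that
position's denominator rather than being padded.

## Spliced-read scan and intron filter

A read that fails contiguous exact mapping becomes a junction candidate
when its first and last 15 nt each match the genome perfectly on the same
strand of the same chromosome, in splice orientation with a positive gap,
and with an anchor-to-anchor genomic footprint of at most 1000 nt (the
footprint, not the gap, is bounded — the conservative reading). Reads with
several compatible anchor pairings are discarded as ambiguous rather than
risking spurious junctions; reads shorter than 30 nt are skipped and
counted. Candidates are then filtered on coverage: the mean depth of the
gap ("intron") must be at least five times below the mean of the two
adjacent flanks (flank width = gap length capped at 100 bp); a candidate
with zero flank coverage is removed because the drop cannot be
demonstrated.

## Strandedness and poly(A) dependence

At loci with stranded coverage above 1 RPM, the major/minor strand count
ratio classifies the locus: single-stranded iff >= 9:1, with a zero minor
strand treated as an infinite ratio (the limit of the rule). Pol IV/RDR2
products are double-stranded; Pol II products are single-stranded. The
poly(A) contrast computes the control/mutant fold separately in the
poly(A)+ and poly(A)- fractions per locus; precursor loci show the
depletion only in the poly(A)- fraction.

## CHH methylation and chromatin context

DMRs between two per-cytosine CHH tables use 100-bp windows with >= 4 WT
sites, WT weighted level >= 0.1, and a >= 50% drop of the weighted level
in the mutant; qualifying windows merge at gap 0. These thresholds are
package defaults (the source DMR sets in the motivating analyses came from
published methylome studies with their own parameters), and precomputed
DMR BEDs can be supplied instead. A siRNA locus is D2 if it overlaps
DRM2-dependent DMRs, C2 for CMT2; a locus overlapping both goes to the
class with the greater overlapped length, with an exact tie falling to
"other". Quartile tables rank loci descending (quartile 1 = highest) with
ties broken by genomic position for determinism; group sizes differ by at
most one. Relative siRNA abundance in a mutant is (mutant P4-locus reads /
mutant non-P4 reads) / (the same WT ratio): normalizing inside the library
against Pol IV-independent small RNAs cancels library size and
composition, so WT/WT is exactly 1 and a planted fourfold loss reads back
as 0.25. Histone-mark overlap tiles each mark's domains (and their
base-level intersection) into 500-bp windows, keeping final partial
windows, and reports the percentage of windows containing loci and of loci
carrying each mark.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every draw taken from one seeded generator (same config + seed gives
byte-identical outputs).

**Genome and annotation.** Two 500-kb chromosomes by default. The middle
third of each chromosome is designated pericentromeric and receives the
C2 loci; D2 loci, Pol II loci and intron-containing genes (2-3 exons of
150-400 bp, introns 80-300 bp) are packed into the arms with >= 300-bp
spacing. Background sequence is 64% A/T (typical for *A. thaliana*);
P4 locus bodies are rewritten at 50% GC with 50-nt flanks at 80% A/T.
Per-locus expression weights are lognormal (sigma 0.6) and shared across
assays.

**Libraries.** 19 libraries: sRNA-seq (WT, `nrpd1`; 3 replicates),
dsRNA-seq (`dcl234`, `dcl234 nrpd1`, `dcl234 rdr2`; 3 replicates), and
stranded poly(A)+ / poly(A)- (`dcl234`, `dcl234 nrpd1`). Counts per locus
and replicate are negative binomial (dispersion 0.1; Poisson available);
read positions are uniform within the locus. The Pol IV-dependent
component is 50% of library mass in the control genotypes, and mutants
retain 1/20 of it by default — near-complete loss, consistent with the
essentially abolished 24-nt siRNA class in `nrpd1` — while libraries are
resampled to a fixed sequencing depth, so the collapse of one component
inflates the others exactly as real library-size normalization does.
(This composition effect is why a generator that made precursors 90% of
the library would cap the observable RPM fold change below the 4x calling
rule regardless of the true depletion.) Precursor and siRNA reads come
from both strands; poly(A)+ reads come from the planted strand with
probability 0.95 at Pol II loci and at each P4 locus's residual Pol II
strand; Pol IV-independent small RNAs are drawn mostly from genes and
never from P4 loci. Genic poly(A)+ reads include 10% exon-exon spliced
reads, emitted as two 20-nt BED segments sharing a read id plus a sidecar
table of their unaligned sequences (no CIGAR needed), with the true
junction recorded per read id.

**Epigenome.** CHH methylation levels: 0.30 at P4 loci in WT, dropping to
0.02 at D2 loci in `drm1 drm2` and `nrpd1` and at C2 loci in `cmt2`;
background 0.02; binomial sampling at ~20x coverage over a thinned set of
genomic cytosines. Nucleosomes are 147-bp calls in a jittered genome-wide
array, with calls overlapping the 50-nt locus flanks removed and a
well-positioned call just inside each locus end. H3K9me2/H3K27me1 domains
tile ~95% of the pericentromere and form sparse correlated islands on the
arms, so C2 loci almost always carry both marks and D2 loci rarely do.

**What it does not model.** Sequencing errors, quality scores, adapters,
mapping ambiguity (reads arrive as alignments), copy-number structure,
transposon families, CG/CHG contexts, and locus-level correlation between
expression and methylation beyond the planted class structure. Passing
tests therefore demonstrate correctness of the computational method under
the planted statistical structure — not performance on real libraries,
where dispersion, mappability and composition effects are harsher.

## Problem sizes and defaults

Default scale (2 x 500 kb, 300 P4 loci, 50 Pol II loci, 100 genes, 2e5
reads per library) runs the full pipeline in seconds on one CPU and gives
a few hundred reads per locus and replicate — enough that the 4x/P<0.01
rule operates away from its detection floor, as in the motivating design.
The no-effect calibration uses 2000 windows at NB dispersion 0.1 with 3+3
replicates. The test suite's determinism check uses a miniature
configuration (2 x 60 kb) purely to keep byte-level comparison brisk.

## Known limitations

Fisher on pooled counts (no dispersion modelling) as discussed above; the
splice scan requires exact 15-mer anchors, so any sequencing error in an
anchor loses the read (the real analogue tolerated mismatches via BLAST);
locus boundaries are window-quantized, so called loci can exceed planted
extents by up to one window on each side; the D2/C2 tie rule and the
window grid make classification deterministic but grid-dependent at the
margins.
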