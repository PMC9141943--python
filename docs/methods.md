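# Methods

This note documents the models, parameters and design choices behind
`pulascreen`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data do and do not emulate.

## Coordinate conventions

All positions are 1-based with inclusive intervals, matching the
gene-centric convention used when quoting variant positions on a gene
("CDS position 156" is the 156th base of the coding sequence). BED files
are converted to/from 0-based half-open form only at the I/O boundary.
Indel alleles are VCF-style: left-aligned through repeat runs and anchored
on one reference base, so identical planted events unify across samples
under the merge key (pos, ref, alt).

## Locus model

A `Locus` is a single contiguous reference sequence with one CDS interval
and named features (signal peptide, cre site, promoter region). The motif
scanner expands IUPAC degeneracy codes per position and scans both strands;
because the catabolite-responsive-element (cre) operator is a
reverse-complement palindrome, a forward and a reverse hit on a
self-reverse-complement window are the same physical site and are reported
once (forward strand). The default mismatch allowance for the cre scan is
1: the known operator sequence TGTTATCGATAACA differs from the consensus
TGWAANCGNTNWCA at exactly one position (consensus position 4 expects A,
the site has T), so an exact scan would miss the canonical example.
Ambiguity codes are accepted in motifs only, never in subject sequences.

Amplicon arithmetic: for a forward primer whose 5′ end anneals `u` bp
upstream of the CDS start and a reverse primer whose 3′ end lies `d` bp
downstream of it, the product length is `u + d` (the start-site base is
counted once, in `d`). The simulator plants a real primer pair at u = 42,
d = 257 so the 299-bp product can be verified by substring search as well
as by the formula.

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
convenience: its defaults are the conditions every recovery property is
evaluated under.

* **Locus**: 1500 codons of CDS plus 171-bp flanks (4842 bp total), ATG
  start, TAA stop, no internal in-frame stop. Codons 52, 69 and 75 are
  fixed to TAC so that single C→A substitutions at CDS positions 156, 207
  and 225 create premature stops — the N-terminal stop-gain positions the
  screen is most interested in. A cre palindrome sits in the upstream
  flank; the amplicon primer pair is planted at its stated offsets when the
  locus is large enough (CDS ≥ 87 codons, flanks ≥ 76 bp).
* **Genotype archetypes** (presets): intact; 2-nt deletion at CDS 156–157
  (signal-peptide frameshift); stop-gains at CDS 156/207/225; a ~1-kb
  transposase insertion after CDS position 100; an 800-bp deletion from CDS
  position 101. The exact placement of the frameshift and large deletion
  within the N-terminal region is this package's choice — the source
  strains' coordinates are not published — and the positions are stated in
  the truth records.
* **Reads**: single-end, length 150, uniform start and strand, substitution
  errors at 0.001/base (uniform among the three alternatives), constant
  quality. Per-haplotype read counts are Poisson with mean
  `depth × proportion × L / read_length`. No indel errors, quality ramps,
  PCR duplicates, GC bias or non-target (host/other-taxa) reads are
  simulated; consequently passing tests demonstrate the screen's logic and
  thresholds, not robustness to those real-data artifacts. Because read
  starts are uniform, coverage ramps down within one read length of the
  locus ends; flanks are sized so the CDS sits outside the ramp, and the
  coverage gate is defined on the CDS only.
* **Transposase set**: each family is a random consensus (shipped as its
  first copy) plus copies substituted at 2%/base from that consensus, so
  member-to-consensus identity ≈ 98% (comfortably above the 95% clustering
  threshold) while inter-family identity is far below it. Truth records
  the family of every copy.
* **Determinism**: every sample owns one integer seed; identical specs give
  byte-identical FASTQ and truth JSON.

Truth classification mirrors the screen's definition: a sample is
disrupted iff some disruptive planted edit (frameshift indel, stop-gain,
element insertion, or deletion/insertion ≥ 50 bp) has expected allele
frequency ≥ 0.7.

## Read alignment

The screen maps against one gene, so a general-purpose mapper is replaced
by a single-target seed-and-extend aligner: exact 15-mer seeds locate
candidate diagonals (reverse-strand queries are reverse-complemented);
each seeded diagonal band, padded by `band_width` = 32 bp, is resolved by
an exact affine-gap Smith–Waterman kernel (numba) on that reference
window. Scores: +2 match, −3 mismatch, gap of length L costs −5 − 2L.
Alignment is local: read ends outside the best local alignment become soft
clips, which is precisely the junction evidence the SV stage needs. If
neither strand seeds at all and the reference is small (≤ 20 kb), a
full-matrix alignment is attempted before declaring the read unmapped
(score < 40). Ties break to the lowest reference start, then the forward
strand. Indels are left-aligned through repeats after traceback; the band
width bounds the largest indel alignable within one read (larger events
surface as soft clips instead, by design). Within its window the kernel is
exact, and equivalence with an independently written brute-force
Smith–Waterman is asserted over randomized instances in the test suite.

Soft clips shorter than 10 bp are not used as breakpoint evidence: at
error rate 1e-3 the score-optimal alignment occasionally clips a noisy
read end, and the 10-bp floor suppresses those.

## Small-variant calling

Calling is pooled-continuous — each sample is a population, not a diploid —
so the caller is a pure frequency thresholder: emit any allele with site
depth ≥ 10, alternate reads ≥ 2 and alternate fraction ≥ 0.01, with
AF = alt/depth. No genotype likelihoods are computed; every downstream
decision uses only the allele frequencies and the printed thresholds.
Cohort reporting applies the prevalence filter (AF ≥ 0.05 in ≥ 3 samples);
retained records keep all per-sample evidence, including sub-threshold
observations. Deleted positions count toward site depth (a read spanning a
deletion is informative there); soft-clipped bases count nowhere.

Impact classes: MODIFIER outside the CDS; HIGH for frameshift indels,
stop gain, start loss, stop loss, and any indel straddling a CDS boundary;
MODERATE for amino-acid changes and in-frame indels; LOW for synonymous
changes. In-frame indels are MODERATE by definition even if the junction
happens to spell a stop codon — the class is decided by the length
arithmetic, as is conventional for effect annotators. The test oracle
classifies SNVs independently by applying the allele to the sequence,
translating both coding sequences and comparing the proteins.

The high-frequency threshold is applied inclusively (AF ≥ 0.7). The
source material states the rule both as "> 0.7" and as "a minimum
frequency of 0.7"; the methods-style phrasing (≥) is taken as defining.

**Coverage gate.** A sample is screened only when 100% of CDS positions
have depth ≥ 10 ("full-length" coverage). The fraction is configurable
(`coverage_gate_fraction`) for ragged real data. Note the corollary: a
sample whose dominant haplotype carries a large deletion inside the CDS
has zero interior coverage and is reported `insufficient_coverage`, not
disrupted — the gate is defined on the reference gene, and a desk review
of the depth track is the intended follow-up for such samples.

**Classification scope.** Per-sample disruption calls are made from the
sample's own calls (annotated, frequency-thresholded), while the ≥ 3-sample
prevalence filter governs the cohort variant report. Tying classification
to the cohort filter would make a sample's status depend on which other
samples happen to be in the run — e.g. a clear dominant stop-gain seen in
one sample only would be "filtered away" — so the two concerns are kept
separate.

## Structural variants and transposase evidence

Soft-clip positions (clips ≥ 10 bp) are clustered within a 5-bp window per
side; a cluster needs ≥ 10 clipped reads. A right-clip and a left-clip
cluster at the same junction form an insertion; a right/left pair whose
clipped tails re-map across a gap (> 5 bp) forms a deletion spanning the
gap; unpaired clusters are reported `unresolved` (inversions, duplications
and translocations are never typed). SV frequency is
clipped / (clipped + cleanly spanning) at the junction, averaged over both
breakpoints for deletions and over the two clip sides for insertions. A
"cleanly spanning" read must align ≥ 10 bases on each side of the
junction: micro-homology between an inserted element and the reference
lets junction reads align a base or two past the true breakpoint, and
without the margin such reads would be double-counted as reference
support (halving the frequency of a homozygous insertion).

The transposase database is built by greedy incremental clustering at 95%
identity, longest sequence first, ties by identifier — deterministic.
Identity is matching columns / alignment columns of a semi-global
alignment of the shorter sequence onto the longer (edlib). Clipped tails
(≥ 20 bp, so a tail can reach the aligner's reporting score) plus reads
the locus could not place are aligned against the representatives with the
same aligner and scoring as the main mapping; a read counts for its
best-scoring representative at score ≥ 40. The per-sample evidence flag
requires strictly more than 20 matching reads (21 fires, 20 does not), and
the count is the sample total across elements, with per-element counts
reported for inspection. Transposase evidence only ever annotates an
independently supported, frequency-qualified insertion call; read counts
alone never disrupt a sample.

## Cohort summaries

Disrupted / covered fractions are displayed as whole percents with
half-away-from-zero rounding (62/270 → 23%, 12/102 → 12%). Note that
19/55 = 34.5% rounds to 35% under this rule although it has been printed
elsewhere as 34%; the package keeps one documented rounding rule rather
than matching both. Samples failing the coverage gate are excluded from
the denominator. A sample with several causes counts once in the
disrupted numerator (union counting); per-cause counts are reported
alongside. Stratification is a generic group-by over a sample→label map,
with unlabeled samples pooled under `unknown`.

## Proteome ratios

Quantities are used exactly as shipped in the fixture table (iBAQ values
printed at two significant digits); "not detected" (ND) is a distinct
state, never imputed, and any ratio with an ND or zero input is ND.
Display rounding is one decimal for log2 ratios and nearest-ten for
"N-fold" phrases ≥ 50. Recomputing the fixture's two contrast columns
from its quantity columns reproduces the printed ratios within 0.1 —
the slack expected from 2-significant-digit inputs against ratios
computed from unrounded values — except for two cells (K1MET7's
glycogen/glucose ratio and A0A7V8KTK5's strain ratio) that are internally
inconsistent with the printed quantities themselves; the tests exclude
exactly those two and assert the headline values (6.5, 4.6, −7.9,
~90-fold, > 200-fold) exactly at printed precision. The "fraction of
total detected proteins" row requires whole-proteome totals that are not
part of the table and is therefore exposed as a function taking the
totals as input rather than recomputed from the fixture.

## Problem sizes and numerical choices

Simulation-based tests run at the defaults above (4842-bp locus, depth 50
for the 12-sample end-to-end cohort, depth 200 for allele-frequency
recovery) or on a compact 300-codon locus for the breakpoint-recovery and
mixture-boundary sweeps, with 3–10 seeds per sweep — sizes chosen so each
property is exercised at meaningful coverage while the whole suite stays
desk-scale. Allele-frequency recovery at depth 200 is a ~2σ bound per
variant (binomial sampling of read origins), so that check uses
high-frequency mixtures (0.8–0.9) where the bound holds with margin.
All randomness flows from explicit integer seeds; reruns are
byte-identical, including the JSON run manifest (no timestamps).

## Known limitations

* Single locus, single-end reads, no mapping-quality model; reads from
  paralogous genes elsewhere in a real metagenome would need a
  pre-filtering step this package does not provide.
* SV typing is limited to insertion/deletion; breakpoints are reported to
  cluster-window (±5 bp) precision and inserted sequence is not assembled.
* The coverage gate's interaction with homozygous large deletions (above)
  means cohort-level deletion prevalence is conservative.
* The caller has no strand-bias or base-quality filters; at the default
  error rate and depths these are unnecessary, but noisy real data would
  need them.
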