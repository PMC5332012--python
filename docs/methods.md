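# Methods

## Screen model

A pooled insertional-mutagenesis screen is modelled as a set of mutants,
each tagged by one (occasionally two) piggyBac gene-trap integrations and a
random 25-bp barcode per transposon end. Barcode read counts are a noisy
proxy for cell abundance; comparing drug-exposed to vehicle (DMSO) exposed
replicate cultures of the same pool identifies mutants whose disrupted gene
changes drug sensitivity. The analysis has four stages — barcode counting,
barcode→site linking, per-barcode differential abundance, and gene-level
aggregation — plus a simulator that generates all inputs with truth.

## Barcode counting and grouping

Extraction matches a fixed vector flank at the start of each read by
Hamming distance over a fixed window (no indel alignment; default budget 2
mismatches) and takes the following 25-mer. Reads that are too short, fail
the flank, or contain an N inside the barcode window are discarded and
tallied; N-containing barcodes are dropped rather than wild-carded so that
error clouds are not artificially bridged.

Sequencing and PCR errors scatter a true barcode into a cloud of
near-identical variants, so raw barcodes are clustered by single linkage
under Levenshtein distance with default threshold `max_edit = 2`.
Levenshtein (not Hamming) is used because indels are a common error mode on
the semiconductor sequencing platforms these screens use. Clustering runs
over the pooled barcode universe across all samples, so grouping is
identical everywhere; the canonical barcode is the most abundant member
(ties broken lexicographically) and per-sample counts are summed over
members, conserving reads exactly. Candidate pairs are found with a
pigeonhole substring index (each of `max_edit+1` pieces of a barcode looked
up over a ±`max_edit` position window, which can never miss a true pair)
and verified with bounded edit-distance alignment; below ~300 distinct
barcodes plain all-pairs comparison is cheaper and used instead.
Correctness, not speed, is the contract: tests compare the clustering
against an independent all-pairs dynamic-programming oracle.

## Site linking

Inverse-PCR read pairs carry the barcode amplicon on one mate and the
transposon–genome junction on the other. The junction read must open with
the transposon terminal sequence (configurable mismatch budget, default 1)
and retain ≥ 20 genomic bases after trimming; the barcode is recovered from
the mate with the extraction logic above.

The built-in mapper is an exact-seed (k = 16) plus ungapped-extension
aligner: a junction maps iff it has a unique best placement with ≥ 95%
identity over ≥ 20 compared bases, on either strand. No gapped or spliced
alignment is attempted — junction reads are short genomic flanks.
Pre-computed SAM alignments can be imported instead; leading query clips
are arithmetically restored so the site position still refers to the first
junction base (verified against a brute-force scan, including hard-clipped
records). Records with mapping quality 0 are treated as multi-mapping.

Coordinates are 1-based; a site's position is the first genomic base
flanking the transposon end, which for minus-strand junctions is the
rightmost base of the aligned window. Reads-per-million uses the total
mapped reads of the site's (library, transposon-end) mapping run as the
denominator, since filtering was defined per mapping run. Sites with
rpm < 10 (strictly) are discarded; surviving sites from the same library on
the same chromosome and strand and the same transposon end within 5 bp
(inclusive) are merged transitively. The merged site takes the position of
its most-supported member (ties: smallest position) and the summed read
count — chosen for determinism and read conservation, and making the
operation idempotent. Restricting the merge to same strand/end (the rule
itself only says "same library") avoids collapsing the two ends of one
transposon into a single record.

Barcode→site links require ≥ 2 supporting read pairs; a barcode still
linked to more than one merged site is flagged ambiguous (multi-copy
integrations or plasmid-pool barcode collisions) and excluded from gene
tallies by default, but kept in all tables. Gene annotation assigns every
gene whose body span (min start to max end of its GTF records) overlaps the
site position, strand-agnostically; gene-trap orientation is recorded but
not used as a filter, since the mapping data being emulated is not
orientation-filtered.

## Differential abundance

Counts are modelled negative binomial with common dispersion φ
(Var = μ + φμ²).

**Normalization.** Trimmed mean of M-values against a reference sample (the
one whose counts/library-size upper quartile is closest to the mean upper
quartile): M and A values on barcodes nonzero in both samples, double
trimming (30% of M, 5% of A from each end, rank-based), inverse asymptotic
variance weights, factors rescaled to geometric mean 1. This matches an
external reference implementation of TMM to 1e-6 on a frozen fixture. Note
that TMM is only approximately invariant to scaling one column by a
constant (~0.3% CPM shift on a 500×4 fixture, identical in the reference
implementation), because the precision weights mix obs- and ref-terms.

**Dispersion.** Quantile-adjusted conditional maximum likelihood: counts
are mapped to the geometric-mean library size via a quantile-to-quantile
NB transform (averaging normal and gamma tail approximations), then the
conditional log-likelihood given each barcode's per-group total,
l(φ) = Σ[Σᵢ lnΓ(yᵢ+1/φ) + lnΓ(n/φ) − lnΓ(z+n/φ) − n lnΓ(1/φ)],
is maximized by golden-section search on φ ∈ [1e-6, 10]; adjustment and
maximization alternate twice from φ₀ = 0.01. With no replicated condition
the configured default φ = 0.1 is returned with a warning.

**Exact test.** Conditional on t = sumA + sumB (group sums of
library-size-equalized counts, rounded), the sum of a group's counts is
treated as NB with size parameter proportional to its replicate number.
The P-value sums the probabilities of every split (a, t−a) whose null
probability is ≤ that of the observed split, normalized by the total —
two-sided by minimal likelihood, chosen over tail doubling because it
agrees exactly with enumeration and with the convention of the standard
package for this test. t = 0 returns P = 1 so the BH vector stays
well-defined; at φ = 0 the test collapses to the exact binomial test.

**Fold changes** are log2 ratios of prior-augmented mean CPMs (prior count
0.125, scaled by relative library size), finite even at zero counts.
Benjamini–Hochberg adjustment runs over tested barcodes only; barcodes with
zero counts everywhere are excluded from testing and from the BH
denominator. Replicates are compared within a screen/library; cross-library
evidence is combined at the gene level.

## Gene aggregation

Differential results join to links on the canonical barcode (orphans —
counts without mapping — are reported separately). Per gene and direction,
insertions passing |log2FC| ≥ 1 and P < 0.05 (defaults; both exposed) are
counted; genes with ≥ 2 such insertions are ranked by count, then Fisher's
combined P (−2 Σ ln Pᵢ against χ² with 2k d.f.) over the significant
members. Combining only significant members mirrors "multiple depleted
insertions" as the unit of evidence; a flag combines all same-direction
members instead. Insertions from different libraries count as independent
evidence. The cutoff defaults are working choices, not reproductions of any
particular published threshold.

## Simulator

The generator emulates the experiment's structure: random genome (TTAA at
natural ~1/256 bp density, every gene span guaranteed ≥ 1), non-overlapping
gene bodies, libraries of default 10 pools × 10,000 mutants, integrations
uniform over TTAA sites with ~5% two-copy mutants (matching the observed
~2× excess of integrations over pooled colonies), barcodes drawn with
replacement from a finite pool (default 10⁶; the plasmid pool's real
complexity was lower than its nominal 2×10⁶ transformants, producing
collisions) or, with `barcode_pool_size: null`, guaranteed-unique barcodes
for truth-identity tests. Selection is deterministic exponential growth
cells·2^(g·f) with multiplicative lognormal noise (σ = 0.1) — enough to
create NB-like overdispersion after read sampling without a branching
process. Default generations g = 8 over the screening window (a free
parameter; the true effective doubling count is not known), and the drug
dose calibration "kills 50% of wild-type cells" fixes the neutral drug
fitness at 1 − 1/g. Reads are multinomial in cell abundance with optional
gamma PCR jackpotting, constant quality, and per-base substitution errors
(default 1%); no homopolymer/flowgram error model, no restriction-fragment
length modelling, no instrument demultiplexing.

Three generator choices exist purely to keep truth comparisons exact at
desk scale: selected integration sites keep ≥ 6 bp spacing per
chromosome/strand so the 5-bp site merge never conflates two distinct
mutants (on a real-genome-sized target the collision probability is
negligible, but a 10⁵–10⁶ bp toy genome would inflate it); sites stay at
least one junction-read length from contig edges so every junction window
lies fully on the contig; and read names embed truth ids for traceability
(parsers never rely on them).

What passing simulated tests does **not** show about real data: real
flanks/primers differ per assay and must be configured; Ion Torrent
homopolymer errors are harsher than the uniform substitution model; real
screens have batch structure, uneven pool sizes and orientation-dependent
gene-trap efficacy, none of which the generator produces.

## Problem sizes and numerical choices

Validation experiments run at reduced scale chosen to keep the whole suite
in minutes on one CPU while preserving the regime of interest: null
type-I at 1,000 barcodes × 20 seeds; the spike-in analogue at the full
10,000-mutant, 1:10,000 mixing ratio of the original experiment (200
spike cells vs 2×10⁶ library cells, 10⁶ reads/sample, 20 seeds);
end-to-end truth recovery at 500 mutants on a 2×150 kb genome; grouping
and filter/merge oracles at 500/1,000 random instances. Ties in the exact
test's probability comparison use a 1e-12 relative tolerance; dispersion
search terminates at interval width 1e-8; TMM factors below 2^±1e-6 snap
to 1. Degenerate inputs: empty FASTQ warns and returns empty counts;
all-zero samples and unknown sample names are hard errors; zero-total
barcodes get P = 1.

## Known limitations

Single common dispersion (no tagwise/trended estimation, no GLM framework
or batch covariates); no demultiplexing or quality-aware clustering; the
built-in aligner is ungapped and intended for clean junction flanks, with
bwa-class aligners supported through SAM import; ambiguous multi-site
barcodes are excluded from gene evidence rather than fractionally
assigned.
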