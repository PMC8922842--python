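# Methods

This note documents the models, estimators, defaults and numerical
choices behind `metadiv`, and what the synthetic fixtures do and do not
establish about real data.

## Model and assumptions

Each reference contig represents a *population*: a cloud of co-existing
strains sharing roughly ≥ 95% nucleotide identity, collapsed to one
representative by upstream de-replication. Reads from a sample that
align to the representative are treated as draws from that population's
allele pool; the organisms are assumed haploid, and each sample is
assumed to be a single community (pooling communities would create
hybrid allele pools and bias the population-genetic statistics).
Alignment is taken as given — the pipeline filters and interprets
alignments, it never maps reads.

## Pre-processing

- **Identity filter** (default 0.95, inclusive): identity is
  1 − NM/(M+I+D). The aligned span counts matches, mismatches,
  insertions and deletions; soft clips are excluded. This is the
  standard alignment-level identity; it is stated explicitly because
  several near-equivalent definitions circulate.
- **Length filter** (default 30 bp) applies to the *aligned* query
  length (soft clips excluded): a read "mapping" at some identity only
  makes sense over its aligned portion.
- Secondary and supplementary alignments are dropped before filtering
  so no template contributes depth twice.
- **Detection presets**: viral and fragmented-bacterial contigs are
  detected at ≥ 5 kbp covered (genomes > 5 kbp) or ≥ 70% breadth
  (shorter); complete bacterial genomes at ≥ 20% breadth. All
  thresholds are user-overridable; there is deliberately no silent
  default preset because the rules differ materially.
- **Truncated mean abundance**: the per-position depth distribution
  (zeros included) is truncated at its 10th/90th percentiles (linear
  interpolation, inclusive bounds) and the mean of the retained
  positions is the raw abundance. If truncation would discard every
  position the untruncated mean is used and a warning recorded.

## Macrodiversity

Normalization multiplies each sample's column by
max(library size)/library size, preserving within-sample ratios
exactly; the user chooses reads or base pairs as the unit (base pairs
recommended when read lengths differ across platforms).

Richness, Shannon's H (natural log), Simpson (1 − Σp²), inverse
Simpson and Pielou's J (H/ln richness, undefined at richness 1) are
computed on relative abundances. Chao1, ACE and Fisher's α are defined
for counts, so they receive normalized abundances rounded to the
nearest integer (floor 1 for detected populations) — an explicit
stand-in for the common practice of feeding count-based estimators
scaled coverages; treat those three columns as heuristics. Chao1 is the
classical S + F1²/(2F2) with the F2 = 0 correction S + F1(F1−1)/2;
Fisher's α solves S = α·ln(1 + N/α) by bisection to 1e−9 relative
tolerance; ACE comes from scikit-bio.

β-diversity: Jaccard on presence/absence, Bray–Curtis on normalized
abundances, and Euclidean distance of CLR-transformed compositions. For
the CLR, zeros receive a pseudocount of 1e−6 × the smallest nonzero
abundance in the matrix; on strictly positive compositions the CLR
distance is invariant to per-sample rescaling (tested). A sample with
no detections yields set-convention distances and a warning.

## Codon-usage bias

Per gene, each amino acid's synonymous codons get fractions summing
to 1 (61 sense codons, translation table 11; stop codons and
start-codon recoding ignored; codons with ambiguous bases skipped and
tallied). The genome average is the per-dimension mean over genes that
observe the amino acid. A gene's distance to the average is Euclidean
over the dimensions of its own observed amino acids only — absent amino
acids are excluded rather than zero-filled, so short genes are not
penalized for composition instead of bias (a configurable deviation
risk against tools that zero-fill). Outliers exceed the one-sided Tukey
fence Q3 + 1.5·IQR of the genome's distances; genomes with < 4 genes
yield no calls. Genes come from a supplied GFF3/FFN or an external
prodigal call in metagenome mode.

## Variant calling

Genome/sample pairs enter the variant arm at ≥ 70% breadth and ≥ 10×
truncated mean depth. The pileup is computed internally from the
filtered alignments, counting only bases with quality ≥ 20 at M/=/X
positions; this per-base quality filter stands in for an external
caller's variant-quality filter, and a VCF import path
(`vcf_candidate_positions`) can restrict candidate sites to an external
callset when exact reproduction of another caller's site list is
needed.

Global SNPs: pooled counts across eligible samples; consensus = pooled
majority (ties broken A<C<G<T, deterministic); alternate alleles need
pooled frequency ≥ 1% *and* ≥ 4 pooled reads, both inclusive (the
support rule is interpreted as pooled reads, not per-sample). Local
SNPs restrict global positions to samples with ≥ 1 quality-passing
non-consensus base. Genic SNPs get strand-aware codon index/position,
and a warning fires when 1st+2nd-position SNPs outnumber 3rd-position
ones (synonymous third positions should dominate; an excess suggests
frame problems). The pooled consensus replaces the reference base at
every SNP position before any codon logic; re-calling on the updated
reference is a fixed point (tested).

**Linkage.** Reads spanning a SNP-bearing codon with M/=/X at all three
bases, quality ≥ 20, and no indel inside the codon contribute a codon
string. For each pair of alternate alleles at distinct positions in the
codon, the 2×2 table (both/only1/only2/neither) feeds a two-sided
Fisher exact test and φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)). p < 0.05
with φ > 0 is linked, with φ < 0 independent, anything else (including
zero-margin tables, φ = 0, and p exactly at α) ambiguous; ambiguous is
treated as independent downstream. A p-value exactly equal to α can
land on either side of the threshold in floating point (e.g. the table
(2,2,0,12) has p = 1/20), so equality is detected with a 1e−9 relative
guard and classified not-significant. No multiple-testing correction is
applied by default (matching common practice for per-codon screens);
`benjamini_hochberg` adjusts the reported p-values for users who want
FDR control across tests.

**Downsampling** to 10× (default) without replacement: whole codon
strings at genic SNP loci — linkage survives by construction — and
single bases (multivariate hypergeometric) at intergenic loci or when
no spanning read passes. RNG substreams are keyed on
(seed, crc32(genome), position), so draws are independent of iteration
order and fully reproducible from the pipeline seed.

## Population-genetic statistics

All statistics run on the downsampled counts, for global and local
scopes side by side. With N = SNP positions in a gene/genome (scope
set), n = those covered in the sample, and |G| the gene/genome length,
the *effective length* is |G| − (N − n).

- θ = N/(|G| − (N − n)), implemented exactly as this closed form (no
  harmonic-number correction).
- π sums, over covered SNP sites, the unbiased mismatch probability of
  two reads drawn without replacement, (c² − Σx²)/(c(c−1)) — equal to
  the ordered-pair sum Σ_{B₁≠B₂}(x_{B₁}/c)(x_{B₂}/(c−1)) — divided by
  the effective length. Sites with coverage 1 are skipped with a
  warning. (The published form of this estimator prints the first
  site's coverage in both denominators; the per-site reading is the
  only one consistent with the summation index and is used here.)
- F_ST = 1 − ((π_x + π_y)/2)/π_xy with the *total* genome length as the
  common denominator for all three terms, because effective lengths are
  not comparable between samples with different SNP coverage. π_xy
  crosses one read from each sample at sites covered in *both* samples
  (the intersection; a union convention would mix within- and
  between-sample information at half-covered sites). π_xy = 0 leaves
  F_ST undefined (reported missing). Sampling noise at finite coverage
  makes F_ST slightly negative for identical samples; no clamping is
  applied.
- pN/pS: expected counts tally the 9 single-nucleotide mutants of every
  consensus codon with equal weight (mutants creating or destroying
  stops count as non-synonymous); observed counts take each distinct
  variant codon once, where transitively linked alt alleles merge into
  one joint variant codon and unlinked/ambiguous ones stay separate
  single substitutions. Classification is by actual translation
  (table 11) — no amino acid is special-cased, since synonymous
  double-substitution codon pairs exist for leucine, serine and
  arginine. S_obs = 0 with N_obs > 0 is reported as a
  positive-selection candidate with an undefined ratio rather than a
  pseudocounted number. Variant codons are counted unweighted by read
  support; a support-weighted variant would require joint read counts
  for merged variants and is not implemented.
- Tajima's D uses the 1989 constants with S = the gene's SNP-position
  count and n = the ceiling of the gene's mean read depth as the number
  of sequences (undefined below n = 4 or S = 1). The per-site π is
  rescaled by the effective gene length before entering the numerator —
  per-site π and raw S are dimensionally incommensurable otherwise;
  this rescaling is this implementation's documented interpretation.
- `sample_average_pi` implements the subsample-averaged π used in
  virome survey comparisons: mean over r repetitions of the mean π of k
  populations drawn without replacement, seeded.

## Synthetic communities

`metadiv.simulate` generates i.i.d.-base genomes at a target GC,
plants frame-clean ORFs (ATG + non-stop codons + TAA, alternating
strands), and emits per-sample reads at true coordinates as
coordinate-sorted SAM with correct CIGAR/NM/MD and constant base
qualities. Read counts are chosen so the interior (plateau) depth
equals the target; the one-read-length coverage ramp at genome edges is
removed by the 10/90 truncation, so truncated mean abundance matches
the planted depth. SNPs are planted per molecule: independent sites by
Bernoulli draws at the target frequency (optionally per-sample
frequencies, including 0 and 1 for fixed between-sample differences),
linkage groups by one draw per molecule applied to all members
(expected class: linked), exclusive groups by a categorical draw
assigning at most one member (expected class: independent). Sequencing
errors default to 0 and, when enabled, avoid a ±2 bp window around
planted SNPs unless "dirty" mode is set, so truth tables stay exact.

What the fixtures do **not** emulate: mapping artifacts and reference
bias, platform error profiles (homopolymers, quality decay), uneven
coverage from GC or origin-of-replication effects, strain mixtures with
genome-scale linkage, and inter-population read misrecruitment. Tests
passing on these fixtures certify the pipeline's arithmetic and
decision rules, not robustness to those real-data pathologies.

## Problem sizes and calibration checks

The shipped checks use desk-scale sizes chosen to make sampling noise
negligible relative to the tolerances: heterozygosity recovery uses 50
sites per genome at 100× over 20 seeds (aggregate π error ~1–2% before
and ~4–6% after 10× downsampling); F_ST endpoints use 25 sites at 100×
in two samples; linkage fixtures use a planted Asp (GAT) codon pair at
30% co-segregating frequency and a mutually exclusive pair at 35% each
(the exclusive frequencies keep the reference allele safely the
consensus — near 50% a sampling fluctuation can flip the pooled
consensus, after which the complement allele is genuinely positively
linked with the partner alt); Tajima's D neutrality uses 200 genes with
12 segregating sites whose allele counts follow the 1/k neutral
spectrum at n = 20, for which E[π_total] = S/a₁ exactly, so the mean D
is near 0 by construction.

## Known limitations

- Chao1/ACE/Fisher on rounded coverages are heuristics, not estimators
  with their sampling theory intact.
- The per-base quality filter is not identical to an external caller's
  variant-quality (QUAL) filter; imported VCF sites close most of the
  gap but genotype-likelihood-based filtering is out of scope.
- Linkage is assessed within codons only; genome-scale haplotypes and
  linkage disequilibrium are out of scope by design.
- No confidence intervals on π/θ/F_ST; no codon substitution models
  behind pN/pS; no recombination-aware statistics.
- The pipeline is serial; `--threads` is accepted for interface
  stability but currently ignored.
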