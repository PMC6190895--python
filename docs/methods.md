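# Methods

## Problem setting

A trio design detects de novo mutations — variants carried by an offspring
but by neither parent — directly from whole-genome sequencing of
parent–offspring trios. In genome-edited livestock the question is twofold:
does the edited lineage show an elevated de novo rate, and do any de novo
(or parent-shared) variants fall at plausible Cas9 off-target sites? The
package answers both with a deterministic filter cascade, a coverage-aware
rate estimator, and a PAM-aware off-target search with a distance-null
test, all exercised end to end on synthetic cohorts with known ground
truth.

## Filter cascade

A candidate must pass, in order:

1. **Caller intersection.** Keys `(chrom, pos, ref, alt)` present in both
   callers' normalized callsets; per-sample evidence is taken from the
   primary caller. Indels are left-aligned and parsimony-trimmed against
   the reference before any comparison, so two spellings of one event
   share a key; only indels with a 2–100 bp allele-length difference are
   admitted at read time.
2. **Cohort uniqueness.** The alternate allele is carried (het or hom-alt)
   by the focal offspring and by no other cohort member, parents included.
3. **Known-database subtraction.** Set difference on keys against a
   population variant database.
4. **Depth / allelic balance.** Both parents ≥ `min_parent_depth` (12) and
   offspring depth ≥ 1/10 of the summed parental depth. The fraction is
   compared in exact rational arithmetic (`10·d_off ≥ d_sire + d_dam`), so
   boundary depths are decided by the inequality itself, not by floating
   point: the stated conditions are removal conditions, hence equality
   passes (a parent at exactly 12×, or an offspring at exactly one tenth,
   survives).
5. **Genotype-likelihood pattern.** Normalized phred-scaled likelihood
   triples ordered (AA, AB, BB): offspring (>20, 0, >0), each parent
   (0, >20, >20) — the only assignment consistent with a heterozygous de
   novo call against homozygous-reference parents. Non-normalized triples
   (minimum ≠ 0) exclude the variant with a warning.
6. **Soft clipping.** The offspring carries the putative de novo allele,
   so its mean per-read soft-clipped fraction is tested; > 0.10 removes,
   exactly 0.10 passes. The fraction travels as a custom VCF FORMAT field
   `SCF` (quantized to 4 decimals so text round trips are exact); a
   missing value passes with a warning.
7. **Context review.** Automated proxies for manual inspection: another
   candidate within 10 bp, a homopolymer run ≥ 10 bp at or flanking the
   site, or an N base within 10 bp. Flagging is non-destructive by default
   (a strict mode removes flagged records), because visual review is a
   judgement call, not an algorithm; both the pre-review count and the
   flag count appear in the trace.

The surviving count *entering* review is exported as μ̂α for rate
estimation: back-calculation against the published per-animal rates shows
the rate numerator is the post-soft-clip count, not the post-manual-review
count. Missing role calls are excluded at the first stage that inspects
the missing field, and the exclusion is counted there, keeping traces
interpretable. Because stages 2–6 are per-variant predicates, the final
set is invariant to stage order (a property the tests assert by permuting
stages); only the trace differs.

## Mutation rate

μ̂g = μ̂α / (2R) per base pair per generation. R is the effective genome:
the count of autosomal windows (default 10 kb) whose mean coverage lies in
[13, 130], both ends inclusive, times the window size — so R is an exact
integer multiple of the window size. The 13×/130× bounds are absolute
depths, not multiples of the sample mean. Sex chromosomes are excluded by
default (flag-controlled). Rates are reported at full precision and, for
display, in 10⁻⁸ units rounded half-up to two decimals.

## Substitution spectrum

Single-base substitutions map onto nine strand-folded classes
(T>G, T>C, T>A, G>T, G>A, C>T, A>T, A>G, A>C). Of the three ordered types
without a listed label, C>A folds to its reverse complement G>T; the
complementary pair C>G/G>C has no listed representative and folds to a
configurable target (default G>A, the listed class sharing the G
reference). The fold table affects spectrum labels only — never filtering
or rates. A `full12` scheme returns raw ordered types.

`compare_spectra` is a paired two-sided t-test across per-class proportion
pairs. A caveat the implementation makes explicit: complete proportion
vectors are compositional (each sums to 1), so the mean paired difference
over *all* classes is identically zero and the full-vector statistic is
essentially degenerate (statistic ≈ 0, p ≈ 1 regardless of input). Passing
a `classes` subset — e.g. the predominant transitions — yields a
non-degenerate, conservative comparison; proportions are still computed
over the full profile.

## Off-target search and distance null

A site is any 20-nt window, on either strand, whose 3′-adjacent triplet
matches the IUPAC PAM pattern (NGG by default; NRG for the relaxed preset)
and whose Hamming distance to the protospacer is within a total budget
(default 5) and a seed budget (default 1) over the PAM-proximal seed
(default 12 bp, the common convention; the source protocol names no
length). N bases never match, including at PAM positions. The scan is a
vectorized shifted-array comparison; tests hold it equal to an independent
naive per-window oracle on randomized genomes and assert strand symmetry
and budget nesting. Two-predictor consensus is emulated by intersecting
two parameterizations of this engine on `(chrom, start, strand, guide)`;
externally produced BED site lists are also accepted.

For the null test, each query position gets its least distance to any site
(0 inside the half-open protospacer interval; otherwise distance to the
nearest base; positions are 0-based at this interface, variant positions
convert as pos−1). Null positions are drawn with replacement (default
n = 100,000) from a pool — by default the cohort's called-SNV positions,
with a uniform-positions alternative since the protocol is ambiguous on
this point. Observed and null distances are compared with a two-sample
two-sided KS test (asymptotic p), and a pointwise 95 % band around the
null empirical CDF is built by bootstrap percentiles on a fixed quantile
grid (an analytic band was not chosen because the bootstrap needs no
distributional assumption about heavily tied distances).

## Kinship QC

Pairwise kinship uses the within-pair robust (KING-robust family)
estimator φ̂ = (N_het,het − 2·N_opp-hom) / (N_het,i + N_het,j), which needs
no allele-frequency estimates, is invariant to allele-label flips, and
gives ≈ 0.5 for duplicates, 0.25 for parent–offspring, 0.125 for
half-sibs, 0 for unrelated pairs. A trio passes when both parent–offspring
coefficients fall in the first-degree window [0.177, 0.354] (powers-of-two
inference bins); an elevated sire–dam coefficient warns rather than fails
by default, since related matings occur in edited herds and are not a
pedigree error.

## Synthetic cohort generator

The generator emulates the statistical structure the cascade assumes, not
reads: no FASTQ/BAM, no linkage disequilibrium, no recombination maps, no
sequencing-error spectra. What passing tests show is therefore that the
*logic* of every stage is correct under the stated evidence model — not
that the thresholds are optimal for any particular sequencer or aligner.

Defaults mirror the study design the pipeline targets: an 11-animal cohort
forming five trios (two sires; one dam mated twice giving twin offspring),
mean depth 36.8× with gamma-Poisson overdispersion (dispersion 0.1),
20 de novo SNVs plus 3 de novo indels per offspring (the same order as
real per-genome candidate counts), population SNP rate 10⁻³/bp with
allele frequencies uniform on [0.05, 0.95] and Hardy–Weinberg founders,
database inclusion 0.9, caller discordance 0.05, and a desk-scale genome
(two 200-kb autosomes plus a 100-kb X) so everything regenerates in
seconds. Guides are random 20-mers planted with one exact on-target match
and configurable mismatched copies (total/seed counts per site, random
strand).

Evidence synthesis: per sample and site, depth is Gamma–Poisson; alt reads
are binomial given the genotype (error 10⁻³); the PL triple is the
phred-scaled binomial likelihood vector renormalized to minimum 0; the
recorded genotype is required to equal the PL argmin (draws are rejected
otherwise). True de novo sites are additionally redrawn until they pass
every cascade criterion — the generator defines detectable events, so
zero-artifact recall is 1.0 by construction and any miss is a pipeline
bug, not sampling noise. Artifact variants are built like de novo events
and then perturbed to violate exactly one criterion each (orthogonal
design): a parent at depth 7–11 (PL pattern still passing), an offspring
below the 1/10 depth fraction (PL still het-consistent), a parent PL of
(0, <20, ·) with genotype still AA, offspring SCF in 0.12–0.30, key
injection into the database, or a second cohort carrier. Artifact counts
per class are Poisson with mean `rate × true_denovo_count`. Caller B drops
each variant with the discordance probability and gains an equal expected
number of private calls. One generator seeded by `rng_seed` drives
everything in a documented draw order (genome, guides, population SNPs,
de novo, artifacts, discordance, coverage), so identical configs produce
byte-identical output files.

Coverage windows tile each chromosome (partial final window dropped);
window means are gamma-distributed around the configured depth, and a
configurable fraction is forced outside [13, 130] to exercise the
effective-genome filter; the ground truth records the realized in-bounds
count.

## Numerical conventions and degenerate inputs

- Variant positions are 1-based (VCF); intervals 0-based half-open (BED);
  conversion confined to readers/writers and the distance interface.
- Depth-fraction comparisons are exact rational; no floating-point
  boundary artifacts.
- Multiallelic rows split into biallelic records on read; the PL triple of
  a split record is the diploid subset for that (ref, alt) pair, and a
  sample carrying a third allele is `missing` in that record's frame.
- Empty callsets produce an all-zero trace; an empty spectrum has
  undefined (None) proportions; R = 0 makes the rate undefined (error);
  identical samples give KS statistic 0, p 1; zero shared genotyped sites
  give a NaN kinship entry with a warning.
- Acceptance-style checks run at desk scale by design: two-trio cohorts on
  a 100-kb autosome for cascade replicates, 30–50-kb genomes for oracle
  comparisons, 10,000 sites for kinship — sizes at which exact brute-force
  oracles are feasible and the whole suite stays fast.

## Known limitations

- Soft-clip fractions must arrive in the VCF (`SCF`); computing them from
  alignments is out of scope, as is any re-calling or recalibration.
- The off-target model is Hamming-only: no DNA/RNA bulges, no activity
  scores.
- The full-vector spectrum comparison is compositionally degenerate (see
  above); use a class subset for a meaningful test.
- The kinship estimator is a documented choice of the robust
  heterozygote-concordance family; sources that merely cite "kinship
  validation" may have used a different estimator with different windows.
- Sex chromosomes are treated as diploid by the generator and excluded
  from R by default; no X-specific kinship or rate handling.
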