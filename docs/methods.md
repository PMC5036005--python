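# Methods

This note documents the models implemented in `apobecsig`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 1-based inclusive, following MAF/SEG
conventions; 0-based half-open sources must be converted at the boundary.
Mutation tables default to TCGA MAF column names
(`Tumor_Sample_Barcode`, `Chromosome`, `Start_Position`, `Reference_Allele`,
`Tumor_Seq_Allele2`, `t_ref_count`, `t_alt_count`) and accept a user dialect
map. Multi-allelic VCF records are split into bi-allelic sites on read,
because pairwise r² is defined for bi-allelic SNPs; unphased genotypes are
rejected outright rather than approximated, since every linkage statistic
here assumes phase. Readers validate on entry (allele alphabet, coordinate
sanity, segment non-overlap, purity in (0, 1], coverage = Σ base counts), so
downstream modules never re-parse or re-check files.

## Trinucleotide spectra and motif weighting

Substitutions are reported pyrimidine-centric: a purine-reference mutation is
reverse-complemented so the mutated base is always C or T, giving 96 channels
labelled `5'[ref>alt]3'`. Reference motif frequencies are computed in two
modes:

- `collapsed` (default): every length-3 window is counted under its
  pyrimidine-centric key (32 motifs). Because each genomic locus contributes
  the same key from both strands, this equals the double-strand count divided
  by its doubled denominator; it is the mode that matches strand-collapsed
  mutation channels.
- `literal`: the supplied strand verbatim (64 motifs), with denominator
  length − 2 — the textbook single-strand definition.

Weighted frequencies divide each channel count by its motif frequency and
renormalize: `w_c = (n_c / f_c) / Σ_k (n_k / f_k)`. A nonzero count at a
zero-frequency motif is impossible by construction and raises.

Signature categories are single-channel rules: **APOBEC** = C→T at TCW
(5′ T, 3′ A/T), **smoking** = C→A at any motif, **ageing** = C→T at CG.
Because TCW excludes a 3′ G, the categories are mutually exclusive. An
`extended_apobec` flag adds C→G at TCW — the fuller TCW accounting that
includes the transversion arm of the signature; the default (transition-only)
set is what the group comparisons use. Per-patient proportions are computed
per timing class with the category count over the cell total, and any
patient-timing cell with fewer than four mutations is excluded ("fewer than
four" excludes ≤ 3; a cell of exactly 4 is retained).

## Clonality timing

Multiplicity (tumour copies bearing a mutation) inverts the expected-VAF
relation:

    m̂ = v · (ρ·CN + 2(1 − ρ)) / ρ,   adjusted AF = m̂ / CN

with ρ the tumour purity and CN the local total copy number. The two printed
anchors (VAF 0.50 ↔ 1 of 2 copies; VAF 0.667 ↔ 2 of 3 copies at ρ = 1) fix
this form.

Uncertainty: each bootstrap replicate redraws the alternate read count at
**half** the observed coverage — Binomial(⌈cov/2⌉, alt/cov) — and maps the
replicate VAF through the multiplicity formula; the 95% CI is the percentile
interval over 10,000 replicates. Resampling at half coverage intentionally
widens the intervals (the CI behaves like a full-coverage interval inflated
by ~√2), which makes the timing calls conservative; empirical coverage at
nominal 95% is therefore above nominal, which the acceptance suite checks
(≥ 93% bound). Percentile rather than BCa intervals: the procedure is plain
read resampling, and percentiles are its simplest faithful summary. Odd
coverages round the half up. Per-mutation RNG substreams are derived from
(global seed, sample, chrom, pos) via CRC-32, so calls are independent of
input order.

Classification on the copy scale:

- `early_clonal` — lower CI bound > 1 copy. With integer multiplicities,
  "significantly above one copy" implies at least two, i.e. the mutation
  predates the amplification in gained regions and predates a copy-neutral
  duplication in diploid regions. The alternative reading of the
  amplified-region rule — requiring the lower CI bound to reach 2.0 — was
  rejected because under half-coverage resampling at WES depths a true
  2-of-3-copies mutation (the printed CN=3/AF=0.667 example) essentially
  never attains it: at depth 120 and purity 1 the lower bound concentrates
  near 1.6, and the rule would label the canonical early mutation late.
- `subclonal` — upper CI bound < 1 copy.
- `late_clonal` — everything else with CN ≥ 2. This is also the tie-break
  for intervals lying entirely above 1 copy without qualifying as early
  (clonal, but not demonstrably pre-amplification).
- `unevaluable` — CN < 2 (no published rule covers deleted regions; an
  opt-in flag applies the CI-versus-1-copy rules there), or missing counts,
  segment, or purity, each with an explicit reason.

## Germline genotyping

**A3B.** A sample is called `null` when any copy-number segment overlapping
the A3B interval has segment mean ≤ −1.5 (the published array criterion) and,
if normalized exon depths are supplied, the mean depth over exons inside the
interval divided by the mean over flanking exons is ≤ 0.2; `intact` requires
segment mean ≥ −0.25 with a depth ratio ≥ 0.75; anything between is
`indeterminate` with a reason. The depth-ratio thresholds operationalize what
was originally a manual inspection step and are deliberately configurable;
the default interval anchors at the published probe start positions on
chromosome 22.

**A3H.** Diploid genotypes are called per site from base counts: homozygous
when the major allele holds ≥ 0.9 of reads, heterozygous when the minor
allele holds ≥ 0.25, uncallable otherwise or below 8× coverage / Q20. The
(site, haplotype, allele) table mapping genotype patterns to haplotypes I–VII
is packaged **data**, not code: the shipped default is a synthetic tagging-SNP
encoding of the published protein dichotomies (Gly105 vs Arg105; the Asn15
deletion in III/IV/VI) in which every haplotype is distinguishable, and it
should be overridden where real panel definitions exist. Phase between sites
is not inferred: when several haplotype pairs are compatible with the
unphased genotypes (e.g. III+V vs II+IV under the default table), the
lexicographically smallest pair is reported with an ambiguity flag and the
full compatible set is exposed. Carrier status ("A3H-I carrier" = ≥ 1 Gly105
copy) is a pure function of the codon-105 genotype and is callable even when
the full pair is not.

At the default thresholds, a heterozygous site at depth 30 becomes
uncallable when the binomial 50/50 allele split drifts to ≤ 7 reads for one
allele (~0.5% per site, dominated by allele sampling rather than sequencing
error); with about one heterozygous defining site per diplotype this puts
expected pair recovery near 99.5%, which is what the ≥ 99% acceptance bound
allows for.

## Linkage disequilibrium and population frequencies

r² = D²/(p_A(1−p_A)·p_B(1−p_B)) with D = p_AB − p_A·p_B, computed over phased
haplotypes only. Monomorphic sites yield not-a-value (exported as the string
`NA`, never 0, to avoid fabricating "no linkage"); a minor-allele-frequency
floor (default 0.01 in the CLI) flags near-monomorphic SNPs instead of
silently dropping them. Matrix order follows input SNP order, matching a
locus heatmap layout.

Population allele frequencies are alt-haplotype counts over 2 × samples per
population; the pooled value is the haplotype-count-weighted mean. The
cross-population Spearman correlation uses mid-ranks for ties, the exact
permutation distribution for n ≤ 9 and the large-sample t approximation
otherwise; constant vectors return NaN with a logged reason.

## Amplicon hypermutation counting

Amplicons are globally aligned (Needleman–Wunsch, affine gaps: match +1,
mismatch −1, gap open −4, extend −1 per additional base, end gaps penalized,
deterministic first-optimal traceback) — appropriate because the inputs are
full-length, near-identical Sanger-scale sequences, so no read mapper is
needed. Every mismatch column is tallied by substitution type; columns within
±1 of a gap (configurable, 0 disables) and columns containing ambiguity
codes (degenerate primers can introduce R/Y/...) are excluded as alignment or
chemistry artifacts. Rates are per kilobase of aligned (non-gap,
non-excluded) reference bases. The context spectrum keys mutated cytosines of
the chosen type by their 5′ base (TC/CC/GC/AC; `NC` when the 5′ base is
unknown at a sequence start), so its counts always sum to the type count. In
`cDNA` mode the alignment and reference are reverse-complemented before
counting, so genomic-strand G→A hypermutation is reported as C→T with its
context on the reported strand — exactly equivalent to an as-given run on
reverse-complemented input.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
every planted quantity recoverable:

- **Processes.** APOBEC mutations occur only at TCW-context cytosines
  (pyrimidine strand) as C→T (70%) or C→G (30%); smoking as C→A at any
  cytosine; ageing as C→T at CG; "other" uniformly over positions and
  alternate bases. Default mixture: 0.3/0.3/0.2/0.2 in every timing class.
  The uniform background necessarily leaks ~1% of apparent APOBEC-category
  mass (random hits on TCW C→T/G channels), which recovery tests must budget
  for.
- **Clonal architecture.** 30% early-clonal (multiplicity 2, cancer-cell
  fraction 1), 40% late-clonal (multiplicity 1, CCF 1), 30% subclonal
  (multiplicity 1, CCF ~ Uniform(0.1, 0.5) — kept clearly below the clonal
  boundary so classification-recovery tests are sharp).
- **Reads.** Expected VAF = m·f·ρ / (CN·ρ + 2(1−ρ)); alt reads ~
  Binomial(depth, VAF) at constant depth (default 100×; the acceptance
  cohort uses 120×). Purity ~ Uniform(0.6, 1). The genome is one chromosome,
  70% diploid and 30% at CN 3.
- **Carriers.** A configurable fraction (default 0.5) of patients are A3H-I
  carriers; a planted effect adds a boost to their early-clonal APOBEC weight
  with the other processes scaled down proportionally. Carrier patients
  receive planted diplotypes containing haplotype I and per-site base-call
  summaries at depth 30 with 0.5% error.
- **Panels.** LD blocks draw a latent allele Z ~ Bernoulli(p) per haplotype;
  each SNP copies Z with probability 1 − e and redraws otherwise, with
  e = 1 − r²^{1/4} so every within-block pair has the target r² in
  expectation; blocks are independent. A packaged synthetic global survey
  (17 populations) encodes the reported inverse geography of the A3B deletion
  and A3H-I — near-universal A3B with rare A3H-I in African populations,
  frequent deletion with ~65% A3H-I in Southeast Asia — as two unlinked
  markers; the per-population numbers are invented within those reported
  ranges, not transcribed frequencies.
- **Amplicons.** C→T deamination planted per 5′-dinucleotide context on the
  given strand; truth counts equal planted events exactly.

Not emulated: realistic error profiles (quality-dependent, strand-biased),
indels, kataegis clustering, subclonal population structure (discrete CCF
clusters), inter-chromosome variation, and germline variation beyond the
phased panels. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated model, not robustness to artifacts real
tumour data contain.

Determinism: one RNG stream per operation, seeded from its config; identical
config and seed give byte-identical outputs. Derived sub-seeds stay below
2³¹.

## Statistics

Group comparisons use Welch's two-tailed unequal-variance t-test
(Welch–Satterthwaite degrees of freedom) on per-patient proportions, with
group means and standard errors reported; groups need ≥ 2 values. Two
zero-variance identical groups return t = 0, P = 1 explicitly rather than
0/0. Enrichment tests use Fisher's exact test (two-sided, sum of
hypergeometric probabilities ≤ the observed table's); the odds ratio applies
a 0.5 continuity correction, flagged, when any cell is zero. Both are checked
in the test suite against independent brute-force oracles (exact rational
enumeration for Fisher; a three-state dynamic program for alignment scores;
direct 2×2 haplotype-table arithmetic for r²).

## Problem sizes

The shipped test suite and acceptance script size their simulations as
follows: mixture recovery on 5 replicate 2-patient × 500-mutation cohorts
per weight; LD recovery at 5,000 haplotypes; diplotype recovery over 1,000
(script) or 3,000 (suite) samples at depth 30 and 1% error; bootstrap
coverage over 2,000 replicates at depth 100 with 10,000-replicate CIs;
timing recovery on a ~2,000-mutation cohort at depth 120; the planted
carrier effect at 60 + 60 patients with 10,000-replicate CIs; and type-I
calibration over 200 null runs of 30 patients with 400-replicate CIs (the
reduced bootstrap depth there only widens CIs slightly and does not affect
test calibration).

## Known limitations

- The haplotype table is a synthetic stand-in; results at haplotype-pair
  resolution (beyond carrier status) depend on its allele encoding.
- Unphased genotype patterns cannot always identify the haplotype pair
  (an information limit, flagged per sample, not an implementation one).
- Timing assumes one clonal population plus independent subclonal mutations;
  no subclonal deconvolution or allele-specific copy number is attempted.
- The amplicon counter assumes near-full-length, high-identity sequences;
  heavily rearranged reads would need a local aligner.
- Welch comparisons treat per-patient proportions as approximately normal;
  with very few mutations per cell the test is conservative.
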