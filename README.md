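# apobecsig

Tools for linking **APOBEC3 germline genotypes** to **somatic mutation
signatures** and their **clonal timing** in tumour cohorts.

APOBEC3 cytidine deaminases leave a recognizable scar in cancer genomes:
C→T transitions and C→G transversions concentrated at TCA/TCT ("TCW")
trinucleotides. Two common germline variants shape which family member can be
responsible in a given patient: a ~29.5-kbp deletion that removes the entire
*APOBEC3B* coding sequence ("A3B-null" when homozygous), and *APOBEC3H*
haplotype I, whose Gly105 (versus Arg105 in the stable haplotypes) lowers
protein expression but increases nuclear access. Testing whether A3H-I
carriers accumulate more early-clonal APOBEC-signature mutations requires a
chain of analyses — germline calling, 96-channel spectrum construction,
purity/copy-number-adjusted mutation timing, and group statistics — that this
package implements as a tested pipeline, together with a synthetic-cohort
generator so that every stage can be validated against a known ground truth
without controlled-access patient data.

## What it computes

- **A3B deletion zygosity** from copy-number segments (segment mean ≤ −1.5
  over the A3B interval) with an optional exon-coverage confirmation, and
  **A3H diplotypes** (haplotypes I–VII, carrier status = ≥1 Gly105 copy) from
  per-site base-call summaries.
- **96-channel trinucleotide spectra**, pyrimidine-collapsed, with
  motif-abundance weighting: each channel count is divided by the frequency of
  its trinucleotide in the reference (windows / (length − 2)) and
  renormalized. Signature categories: APOBEC (C→T in TCW; optionally + C→G),
  smoking (C→A anywhere), ageing (C→T at CG).
- **Clonality timing**: the multiplicity of a mutation with variant allele
  fraction *v* in a tumour of purity ρ and local total copy number *CN* is

  *m̂ = v · (ρ·CN + 2(1 − ρ)) / ρ*,

  so VAF 0.50 ↔ 1 of 2 copies and VAF 0.667 ↔ 2 of 3 copies at ρ = 1. A
  95% CI comes from resampling reads at **half** the observed coverage
  (10,000 bootstrap replicates); mutations are `early_clonal` (lower CI > 1
  copy), `late_clonal` (CI consistent with 1 copy) or `subclonal` (upper
  CI < 1 copy).
- **Linkage disequilibrium** r² = D²/(p_A(1−p_A)p_B(1−p_B)) between SNPs from
  phased haplotype panels, and per-population allele frequencies with their
  cross-population Spearman correlation.
- **Amplicon hypermutation counting**: global affine-gap alignment of Sanger-
  scale amplicons to a reference, substitutions per kilobase, and 5′-
  dinucleotide context spectra (TC/CC/GC/AC), with a cDNA strand mode that
  reports genomic-strand G→A events as C→T.
- **Synthetic cohorts** with recoverable truth: mixed mutational processes
  with clonal architecture and binomial read counts, SEG/purity files, phased
  panels with block LD, site-call summaries, and deaminated amplicons.

## Worked example

Simulate a 40-patient cohort in which A3H-I carriers get a +0.15 early-clonal
APOBEC mixture boost, then run the full analysis:

```python
from apobecsig import pipeline, timing
from apobecsig import simulate as sim

cohort = sim.CohortConfig(n_patients=40, mean_mutations=100,
                          reference_length=40_000,
                          carrier_early_apobec_boost=0.15, rng_seed=7)
result, bundle = pipeline.run_simulated_study(
    cohort, pipeline.RunConfig(rng_seed=7))
row = result.comparison("early_clonal", "APOBEC")
print("timing classes:", result.timing_counts)
print(f"early-clonal APOBEC: carrier {row['mean_carrier']:.3f} "
      f"vs non-carrier {row['mean_noncarrier']:.3f}  "
      f"(Welch t={row['t']:.2f}, P={row['p']:.2e})")
print(f"adjusted multiplicity at VAF 0.667, CN 3, purity 1: "
      f"{timing.adjusted_multiplicity(0.667, purity=1.0, total_cn=3):.3f}")
```

prints

```
timing classes: {'early_clonal': 1268, 'late_clonal': 1618, 'subclonal': 1158, 'unevaluable': 0}
early-clonal APOBEC: carrier 0.340 vs non-carrier 0.209  (Welch t=5.52, P=2.94e-06)
adjusted multiplicity at VAF 0.667, CN 3, purity 1: 2.001
```

The timing split recovers the generator's 0.3/0.4/0.3 architecture, the
planted carrier effect is detected by Welch's two-tailed t-test on per-patient
early-clonal APOBEC proportions, and the multiplicity formula reproduces the
2-of-3-copies worked example.

The same stages are available from a shell via the `apobecsig` CLI
(`simulate`, `genotype-a3b`, `genotype-a3h`, `spectrum`, `timing`, `ld`,
`hypermut`, `compare`, `run-all`); every output TSV carries `#` header lines
recording the package version, seed and thresholds.

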