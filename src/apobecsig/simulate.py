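"""Synthetic cohorts with recoverable ground truth.

Every analysis stage in the package can be exercised against data whose true
generating parameters are known: per-patient mutation catalogs drawn from mixed
mutational processes (APOBEC, smoking, ageing, uniform-other) with a clonal
architecture and binomial read counts; SEG/purity tables; phased SNP panels
with block LD structure; per-site base-call summaries at haplotype-defining
positions; and deaminated amplicon sequences.

Read-count model
----------------
A mutation with multiplicity ``m`` (copies carrying it), cancer-cell fraction
``f``, in a segment of total copy number ``CN`` of a tumour of purity ``rho``
has expected allele fraction::

    AF = m * f * rho / (CN * rho + 2 * (1 - rho))

and its alternate read count is Binomial(depth, AF). This is exactly the
algebra the timing module inverts, so classifier-recovery tests are sharp.

All operations are deterministic given their seed; there is no hidden global
RNG state.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import (BASES, CopySegment, HaplotypePanel, MutationRecord, SampleMeta,
                 SiteCallSummary)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PROCESSES = ("APOBEC", "smoking", "ageing", "other")
TIMING_CLASSES = ("early_clonal", "late_clonal", "subclonal")

#: Default per-timing-class signature mixture (weights sum to 1 per class).
DEFAULT_SIGNATURE_WEIGHTS: dict[str, dict[str, float]] = {
    cls: {"APOBEC": 0.3, "smoking": 0.3, "ageing": 0.2, "other": 0.2}
    for cls in TIMING_CLASSES
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expected_allele_fraction(multiplicity: float, ccf: float, purity: float,
                             total_cn: int) -> float:
    """Closed-form expected VAF under the purity/copy-number model."""
    return multiplicity * ccf * purity / (total_cn * purity + 2.0 * (1.0 - purity))


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

def simulate_reference(length: int, gc_fraction: float = 0.45,
                       rng_seed: int = 0) -> str:
    """An i.i.d. random sequence over A/C/G/T with the requested GC content."""
    if length < 3:
        raise ValueError("reference length must be >= 3 (no trinucleotide exists)")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2,
             gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


# ---------------------------------------------------------------------------
# Cohort configuration and truth labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one simulated mutation."""

    sample_id: str
    process: str
    timing_class: str
    multiplicity: int
    cancer_cell_fraction: float

    def __post_init__(self) -> None:
        if self.timing_class in ("early_clonal", "late_clonal") \
                and self.cancer_cell_fraction != 1.0:
            raise ValueError("clonal mutations must have cancer_cell_fraction 1")


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic tumour cohort.

    Defaults describe a WES-like cohort: ~100 substitutions per exome, constant
    depth 100x, purity uniform on [0.6, 1], 70% of the genome diploid and 30%
    at total copy number 3, an early/late/subclonal split of 0.3/0.4/0.3, and
    an even mixture of the four mutational processes in every timing class.
    """

    n_patients: int = 60
    reference_length: int = 100_000
    gc_fraction: float = 0.45
    mean_mutations: float = 100.0
    signature_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SIGNATURE_WEIGHTS.items()})
    timing_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"early_clonal": 0.3, "late_clonal": 0.4,
                                 "subclonal": 0.3})
    subclonal_ccf: tuple[float, float] = (0.1, 0.5)
    early_multiplicity: int = 2
    purity_range: tuple[float, float] = (0.6, 1.0)
    depth: int = 100
    amplified_fraction: float = 0.3
    apobec_cg_fraction: float = 0.3
    carrier_fraction: float = 0.5
    carrier_early_apobec_boost: float = 0.0
    site_depth: int = 30
    site_error_rate: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cls, weights in self.signature_weights.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative mixture weight in class {cls}")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {cls} must sum to 1")
        if abs(sum(self.timing_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("timing fractions must sum to 1")
        lo, hi = self.subclonal_ccf
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("subclonal cancer-cell fractions must lie in (0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def carrier_samples(self, sample_ids: Sequence[str]) -> set[str]:
        """Deterministic carrier assignment: the first round(fraction*n) patients."""
        n_carriers = round(self.carrier_fraction * len(sample_ids))
        return set(sample_ids[:n_carriers])

    def weights_for(self, timing_class: str, carrier: bool) -> dict[str, float]:
        """Mixture weights for one patient cell, with the carrier early-APOBEC boost.

        The boost is added to the early-clonal APOBEC weight of carrier
        patients; the other three processes are scaled down proportionally.
        """
        weights = dict(self.signature_weights[timing_class])
        boost = self.carrier_early_apobec_boost
        if carrier and timing_class == "early_clonal" and boost != 0.0:
            w_a = weights["APOBEC"]
            new_a = min(1.0, w_a + boost)
            scale = (1.0 - new_a) / (1.0 - w_a) if w_a < 1.0 else 0.0
            weights = {p: (new_a if p == "APOBEC" else w * scale)
                       for p, w in weights.items()}
        return weights


# ---------------------------------------------------------------------------
# Context site indexes
# ---------------------------------------------------------------------------

@dataclass
class _SiteIndex:
    """0-based interior positions of the reference, grouped by process context."""

    apobec: np.ndarray   # pyrimidine-strand C in TCA/TCT (TCW)
    smoking: np.ndarray  # any C (pyrimidine strand)
    ageing: np.ndarray   # C in NCG context (pyrimidine strand)
    other: np.ndarray    # every interior position


def index_context_sites(reference: str) -> _SiteIndex:
    seq = reference.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    interior = np.arange(1, n - 1)
    is_c = arr == b"C"
    is_g = arr == b"G"
    pyr_c = (is_c | is_g)[1:n - 1]

    # pyrimidine-strand 5' and 3' neighbours of each interior position
    def _tcw(i: np.ndarray) -> np.ndarray:
        fwd = is_c[i] & (arr[i - 1] == b"T") & np.isin(arr[i + 1], (b"A", b"T"))
        rev = is_g[i] & (arr[i + 1] == b"A") & np.isin(arr[i - 1], (b"A", b"T"))
        return fwd | rev

    def _ncg(i: np.ndarray) -> np.ndarray:
        fwd = is_c[i] & (arr[i + 1] == b"G")
        rev = is_g[i] & (arr[i - 1] == b"C")
        return fwd | rev

    return _SiteIndex(
        apobec=interior[_tcw(interior)],
        smoking=interior[pyr_c],
        ageing=interior[_ncg(interior)],
        other=interior,
    )


def _mutate(ref_base: str, pyr_alt: str) -> str:
    """Alternate base on the genomic strand for a pyrimidine-strand C->pyr_alt."""
    if ref_base in "CT":
        return pyr_alt
    return pyr_alt.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig, reference: str,
                    ) -> tuple[list[MutationRecord], list[CopySegment],
                               list[SampleMeta], list[TruthLabel]]:
    """Simulate mutation catalogs, segments and purities with truth labels.

    Returns parallel mutation and truth lists (one truth label per record).
    Raises if an APOBEC mixture weight is positive but the reference contains
    no TCW site, or if a patient draws more mutations than the reference can
    accommodate without position reuse.
    """
    seq = reference.upper()
    sites = index_context_sites(seq)
    wants_apobec = any(w.get("APOBEC", 0) > 0
                       for w in config.signature_weights.values())
    if wants_apobec and sites.apobec.size == 0:
        raise ValueError("reference contains no TCA/TCT (TCW) site but the "
                         "configuration requests APOBEC mutations")
    rng = np.random.default_rng(config.rng_seed)
    sample_ids = [f"P{i:04d}" for i in range(config.n_patients)]
    carriers = config.carrier_samples(sample_ids)

    diploid_end = int(round(len(seq) * (1.0 - config.amplified_fraction)))
    diploid_end = min(max(diploid_end, 0), len(seq))
    segments: list[CopySegment] = []
    metas: list[SampleMeta] = []
    mutations: list[MutationRecord] = []
    truths: list[TruthLabel] = []

    site_pool = {"APOBEC": sites.apobec, "smoking": sites.smoking,
                 "ageing": sites.ageing, "other": sites.other}
    timing_names = list(config.timing_fractions)
    timing_probs = np.array([config.timing_fractions[t] for t in timing_names])

    for sample in sample_ids:
        purity = float(rng.uniform(*config.purity_range))
        metas.append(SampleMeta(sample_id=sample, purity=purity))
        if diploid_end >= 1:
            segments.append(CopySegment(sample_id=sample, chrom="chr1", start=1,
                                        end=diploid_end, segment_mean=0.0,
                                        total_cn=2))
        if diploid_end < len(seq):
            segments.append(CopySegment(sample_id=sample, chrom="chr1",
                                        start=diploid_end + 1, end=len(seq),
                                        segment_mean=math.log2(1.5), total_cn=3))

        n_mut = int(rng.poisson(config.mean_mutations))
        if n_mut > len(sites.other):
            raise ValueError(
                f"patient {sample} requests {n_mut} mutations but the reference "
                f"has only {len(sites.other)} usable positions")
        used: set[int] = set()
        classes = rng.choice(timing_names, size=n_mut, p=timing_probs)
        for timing_class in classes:
            weights = config.weights_for(timing_class, sample in carriers)
            process = str(rng.choice(PROCESSES,
                                     p=[weights[p] for p in PROCESSES]))
            pool = site_pool[process]
            for _ in range(1000):
                i = int(pool[rng.integers(len(pool))])
                if i not in used:
                    break
            else:
                raise ValueError(f"could not place a {process} mutation without "
                                 f"reusing a position for {sample}")
            used.add(i)
            total_cn = 2 if i < diploid_end else 3
            if timing_class == "early_clonal":
                multiplicity, ccf = min(config.early_multiplicity, total_cn), 1.0
            elif timing_class == "late_clonal":
                multiplicity, ccf = 1, 1.0
            else:
                multiplicity = 1
                ccf = float(rng.uniform(*config.subclonal_ccf))
            ref_base = seq[i]
            if process == "APOBEC":
                pyr_alt = "G" if rng.random() < config.apobec_cg_fraction else "T"
                alt = _mutate(ref_base, pyr_alt)
            elif process == "smoking":
                alt = _mutate(ref_base, "A")
            elif process == "ageing":
                alt = _mutate(ref_base, "T")
            else:
                alt = str(rng.choice([b for b in BASES if b != ref_base]))
            af = expected_allele_fraction(multiplicity, ccf, purity, total_cn)
            alt_count = int(rng.binomial(config.depth, min(af, 1.0)))
            mutations.append(MutationRecord(
                sample_id=sample, chrom="chr1", pos=i + 1, ref_base=ref_base,
                alt_base=alt, ref_count=config.depth - alt_count,
                alt_count=alt_count))
            truths.append(TruthLabel(
                sample_id=sample, process=process, timing_class=str(timing_class),
                multiplicity=multiplicity, cancer_cell_fraction=ccf))
    return mutations, segments, metas, truths


# ---------------------------------------------------------------------------
# Haplotype panels with block LD structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One LD block: SNP count, target within-block r², alternate-allele frequency.

    ``alt_freq`` is either a scalar or a per-population mapping. Each haplotype
    draws a latent block allele Z ~ Bernoulli(p); every SNP copies Z with
    probability ``1 - e`` and otherwise redraws Bernoulli(p) independently,
    with ``e = 1 - r2 ** 0.25`` so that every within-block SNP pair has
    correlation (1-e)² and hence r² equal to the target in expectation.
    """

    n_snps: int
    target_r2: float
    alt_freq: float | Mapping[str, float] = 0.5
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_r2 <= 1.0):
            raise ValueError("target r2 must be in [0, 1]")
        if self.snp_ids is not None and len(self.snp_ids) != self.n_snps:
            raise ValueError("snp_ids length must equal n_snps")

    def freq(self, population: str | None) -> float:
        if isinstance(self.alt_freq, Mapping):
            return float(self.alt_freq[population])
        return float(self.alt_freq)


def simulate_haplotype_panel(n_samples: int, blocks: Sequence[BlockSpec],
                             population_labels: Sequence[str] | None = None,
                             rng_seed: int = 0,
                             chrom: str = "chr22") -> HaplotypePanel:
    """Phased haplotype panel with independent LD blocks.

    Within-block empirical r² approaches each block's target as ``n_samples``
    grows; SNPs in different blocks are generated independently.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if population_labels is None:
        population_labels = ["ALL"] * n_samples
    if len(population_labels) != n_samples:
        raise ValueError("one population label required per sample")
    rng = np.random.default_rng(rng_seed)
    n_hap = 2 * n_samples
    hap_pops = np.repeat(np.asarray(population_labels, dtype=object), 2)

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for b, block in enumerate(blocks):
        p = np.array([block.freq(pop) for pop in hap_pops])
        e = 1.0 - block.target_r2 ** 0.25
        z = (rng.random(n_hap) < p).astype(np.int8)
        for j in range(block.n_snps):
            fresh = (rng.random(n_hap) < p).astype(np.int8)
            use_z = rng.random(n_hap) >= e
            columns.append(np.where(use_z, z, fresh).astype(np.int8))
            snp_ids.append(block.snp_ids[j] if block.snp_ids is not None
                           else f"blk{b}_snp{j}")
            chroms.append(chrom)
            positions.append(100_000 * (b + 1) + 100 * (j + 1))
    haplotypes = (np.stack(columns, axis=1) if columns
                  else np.zeros((n_hap, 0), dtype=np.int8))
    samples = [f"S{i:05d}" for i in range(n_samples)]
    return HaplotypePanel(snp_ids=snp_ids, chroms=chroms,
                          positions=np.array(positions, dtype=np.int64),
                          ref_alleles=["A"] * len(snp_ids),
                          alt_alleles=["G"] * len(snp_ids),
                          samples=samples,
                          populations=list(population_labels),
                          haplotypes=haplotypes)


#: Synthetic global survey of (A3B deletion-allele frequency, A3H-I allele
#: frequency) per population, anchored to the reported geography: African
#: populations carry A3B almost universally (>95% presence) with A3H-I below
#: 10%, Southeast/East Asian populations carry the deletion at >30% with
#: A3H-I near 65%, and European/South-Asian/admixed-American populations sit
#: in between (global A3H-I frequency ~48%). Population codes follow the
#: 3-letter survey convention; the exact per-population values are synthetic.
GLOBAL_POPULATION_PRESET: dict[str, tuple[float, float]] = {
    "YRI": (0.01, 0.06), "LWK": (0.02, 0.08), "GWD": (0.02, 0.05),
    "ESN": (0.01, 0.09), "ACB": (0.04, 0.12),
    "CEU": (0.06, 0.54), "GBR": (0.05, 0.50), "TSI": (0.07, 0.45),
    "IBS": (0.06, 0.42),
    "GIH": (0.15, 0.40), "PJL": (0.12, 0.35),
    "CHB": (0.30, 0.58), "JPT": (0.28, 0.55), "KHV": (0.37, 0.66),
    "CDX": (0.40, 0.68),
    "MXL": (0.20, 0.42), "PEL": (0.25, 0.50),
}


def simulate_global_panel(samples_per_population: int = 120,
                          rng_seed: int = 0,
                          preset: Mapping[str, tuple[float, float]] | None = None,
                          ) -> HaplotypePanel:
    """Phased panel with an A3B-deletion marker and the A3H-I (Gly105) SNP.

    The two markers sit in independent LD blocks (the loci are genetically
    unlinked) with per-population allele frequencies from ``preset``
    (default :data:`GLOBAL_POPULATION_PRESET`).
    """
    preset = dict(preset or GLOBAL_POPULATION_PRESET)
    labels: list[str] = []
    for pop in preset:
        labels.extend([pop] * samples_per_population)
    blocks = [
        BlockSpec(n_snps=1, target_r2=1.0,
                  alt_freq={p: del_freq for p, (del_freq, _) in preset.items()},
                  snp_ids=("A3B_del",)),
        BlockSpec(n_snps=1, target_r2=1.0,
                  alt_freq={p: a3h1 for p, (_, a3h1) in preset.items()},
                  snp_ids=("A3H_I",)),
    ]
    return simulate_haplotype_panel(len(labels), blocks,
                                    population_labels=labels,
                                    rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Site-call summaries at haplotype-defining positions
# ---------------------------------------------------------------------------

def simulate_site_calls(diplotype: tuple[str, str], depth: int,
                        error_rate: float, rng_seed: int = 0,
                        sample_id: str = "S0000",
                        haplotype_table: "Mapping[str, Mapping[str, str]] | None" = None,
                        ) -> list[SiteCallSummary]:
    """Base-call summaries at every haplotype-defining site for one diplotype.

    Each read samples one of the two haplotype alleles with equal probability
    and is then miscalled to a uniform other base with probability
    ``error_rate``. ``depth`` 0 yields zero-coverage summaries (flagged through
    :attr:`SiteCallSummary.no_coverage`).
    """
    from .genotype import load_haplotype_table

    if not (0.0 <= error_rate <= 0.25):
        raise ValueError("error_rate must be in [0, 0.25]")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    table = haplotype_table if haplotype_table is not None \
        else load_haplotype_table().alleles
    h1, h2 = diplotype
    for h in (h1, h2):
        if h not in table:
            raise KeyError(f"unknown haplotype {h!r}")
    rng = np.random.default_rng(rng_seed)
    out: list[SiteCallSummary] = []
    sites = sorted(set(table[h1]) | set(table[h2]))
    for site in sites:
        probs = np.zeros(4)
        for allele in (table[h1][site], table[h2][site]):
            k = BASES.index(allele)
            probs += 0.5 * np.where(np.arange(4) == k,
                                    1.0 - error_rate, error_rate / 3.0)
        counts = rng.multinomial(depth, probs) if depth > 0 else np.zeros(4, int)
        quality = float(np.clip(rng.normal(37.0, 2.0), 2.0, 60.0))
        out.append(SiteCallSummary(
            sample_id=sample_id, site_id=site,
            base_counts={b: int(c) for b, c in zip(BASES, counts)},
            mean_quality=quality, coverage=int(counts.sum())))
    return out


# ---------------------------------------------------------------------------
# Deaminated amplicons
# ---------------------------------------------------------------------------

_CONTEXT_KEYS = ("TC", "CC", "GC", "AC")


@dataclass
class AmpliconSet:
    """Simulated amplicons plus the planted C->T event truth."""

    reference: str
    sequences: list[str]
    truth_per_context: dict[str, int]
    truth_per_sequence: list[int]

    @property
    def total_planted(self) -> int:
        return sum(self.truth_per_context.values())


def simulate_amplicons(reference: str, rates: Mapping[str, float],
                       n_sequences: int, rng_seed: int = 0) -> AmpliconSet:
    """Plant C->T deamination events keyed by the 5' dinucleotide context.

    ``rates`` maps TC/CC/GC/AC to per-site deamination probabilities on the
    given strand. The first base of the reference has no 5' neighbour and is
    never mutated. Truth counts equal planted events exactly.
    """
    seq = reference.upper()
    unknown = set(rates) - set(_CONTEXT_KEYS)
    if unknown:
        raise ValueError(f"unknown context keys {sorted(unknown)}; "
                         f"expected subset of {_CONTEXT_KEYS}")
    if any(not (0.0 <= r <= 1.0) for r in rates.values()):
        raise ValueError("deamination rates must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    sequences: list[str] = []
    per_context = {k: 0 for k in _CONTEXT_KEYS}
    per_sequence: list[int] = []
    c_positions = [i for i in range(1, len(seq)) if seq[i] == "C"]
    contexts = {i: seq[i - 1] + "C" for i in c_positions}
    for _ in range(n_sequences):
        chars = list(seq)
        planted = 0
        for i in c_positions:
            rate = rates.get(contexts[i], 0.0)
            if rate > 0.0 and rng.random() < rate:
                chars[i] = "T"
                per_context[contexts[i]] += 1
                planted += 1
        sequences.append("".join(chars))
        per_sequence.append(planted)
    return AmpliconSet(reference=seq, sequences=sequences,
                       truth_per_context=per_context,
                       truth_per_sequence=per_sequence)


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything one simulated study comprises, with its ground truth."""

    config: CohortConfig
    reference: str
    mutations: list[MutationRecord]
    segments: list[CopySegment]
    purity: list[SampleMeta]
    truth: list[TruthLabel]
    carriers: dict[str, bool]
    diplotypes: dict[str, tuple[str, str]]
    site_calls: list[SiteCallSummary]


_CARRIER_DIPLOTYPES = (("I", "II"), ("I", "I"), ("I", "III"))
_NONCARRIER_DIPLOTYPES = (("II", "II"), ("II", "III"), ("III", "III"))


def simulate_study(config: CohortConfig) -> CohortBundle:
    """Simulate a full study: reference, cohort, planted A3H diplotypes, site calls."""
    seed = np.random.SeedSequence(config.rng_seed)
    ref_seed, cohort_seed, geno_seed = [int(s.generate_state(1)[0] % 2**31)
                                        for s in seed.spawn(3)]
    reference = simulate_reference(config.reference_length, config.gc_fraction,
                                   rng_seed=ref_seed)
    cohort_cfg = replace(config, rng_seed=cohort_seed)
    mutations, segments, purity, truth = simulate_cohort(cohort_cfg, reference)
    sample_ids = [m.sample_id for m in purity]
    carrier_set = config.carrier_samples(sample_ids)
    rng = np.random.default_rng(geno_seed)
    diplotypes: dict[str, tuple[str, str]] = {}
    site_calls: list[SiteCallSummary] = []
    for sample in sample_ids:
        pool = _CARRIER_DIPLOTYPES if sample in carrier_set else _NONCARRIER_DIPLOTYPES
        diplotypes[sample] = tuple(pool[rng.integers(len(pool))])
        site_calls.extend(simulate_site_calls(
            diplotypes[sample], depth=config.site_depth,
            error_rate=config.site_error_rate,
            rng_seed=int(rng.integers(2**31)), sample_id=sample))
    return CohortBundle(config=config, reference=reference, mutations=mutations,
                        segments=segments, purity=purity, truth=truth,
                        carriers={s: s in carrier_set for s in sample_ids},
                        diplotypes=diplotypes, site_calls=site_calls)
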