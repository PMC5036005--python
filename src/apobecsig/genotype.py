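"""Germline APOBEC3 genotype calling and population allele frequencies.

Two germline determinations drive the downstream analyses:

* **A3B deletion zygosity** — a ~29.5-kbp deletion removes the APOBEC3B coding
  sequence. Homozygous deletion ("A3B-null") is called from SNP-array copy
  number segments (segment mean <= -1.5 over the A3B interval by default) and,
  when available, confirmed by a normalized exon-coverage ratio between exons
  inside the deleted interval and the flanking exons preserved with the
  deletion allele.

* **A3H diplotype** — APOBEC3H carries seven reported haplotypes. Haplotype I
  carries Gly105 (versus Arg105 in the stable haplotypes II/V/VII), and
  haplotypes III/IV/VI carry the destabilizing Asn15 deletion. A sample is an
  "A3H-I carrier" when at least one called haplotype carries Gly105. Diploid
  genotypes are called per site from base-call summaries, then resolved to a
  haplotype pair against a (site, haplotype, allele) table that is shipped as
  data and fully overridable.

Population allele frequencies and their cross-population rank correlation are
estimated from phased haplotype panels.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import BASES, CopySegment, HaplotypePanel, SiteCallSummary, _read_tsv

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

#: Default A3B interval on chr22: anchored at the printed SNP-array probe start
#: positions (37693530..37693565) and extended over the ~30-kbp deletion span.
A3B_DEFAULT_INTERVAL: tuple[str, int, int] = ("chr22", 37_693_530, 37_723_530)


# ---------------------------------------------------------------------------
# Haplotype table
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Per-haplotype allele map over the A3H-defining sites.

    ``alleles[haplotype][site_id]`` gives the base carried by that haplotype.
    ``g105_site``/``g105_allele`` identify the codon-105 site and the allele
    encoding Gly105, the only inputs to carrier status.
    """

    alleles: dict[str, dict[str, str]]
    g105_site: str = "site105"
    g105_allele: str = "G"

    def __post_init__(self) -> None:
        sites = None
        for hap, mapping in self.alleles.items():
            if sites is None:
                sites = set(mapping)
            elif set(mapping) != sites:
                raise ValueError(f"haplotype {hap} does not cover the same "
                                 f"sites as the others")
        if sites is not None and self.g105_site not in sites:
            raise ValueError(f"table lacks the codon-105 site {self.g105_site!r}")

    @property
    def sites(self) -> list[str]:
        first = next(iter(self.alleles.values()))
        return sorted(first)

    @property
    def haplotypes(self) -> list[str]:
        return sorted(self.alleles)


def load_haplotype_table(path: str | Path | None = None) -> HaplotypeTable:
    """Load the packaged default haplotype table, or a user TSV override.

    The TSV has columns site_id, haplotype, allele. The packaged default is a
    synthetic tagging-SNP encoding of the published haplotype dichotomies.
    """
    if path is None:
        source = resources.files("apobecsig.data") / "a3h_haplotypes.tsv"
        with resources.as_file(source) as p:
            df, _ = _read_tsv(p)
    else:
        df, _ = _read_tsv(path)
    for col in ("site_id", "haplotype", "allele"):
        if col not in df.columns:
            raise ValueError(f"haplotype table missing column '{col}'")
    alleles: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        hap = str(row[df.columns.get_loc("haplotype")])
        site = str(row[df.columns.get_loc("site_id")])
        allele = str(row[df.columns.get_loc("allele")]).upper()
        alleles.setdefault(hap, {})[site] = allele
    return HaplotypeTable(alleles=alleles)


# ---------------------------------------------------------------------------
# A3B deletion zygosity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class A3BThresholds:
    """Decision thresholds for A3B deletion calling.

    ``null_segment_mean`` follows the published rule (segment mean of -1.5 or
    less). The remaining values operationalize the study's manual-inspection
    confirmation step and are deliberately configurable.
    """

    null_segment_mean: float = -1.5
    null_coverage_ratio: float = 0.2
    intact_segment_mean: float = -0.25
    intact_coverage_ratio: float = 0.75


@dataclass
class A3BZygosity:
    sample_id: str
    call: str  # "null" | "intact" | "indeterminate"
    min_segment_mean: float | None = None
    coverage_ratio: float | None = None
    reason: str | None = None


def call_a3b_zygosity(segments: Sequence[CopySegment],
                      a3b_interval: tuple[str, int, int] = A3B_DEFAULT_INTERVAL,
                      exon_coverage: Mapping[str, tuple[int, float]] | None = None,
                      thresholds: A3BThresholds = A3BThresholds(),
                      sample_id: str | None = None) -> A3BZygosity:
    """Call A3B deletion zygosity for one sample.

    ``segments`` are that sample's copy-number segments. ``exon_coverage``
    optionally maps exon id -> (1-based midpoint position, normalized depth);
    exons inside the interval are the deletion candidates and exons outside
    are the preserved flanks, and their depth ratio confirms the call.
    """
    chrom, start, end = a3b_interval
    if sample_id is None:
        sample_id = segments[0].sample_id if segments else "?"
    overlapping = [s for s in segments
                   if s.chrom == chrom and s.start <= end and s.end >= start
                   and s.segment_mean is not None]
    seg_min = min((s.segment_mean for s in overlapping), default=None)

    ratio: float | None = None
    if exon_coverage:
        inside = [d for pos, d in exon_coverage.values() if start <= pos <= end]
        outside = [d for pos, d in exon_coverage.values() if not start <= pos <= end]
        if inside and outside and sum(outside) > 0:
            ratio = (sum(inside) / len(inside)) / (sum(outside) / len(outside))

    if seg_min is None and ratio is None:
        return A3BZygosity(sample_id=sample_id, call="indeterminate",
                           reason="no evidence")

    th = thresholds
    seg_null = seg_min is not None and seg_min <= th.null_segment_mean
    seg_intact = seg_min is not None and seg_min >= th.intact_segment_mean
    ratio_null = ratio is not None and ratio <= th.null_coverage_ratio
    ratio_intact = ratio is not None and ratio >= th.intact_coverage_ratio

    if seg_null and (ratio is None or ratio_null):
        call, reason = "null", None
    elif seg_min is None and ratio_null:
        call, reason = "null", "coverage ratio only"
    elif seg_intact and (ratio is None or ratio_intact):
        call, reason = "intact", None
    elif seg_min is None and ratio_intact:
        call, reason = "intact", "coverage ratio only"
    else:
        call, reason = "indeterminate", "evidence between thresholds"
    return A3BZygosity(sample_id=sample_id, call=call, min_segment_mean=seg_min,
                       coverage_ratio=ratio, reason=reason)


# ---------------------------------------------------------------------------
# A3H diplotypes
# ---------------------------------------------------------------------------

@dataclass
class A3HDiplotype:
    """A3H haplotype pair, carrier status and the evidence behind them.

    ``carrier_status`` is True when >= 1 called Gly105 copy, False when the
    codon-105 genotype is called without one, and None when that site could
    not be called. ``haplotype_pair`` is ('unknown', 'unknown') when sites are
    uncallable or the genotype pattern matches no table entry; when several
    pairs are compatible the lexicographically smallest is reported with
    ``ambiguous`` set.
    """

    sample_id: str
    haplotype_pair: tuple[str, str]
    carrier_status: bool | None
    g105_copies: int | None
    ambiguous: bool = False
    compatible_pairs: list[tuple[str, str]] = field(default_factory=list)
    site_genotypes: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    site_evidence: list[SiteCallSummary] = field(default_factory=list)


def call_diploid_genotype(summary: SiteCallSummary, min_coverage: int = 8,
                          min_quality: float = 20.0, hom_fraction: float = 0.9,
                          het_min: float = 0.25) -> tuple[str, str] | None:
    """Diploid genotype at one site from base counts, or None if uncallable.

    Homozygous when the major allele holds >= ``hom_fraction`` of reads; het
    when the second allele holds >= ``het_min``; otherwise uncallable.
    """
    if summary.coverage < min_coverage or summary.mean_quality < min_quality:
        return None
    ranked = sorted(BASES, key=lambda b: (-summary.base_counts[b], b))
    top, second = ranked[0], ranked[1]
    top_frac = summary.base_counts[top] / summary.coverage
    second_frac = summary.base_counts[second] / summary.coverage
    if top_frac >= hom_fraction:
        return (top, top)
    if second_frac >= het_min:
        return tuple(sorted((top, second)))  # type: ignore[return-value]
    return None


def call_a3h_diplotype(site_calls: Sequence[SiteCallSummary],
                       haplotype_table: HaplotypeTable | None = None,
                       min_coverage: int = 8, min_quality: float = 20.0,
                       hom_fraction: float = 0.9, het_min: float = 0.25,
                       ) -> A3HDiplotype:
    """Resolve one sample's site-call summaries to an A3H diplotype.

    Site phase is not inferred: when the unphased genotype pattern is
    compatible with several haplotype pairs, the lexicographically smallest
    pair is reported with an ambiguity flag. Carrier status depends only on
    the called number of Gly105 copies at the codon-105 site.
    """
    table = haplotype_table or load_haplotype_table()
    if not site_calls:
        raise ValueError("no site calls supplied")
    sample_id = site_calls[0].sample_id
    by_site = {c.site_id: c for c in site_calls}
    if table.g105_site not in by_site:
        raise ValueError(f"site calls do not cover the codon-105 site "
                         f"{table.g105_site!r}")

    genotypes: dict[str, tuple[str, str] | None] = {}
    for site in table.sites:
        summary = by_site.get(site)
        genotypes[site] = None if summary is None else call_diploid_genotype(
            summary, min_coverage=min_coverage, min_quality=min_quality,
            hom_fraction=hom_fraction, het_min=het_min)

    g105_gt = genotypes.get(table.g105_site)
    if g105_gt is None:
        g105_copies: int | None = None
        carrier: bool | None = None
    else:
        g105_copies = sum(1 for a in g105_gt if a == table.g105_allele)
        carrier = g105_copies >= 1

    # resolve the pair only when every table site is callable
    pair = (UNKNOWN, UNKNOWN)
    ambiguous = False
    compatible: list[tuple[str, str]] = []
    if all(genotypes[s] is not None for s in table.sites):
        for h1, h2 in itertools.combinations_with_replacement(table.haplotypes, 2):
            if all(tuple(sorted((table.alleles[h1][s], table.alleles[h2][s])))
                   == genotypes[s] for s in table.sites):
                compatible.append((h1, h2))
        if compatible:
            compatible.sort()
            pair = compatible[0]
            ambiguous = len(compatible) > 1
    return A3HDiplotype(sample_id=sample_id, haplotype_pair=pair,
                        carrier_status=carrier, g105_copies=g105_copies,
                        ambiguous=ambiguous, compatible_pairs=compatible,
                        site_genotypes=genotypes,
                        site_evidence=list(site_calls))


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-population alternate-allele frequencies for one SNP."""

    snp_id: str
    by_population: dict[str, float]
    n_haplotypes: dict[str, int]
    overall: float


def estimate_allele_frequencies(panel: HaplotypePanel,
                                snp_id: str) -> AlleleFrequencies:
    """Alt-allele frequency per population: alt haplotypes / (2 x samples).

    The overall frequency is the sample-count-weighted mean, i.e. total alt
    haplotypes over total haplotypes. Populations with no samples are excluded
    with a warning.
    """
    column = panel.column(snp_id)
    hap_pops = panel.haplotype_populations()
    by_pop: dict[str, float] = {}
    n_hap: dict[str, int] = {}
    labels = list(dict.fromkeys(p if p is not None else "ALL" for p in hap_pops))
    for label in labels:
        mask = np.array([(p if p is not None else "ALL") == label
                         for p in hap_pops])
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"population {label!r} has no haplotypes; excluded")
            continue
        by_pop[label] = float(column[mask].sum() / n)
        n_hap[label] = n
    overall = float(column.sum() / len(column)) if len(column) else math.nan
    return AlleleFrequencies(snp_id=snp_id, by_population=by_pop,
                             n_haplotypes=n_hap, overall=overall)


def population_correlation(freq_x: Sequence[float], freq_y: Sequence[float],
                           exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation across paired population frequencies.

    Ties take mid-ranks. The two-sided P value uses the exact permutation
    distribution for n <= ``exact_max_n`` and the standard large-sample
    t approximation otherwise. A constant vector has undefined rho and
    returns (nan, nan).
    """
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must be paired (equal length)")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired populations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant frequency vector: Spearman rho undefined")
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        den = math.sqrt(float((rx_c ** 2).sum()) *
                        float(((ry - ry.mean()) ** 2).sum()))
        rhos = (permuted - ry.mean()) @ rx_c / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return (rho, p)
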