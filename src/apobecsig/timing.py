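"""Clonality timing of somatic mutations from purity/copy-number-adjusted
allele fractions.

Model
-----
A mutation present on ``m`` of ``CN`` tumour copies in a tumour of purity
``rho`` has expected variant allele fraction

    VAF = m * rho / (CN * rho + 2 * (1 - rho)),

so the multiplicity estimate is the inversion

    m_hat = VAF * (rho * CN + 2 * (1 - rho)) / rho,

which reproduces the two printed anchors: VAF 0.50 corresponds to 1 of 2
copies and VAF 0.667 to 2 of 3 copies at purity 1. The adjusted allele
fraction is ``m_hat / CN``.

Uncertainty comes from a read-resampling bootstrap: each replicate redraws the
alternate read count at **half** the observed coverage (odd coverages rounded
up) from Binomial(ceil(cov/2), alt/cov), maps the replicate VAF through the
multiplicity formula, and the 95% CI is the percentile interval of the
replicate multiplicities (10,000 replicates by default). Resampling at half
coverage deliberately widens the intervals, making the timing calls
conservative.

Timing classes (copy scale):

- ``early_clonal`` — lower CI bound > 1 copy: the mutation sits on
  significantly more than one copy and, multiplicities being integers, on at
  least two — in an amplified region that places it before the copy-number
  gain, and in a diploid region before a copy-neutral duplication;
- ``subclonal``    — upper CI bound < 1 copy (present in a subpopulation);
- ``late_clonal``  — everything else with CN >= 2, i.e. the CI is consistent
  with exactly 1 copy;
- ``unevaluable``  — CN < 2 by default (no published rule covers deletions),
  or missing counts/segment/purity.
"""
from __future__ import annotations

import math
import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CopySegment, MutationRecord, SampleMeta

TIMING_CLASSES = ("early_clonal", "late_clonal", "subclonal", "unevaluable")


def adjusted_multiplicity(vaf: float, purity: float, total_cn: int) -> float:
    """Copies carrying the mutation: ``vaf * (purity*CN + 2*(1-purity)) / purity``.

    Monotone increasing in ``vaf``. ``purity`` must be in (0, 1].
    """
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if total_cn < 1:
        raise ValueError(f"total_cn must be >= 1, got {total_cn}")
    return vaf * (purity * total_cn + 2.0 * (1.0 - purity)) / purity


def adjusted_allele_fraction(vaf: float, purity: float, total_cn: int) -> float:
    """Adjusted AF = multiplicity / CN (the copy-scale fraction of the segment)."""
    return adjusted_multiplicity(vaf, purity, total_cn) / total_cn


def bootstrap_ci(ref_count: int, alt_count: int, purity: float, total_cn: int,
                 n_boot: int = 10_000, level: float = 0.95,
                 rng: np.random.Generator | int | None = 0,
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI of the multiplicity, resampled at half coverage.

    Each replicate draws alt* ~ Binomial(ceil(cov/2), alt/cov), forms
    vaf* = alt*/ceil(cov/2) and maps it through the multiplicity formula;
    the CI is the ((1-level)/2, 1-(1-level)/2) percentile pair. Deterministic
    given the generator or seed.
    """
    coverage = ref_count + alt_count
    if coverage < 2:
        raise ValueError("coverage must be >= 2 for a resampling CI")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    half = math.ceil(coverage / 2)
    p = alt_count / coverage
    draws = rng.binomial(half, p, size=n_boot)
    factor = (purity * total_cn + 2.0 * (1.0 - purity)) / purity
    m = draws / half * factor
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(m, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def classify_clonality(ci: tuple[float, float], total_cn: int,
                       allow_low_cn: bool = False) -> str:
    """Timing class from a copy-scale CI (see module docstring for the rules)."""
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"CI lower bound {lo} exceeds upper bound {hi}")
    if total_cn < 2 and not allow_low_cn:
        return "unevaluable"
    if lo > 1.0:
        return "early_clonal"
    if hi < 1.0:
        return "subclonal"
    return "late_clonal"


@dataclass
class ClonalityCall:
    """Per-mutation timing call with its bootstrap evidence."""

    mutation: MutationRecord
    timing_class: str
    multiplicity_hat: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    adjusted_af: float | None = None
    total_cn: int | None = None
    n_boot: int = 0
    seed: int | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.timing_class not in TIMING_CLASSES:
            raise ValueError(f"unknown timing class {self.timing_class!r}")
        if self.timing_class != "unevaluable":
            if None in (self.multiplicity_hat, self.ci_lower, self.ci_upper):
                raise ValueError("evaluated calls require estimate and CI")
            if not (self.ci_lower <= self.multiplicity_hat <= self.ci_upper):
                raise ValueError(
                    f"point estimate {self.multiplicity_hat:.4f} outside CI "
                    f"[{self.ci_lower:.4f}, {self.ci_upper:.4f}]")


def _mutation_seed(global_seed: int, mutation: MutationRecord) -> np.random.SeedSequence:
    """Order-independent per-mutation RNG substream keyed by identity."""
    key = f"{mutation.sample_id}|{mutation.chrom}|{mutation.pos}".encode()
    return np.random.SeedSequence([int(global_seed), zlib.crc32(key)])


def timing_pipeline(mutations: Sequence[MutationRecord],
                    segments: Sequence[CopySegment],
                    purity_table: Sequence[SampleMeta] | Mapping[str, float],
                    n_boot: int = 10_000, level: float = 0.95,
                    rng_seed: int = 0, allow_low_cn: bool = False,
                    ) -> list[ClonalityCall]:
    """Classify every mutation; missing evidence yields ``unevaluable`` with a
    reason. Duplicate (sample, chrom, pos) records are an error. Calls are
    order-independent: each mutation gets an RNG substream derived from
    (seed, sample, chrom, pos).
    """
    seen: Counter = Counter((m.sample_id, m.chrom, m.pos) for m in mutations)
    dupes = [k for k, v in seen.items() if v > 1]
    if dupes:
        raise ValueError(f"duplicate mutation records: {dupes[:5]}"
                         + ("..." if len(dupes) > 5 else ""))
    if isinstance(purity_table, Mapping):
        purity_map = dict(purity_table)
    else:
        purity_map = {m.sample_id: m.purity for m in purity_table}
    seg_by_sample: dict[str, list[CopySegment]] = {}
    for seg in segments:
        seg_by_sample.setdefault(seg.sample_id, []).append(seg)

    calls: list[ClonalityCall] = []
    for mutation in mutations:
        def unevaluable(reason: str) -> ClonalityCall:
            return ClonalityCall(mutation=mutation, timing_class="unevaluable",
                                 reason=reason, n_boot=n_boot, seed=rng_seed)

        if mutation.coverage is None:
            calls.append(unevaluable("no read counts"))
            continue
        if mutation.coverage < 2:
            calls.append(unevaluable("coverage < 2"))
            continue
        purity = purity_map.get(mutation.sample_id)
        if purity is None:
            calls.append(unevaluable("no purity"))
            continue
        segment = next((s for s in seg_by_sample.get(mutation.sample_id, ())
                        if s.overlaps(mutation.chrom, mutation.pos)), None)
        if segment is None:
            calls.append(unevaluable("no segment"))
            continue
        if segment.total_cn is None:
            calls.append(unevaluable("no copy number"))
            continue
        total_cn = segment.total_cn
        if total_cn < 1:
            calls.append(unevaluable("copy number 0"))
            continue
        if total_cn < 2 and not allow_low_cn:
            calls.append(unevaluable("copy number < 2"))
            continue
        vaf = mutation.vaf
        m_hat = adjusted_multiplicity(vaf, purity, total_cn)
        sub_rng = np.random.default_rng(_mutation_seed(rng_seed, mutation))
        lo, hi = bootstrap_ci(mutation.ref_count, mutation.alt_count, purity,
                              total_cn, n_boot=n_boot, level=level, rng=sub_rng)
        calls.append(ClonalityCall(
            mutation=mutation,
            timing_class=classify_clonality((lo, hi), total_cn,
                                            allow_low_cn=allow_low_cn),
            multiplicity_hat=m_hat, ci_lower=lo, ci_upper=hi,
            adjusted_af=m_hat / total_cn, total_cn=total_cn,
            n_boot=n_boot, seed=rng_seed))
    return calls


def timing_summary(calls: Sequence[ClonalityCall]) -> dict[str, int]:
    """Per-class call counts (all four classes present, zero-filled)."""
    counts = Counter(c.timing_class for c in calls)
    return {cls: counts.get(cls, 0) for cls in TIMING_CLASSES}
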