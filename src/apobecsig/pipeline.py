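"""End-to-end composition: genotype -> spectra -> timing -> group comparison.

The study design this mirrors: tumours are stratified by A3H-I carrier status
(at least one Gly105 copy versus none), each tumour's somatic mutations are
timed as early-clonal / late-clonal / subclonal, per-patient signature
proportions are computed within each timing class, and carrier versus
non-carrier groups are compared per (timing class x category) with Welch's
two-tailed t-test.

Every run records a manifest (version, seed, thresholds) sufficient to
reproduce its outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genotype import A3HDiplotype, HaplotypeTable, call_a3h_diplotype
from .io import (CopySegment, MutationRecord, SampleMeta, SiteCallSummary)
from .signatures import (CATEGORIES, CategoryProportion, GroupComparison,
                         TrinucleotideSpectrum, build_spectrum, compare_groups,
                         per_patient_category_proportions)
from .simulate import CohortBundle, CohortConfig, simulate_study
from .timing import ClonalityCall, timing_pipeline, timing_summary


@dataclass
class RunConfig:
    """Thresholds and reproducibility parameters for an end-to-end run.

    Defaults match the published analysis: segment-mean cutoff -1.5 for the
    A3B deletion, minimum 4 mutations per patient-timing cell, 10,000
    half-coverage bootstrap replicates at the 95% level, and the
    C->T-only APOBEC category for group comparisons.
    """

    rng_seed: int = 0
    n_boot: int = 10_000
    ci_level: float = 0.95
    min_count: int = 4
    null_segment_mean: float = -1.5
    extended_apobec: bool = False
    allow_low_cn: bool = False
    min_site_coverage: int = 8
    min_site_quality: float = 20.0

    def manifest(self) -> dict:
        return {"apobecsig_version": __version__,
                **dataclasses.asdict(self)}


@dataclass
class StudyResult:
    """Outputs of one end-to-end analysis."""

    diplotypes: list[A3HDiplotype]
    carriers: dict[str, bool | None]
    timing_calls: list[ClonalityCall]
    timing_counts: dict[str, int]
    proportions: list[CategoryProportion]
    excluded_cells: list[tuple[str, str, int]]
    comparisons: pd.DataFrame
    spectra: dict[str, TrinucleotideSpectrum]
    manifest: dict

    def comparison(self, timing_class: str, category: str) -> pd.Series:
        mask = ((self.comparisons["timing_class"] == timing_class)
                & (self.comparisons["category"] == category))
        rows = self.comparisons[mask]
        if rows.empty:
            raise KeyError(f"no comparison for {timing_class}/{category}")
        return rows.iloc[0]


def run_analysis(mutations: Sequence[MutationRecord],
                 segments: Sequence[CopySegment],
                 purity: Sequence[SampleMeta],
                 site_calls: Sequence[SiteCallSummary],
                 reference: Mapping[str, str] | str,
                 config: RunConfig = RunConfig(),
                 haplotype_table: HaplotypeTable | None = None) -> StudyResult:
    """Run genotyping, timing, stratified spectra and carrier comparisons."""
    # --- genotype: A3H diplotype per sample -------------------------------
    calls_by_sample: dict[str, list[SiteCallSummary]] = {}
    for call in site_calls:
        calls_by_sample.setdefault(call.sample_id, []).append(call)
    diplotypes = [call_a3h_diplotype(calls, haplotype_table=haplotype_table,
                                     min_coverage=config.min_site_coverage,
                                     min_quality=config.min_site_quality)
                  for calls in calls_by_sample.values()]
    carriers: dict[str, bool | None] = {d.sample_id: d.carrier_status
                                        for d in diplotypes}

    # --- timing -----------------------------------------------------------
    timing_calls = timing_pipeline(mutations, segments, purity,
                                   n_boot=config.n_boot, level=config.ci_level,
                                   rng_seed=config.rng_seed,
                                   allow_low_cn=config.allow_low_cn)
    evaluable = [(c.mutation, c.timing_class) for c in timing_calls
                 if c.timing_class != "unevaluable"]
    timed_mutations = [m for m, _ in evaluable]
    timing_labels = [t for _, t in evaluable]

    # --- per-patient signature proportions --------------------------------
    proportions, excluded = per_patient_category_proportions(
        timed_mutations, reference, timing_classes=timing_labels,
        min_count=config.min_count, extended_apobec=config.extended_apobec)

    # --- carrier vs non-carrier Welch comparisons -------------------------
    rows = []
    timing_classes = sorted({p.timing_class for p in proportions})
    for timing_class in timing_classes:
        for category in CATEGORIES:
            values = {True: [], False: []}
            for p in proportions:
                if p.timing_class != timing_class or p.category != category:
                    continue
                status = carriers.get(p.sample_id)
                if status is not None:
                    values[status].append(p.proportion)
            row = {"timing_class": timing_class, "category": category,
                   "n_carrier": len(values[True]),
                   "n_noncarrier": len(values[False])}
            if len(values[True]) >= 2 and len(values[False]) >= 2:
                cmp: GroupComparison = compare_groups(values[True], values[False])
                row.update({"t": cmp.t, "p": cmp.p,
                            "mean_carrier": cmp.mean_a,
                            "mean_noncarrier": cmp.mean_b,
                            "sem_carrier": cmp.sem_a,
                            "sem_noncarrier": cmp.sem_b})
            else:
                row.update({"t": np.nan, "p": np.nan,
                            "mean_carrier": np.nan, "mean_noncarrier": np.nan,
                            "sem_carrier": np.nan, "sem_noncarrier": np.nan})
            rows.append(row)
    comparisons = pd.DataFrame(rows, columns=[
        "timing_class", "category", "n_carrier", "n_noncarrier", "t", "p",
        "mean_carrier", "mean_noncarrier", "sem_carrier", "sem_noncarrier"])

    # --- genotype-stratified spectra --------------------------------------
    carrier_muts = [m for m in mutations if carriers.get(m.sample_id) is True]
    noncarrier_muts = [m for m in mutations if carriers.get(m.sample_id) is False]
    spectra = {"carrier": build_spectrum(carrier_muts, reference),
               "noncarrier": build_spectrum(noncarrier_muts, reference)}

    manifest = config.manifest()
    manifest.update({
        "n_mutations": len(mutations), "n_samples": len(calls_by_sample),
        "n_carriers": sum(1 for v in carriers.values() if v is True),
        "n_noncarriers": sum(1 for v in carriers.values() if v is False),
    })
    return StudyResult(diplotypes=diplotypes, carriers=carriers,
                       timing_calls=timing_calls,
                       timing_counts=timing_summary(timing_calls),
                       proportions=proportions, excluded_cells=excluded,
                       comparisons=comparisons, spectra=spectra,
                       manifest=manifest)


def run_simulated_study(cohort_config: CohortConfig,
                        run_config: RunConfig | None = None,
                        ) -> tuple[StudyResult, CohortBundle]:
    """Simulate a cohort and analyse it end to end (shared RNG seed)."""
    if run_config is None:
        run_config = RunConfig(rng_seed=cohort_config.rng_seed)
    bundle = simulate_study(cohort_config)
    result = run_analysis(bundle.mutations, bundle.segments, bundle.purity,
                          bundle.site_calls, bundle.reference,
                          config=run_config)
    return result, bundle


# ---------------------------------------------------------------------------
# Result serialization helpers (used by the CLI)
# ---------------------------------------------------------------------------

def proportions_frame(proportions: Sequence[CategoryProportion]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in proportions],
                        columns=["sample_id", "timing_class", "category",
                                 "proportion", "n_category", "n_mutations"])


def timing_frame(calls: Sequence[ClonalityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        m = c.mutation
        rows.append({
            "sample_id": m.sample_id, "chrom": m.chrom, "pos": m.pos,
            "ref": m.ref_base, "alt": m.alt_base,
            "timing_class": c.timing_class,
            "multiplicity_hat": c.multiplicity_hat,
            "ci_lower": c.ci_lower, "ci_upper": c.ci_upper,
            "adjusted_af": c.adjusted_af, "total_cn": c.total_cn,
            "reason": c.reason or "",
        })
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref",
                                       "alt", "timing_class",
                                       "multiplicity_hat", "ci_lower",
                                       "ci_upper", "adjusted_af", "total_cn",
                                       "reason"])


def diplotype_frame(diplotypes: Sequence[A3HDiplotype]) -> pd.DataFrame:
    rows = []
    for d in diplotypes:
        rows.append({
            "sample_id": d.sample_id,
            "haplotype_1": d.haplotype_pair[0],
            "haplotype_2": d.haplotype_pair[1],
            "carrier_status": ("" if d.carrier_status is None
                               else str(d.carrier_status)),
            "g105_copies": "" if d.g105_copies is None else d.g105_copies,
            "ambiguous": d.ambiguous,
        })
    return pd.DataFrame(rows, columns=["sample_id", "haplotype_1",
                                       "haplotype_2", "carrier_status",
                                       "g105_copies", "ambiguous"])
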