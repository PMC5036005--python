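"""Readers, writers and in-memory records for every file format the pipeline touches.

All coordinates are 1-based inclusive, matching MAF/SEG conventions; any 0-based
half-open source must be converted before it reaches these types. Readers validate
on entry so downstream modules consume only the types defined here and never
re-parse files.

Formats
-------
- MAF-like TSV for somatic mutations (TCGA column names by default, overridable
  through a dialect map)
- SEG for copy-number segments (six standard columns, optional ``total_cn``)
- TSV for tumour purity and generic result tables
- FASTA for reference and amplicon sequences (Bio.SeqIO)
- VCF with phased GT fields for haplotype panels (cyvcf2); unphased genotypes
  are rejected because downstream linkage statistics require phase
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad row, ...)."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide substitution with optional read-count evidence.

    ``pos`` is the 1-based position of the mutated base. ``ref_count`` and
    ``alt_count`` are the tumour reads supporting the reference and alternate
    alleles; they form the numerator/denominator of the variant allele fraction.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    ref_count: int | None = None
    alt_count: int | None = None

    def __post_init__(self) -> None:
        if self.ref_base not in _BASE_SET:
            raise ValueError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")
        if self.alt_base not in _BASE_SET:
            raise ValueError(f"alt_base must be one of A/C/G/T, got {self.alt_base!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref_count", "alt_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def coverage(self) -> int | None:
        if self.ref_count is None or self.alt_count is None:
            return None
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float | None:
        """Raw variant allele fraction alt/(ref+alt), or None without counts."""
        cov = self.coverage
        if cov is None or cov == 0:
            return None
        return self.alt_count / cov


@dataclass(frozen=True)
class CopySegment:
    """A copy-number segment: log2 ratio (``segment_mean``) and/or integer total CN."""

    sample_id: str
    chrom: str
    start: int
    end: int
    segment_mean: float | None = None
    total_cn: int | None = None

    # |log2 ratio| below this is treated as compatible with CN=2 when checking
    # the sign/CN consistency invariant
    _SIGN_TOLERANCE = 0.25

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn is not None and self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")
        if self.total_cn is not None and self.segment_mean is not None:
            sm, cn, tol = self.segment_mean, self.total_cn, self._SIGN_TOLERANCE
            if (cn < 2 and sm > tol) or (cn > 2 and sm < -tol) or (cn == 2 and abs(sm) > 1.0):
                raise ValueError(
                    f"total_cn={cn} inconsistent with segment_mean={sm:.3f}"
                )

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: tumour purity in (0, 1] and an optional population label."""

    sample_id: str
    purity: float
    population_label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")


@dataclass
class SiteCallSummary:
    """Base-call summary at one genotyping site for one sample.

    ``base_counts`` maps A/C/G/T to read counts; ``coverage`` must equal their
    sum. A summary with coverage 0 represents a site with no usable reads.
    """

    sample_id: str
    site_id: str
    base_counts: dict[str, int]
    mean_quality: float
    coverage: int

    def __post_init__(self) -> None:
        self.base_counts = {b: int(self.base_counts.get(b, 0)) for b in BASES}
        if any(v < 0 for v in self.base_counts.values()):
            raise ValueError("base counts must be non-negative")
        if self.coverage != sum(self.base_counts.values()):
            raise ValueError(
                f"coverage {self.coverage} != sum of base counts "
                f"{sum(self.base_counts.values())} at {self.site_id}"
            )
        if self.mean_quality < 0:
            raise ValueError("mean_quality must be >= 0")

    @property
    def no_coverage(self) -> bool:
        return self.coverage == 0


@dataclass
class HaplotypePanel:
    """Phased alleles for samples x SNPs, two haplotypes per sample.

    ``haplotypes`` is an int8 array of shape (2 * n_samples, n_snps) over {0, 1}
    (0 = reference allele, 1 = alternate). Rows 2i and 2i+1 are the two phased
    haplotypes of sample i.
    """

    snp_ids: list[str]
    chroms: list[str]
    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    samples: list[str]
    populations: list[str | None]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n_snps = len(self.snp_ids)
        if not (len(self.chroms) == len(self.positions) == len(self.ref_alleles)
                == len(self.alt_alleles) == n_snps):
            raise ValueError("per-SNP metadata lengths disagree")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label (or None) required per sample")
        if self.haplotypes.shape != (2 * len(self.samples), n_snps):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"2*{len(self.samples)} samples x {n_snps} SNPs"
            )
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1")
        if len(set(self.snp_ids)) != n_snps:
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        """Alleles of one SNP across all haplotypes (length 2 * n_samples)."""
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None
        return self.haplotypes[:, j]

    def haplotype_populations(self) -> list[str | None]:
        """Population label of each haplotype row (each sample repeated twice)."""
        out: list[str | None] = []
        for label in self.populations:
            out.extend([label, label])
        return out


# ---------------------------------------------------------------------------
# Mutation tables (MAF-like TSV)
# ---------------------------------------------------------------------------

#: Default dialect: TCGA MAF column names.
DEFAULT_MAF_DIALECT: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref_base": "Reference_Allele",
    "alt_base": "Tumor_Seq_Allele2",
    "ref_count": "t_ref_count",
    "alt_count": "t_alt_count",
}

_MANDATORY_FIELDS = ("sample_id", "chrom", "pos", "ref_base", "alt_base")


@dataclass
class MutationTable:
    """Validated mutation records plus a report of skipped rows."""

    records: list[MutationRecord]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def _read_tsv(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read a TSV skipping leading '#' comment lines; return (frame, first data line no)."""
    path = Path(path)
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=n_comments, dtype=str,
                     keep_default_na=False)
    # first data row is at file line n_comments + 2 (1-based, after the header)
    return df, n_comments + 2


def read_mutation_table(path: str | Path,
                        dialect: Mapping[str, str] | None = None) -> MutationTable:
    """Read a MAF-like TSV of somatic substitutions.

    Rows whose alleles are not single A/C/G/T bases (indels, '-' alleles, MNVs)
    are skipped and counted in the returned report. Missing mandatory columns
    raise :class:`FormatError`; an unparsable position raises with the offending
    file line number.
    """
    dialect = dict(DEFAULT_MAF_DIALECT, **(dialect or {}))
    df, first_line = _read_tsv(path)
    for fld in _MANDATORY_FIELDS:
        if dialect[fld] not in df.columns:
            raise FormatError(f"missing mandatory column '{dialect[fld]}' in {path}")
    have_counts = (dialect["ref_count"] in df.columns
                   and dialect["alt_count"] in df.columns)

    records: list[MutationRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = first_line + i
        # positional access: itertuples mangles MAF column names
        vals = {fld: row[df.columns.get_loc(dialect[fld])] for fld in _MANDATORY_FIELDS}
        try:
            pos = int(vals["pos"])
        except (TypeError, ValueError):
            raise FormatError(
                f"unparsable position {vals['pos']!r} at line {line_no} of {path}"
            ) from None
        ref, alt = str(vals["ref_base"]).upper(), str(vals["alt_base"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASE_SET or alt not in _BASE_SET:
            skipped.append((line_no, f"non-SNV alleles {ref!r}>{alt!r}"))
            continue
        if ref == alt:
            skipped.append((line_no, f"ref==alt ({ref})"))
            continue
        counts: dict[str, int | None] = {"ref_count": None, "alt_count": None}
        if have_counts:
            for fld in ("ref_count", "alt_count"):
                raw = row[df.columns.get_loc(dialect[fld])]
                if raw not in ("", "NA", ".", None):
                    try:
                        counts[fld] = int(float(raw))
                    except ValueError:
                        raise FormatError(
                            f"unparsable count {raw!r} at line {line_no} of {path}"
                        ) from None
        records.append(MutationRecord(
            sample_id=str(vals["sample_id"]), chrom=str(vals["chrom"]), pos=pos,
            ref_base=ref, alt_base=alt,
            ref_count=counts["ref_count"], alt_count=counts["alt_count"],
        ))
    return MutationTable(records=records, skipped=skipped)


def write_mutation_table(path: str | Path, records: Iterable[MutationRecord],
                         dialect: Mapping[str, str] | None = None,
                         metadata: Mapping[str, object] | None = None) -> None:
    dialect = dict(DEFAULT_MAF_DIALECT, **(dialect or {}))
    rows = []
    for r in records:
        rows.append({
            dialect["sample_id"]: r.sample_id,
            dialect["chrom"]: r.chrom,
            dialect["pos"]: r.pos,
            dialect["ref_base"]: r.ref_base,
            dialect["alt_base"]: r.alt_base,
            dialect["ref_count"]: "" if r.ref_count is None else r.ref_count,
            dialect["alt_count"]: "" if r.alt_count is None else r.alt_count,
        })
    df = pd.DataFrame(rows, columns=[dialect[f] for f in
                                     (*_MANDATORY_FIELDS, "ref_count", "alt_count")])
    write_table(path, df, metadata=metadata)


# ---------------------------------------------------------------------------
# SEG copy-number segments
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[CopySegment]:
    """Read a SEG file (ID, chrom, loc.start, loc.end, num.mark, seg.mean).

    Columns are taken positionally, per the SEG convention. An extra column
    named ``total_cn`` (any position) supplies integer total copy number.
    Rows with start > end and overlapping segments within a sample/chromosome
    are rejected with their file line numbers.
    """
    df, first_line = _read_tsv(path)
    if df.shape[1] < 6:
        raise FormatError(f"SEG file {path} has {df.shape[1]} columns, expected >= 6")
    cn_col = next((c for c in df.columns if c.lower() == "total_cn"), None)
    segments: list[CopySegment] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = first_line + i
        try:
            start, end = int(float(row[2])), int(float(row[3]))
        except (TypeError, ValueError):
            raise FormatError(f"unparsable coordinates at line {line_no} of {path}") from None
        mean_raw = row[5]
        mean = None if mean_raw in ("", "NA", ".") else float(mean_raw)
        cn = None
        if cn_col is not None:
            cn_raw = row[df.columns.get_loc(cn_col)]
            cn = None if cn_raw in ("", "NA", ".") else int(float(cn_raw))
        try:
            segments.append(CopySegment(
                sample_id=str(row[0]), chrom=str(row[1]), start=start, end=end,
                segment_mean=mean, total_cn=cn,
            ))
        except ValueError as exc:
            raise FormatError(f"line {line_no} of {path}: {exc}") from None
    _check_segment_overlap(segments, path)
    return segments


def _check_segment_overlap(segments: Sequence[CopySegment], path: object) -> None:
    by_key: dict[tuple[str, str], list[CopySegment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise FormatError(
                    f"overlapping segments for {sample}/{chrom} in {path}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_segments(path: str | Path, segments: Iterable[CopySegment],
                   metadata: Mapping[str, object] | None = None) -> None:
    rows = [{
        "ID": s.sample_id, "chrom": s.chrom, "loc.start": s.start,
        "loc.end": s.end, "num.mark": 0,
        "seg.mean": "" if s.segment_mean is None else s.segment_mean,
        "total_cn": "" if s.total_cn is None else s.total_cn,
    } for s in segments]
    df = pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end",
                                     "num.mark", "seg.mean", "total_cn"])
    write_table(path, df, metadata=metadata)


# ---------------------------------------------------------------------------
# Purity tables
# ---------------------------------------------------------------------------

def read_purity(path: str | Path) -> list[SampleMeta]:
    """Read a TSV with columns sample_id, purity and optional population."""
    df, first_line = _read_tsv(path)
    for col in ("sample_id", "purity"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    has_pop = "population" in df.columns
    metas: list[SampleMeta] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = first_line + i
        try:
            purity = float(row[df.columns.get_loc("purity")])
        except (TypeError, ValueError):
            raise FormatError(f"unparsable purity at line {line_no} of {path}") from None
        pop = None
        if has_pop:
            raw = row[df.columns.get_loc("population")]
            pop = None if raw in ("", "NA") else str(raw)
        try:
            metas.append(SampleMeta(
                sample_id=str(row[df.columns.get_loc("sample_id")]),
                purity=purity, population_label=pop))
        except ValueError as exc:
            raise FormatError(f"line {line_no} of {path}: {exc}") from None
    return metas


def write_purity(path: str | Path, metas: Iterable[SampleMeta],
                 metadata: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "purity": m.purity,
        "population": "" if m.population_label is None else m.population_label,
    } for m in metas], columns=["sample_id", "purity", "population"])
    write_table(path, df, metadata=metadata)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA into {name: uppercase sequence}; duplicate names are an error."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate sequence name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site-call summaries
# ---------------------------------------------------------------------------

def read_site_calls(path: str | Path) -> list[SiteCallSummary]:
    df, first_line = _read_tsv(path)
    needed = ("sample_id", "site_id", "A", "C", "G", "T", "mean_quality", "coverage")
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path}")
    out: list[SiteCallSummary] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = first_line + i
        try:
            out.append(SiteCallSummary(
                sample_id=str(row[df.columns.get_loc("sample_id")]),
                site_id=str(row[df.columns.get_loc("site_id")]),
                base_counts={b: int(row[df.columns.get_loc(b)]) for b in BASES},
                mean_quality=float(row[df.columns.get_loc("mean_quality")]),
                coverage=int(row[df.columns.get_loc("coverage")]),
            ))
        except ValueError as exc:
            raise FormatError(f"line {line_no} of {path}: {exc}") from None
    return out


def write_site_calls(path: str | Path, calls: Iterable[SiteCallSummary],
                     metadata: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame([{
        "sample_id": c.sample_id, "site_id": c.site_id,
        **{b: c.base_counts.get(b, 0) for b in BASES},
        "mean_quality": c.mean_quality, "coverage": c.coverage,
    } for c in calls], columns=["sample_id", "site_id", *BASES,
                               "mean_quality", "coverage"])
    write_table(path, df, metadata=metadata)


# ---------------------------------------------------------------------------
# Phased VCF haplotype panels
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path,
                    populations: Mapping[str, str] | None = None) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Every genotype must be phased ('|' separator) and non-missing; violations
    raise :class:`FormatError`. Multi-allelic records are split into bi-allelic
    sites (one per alternate allele) before panel construction, since pairwise
    linkage statistics are defined on bi-allelic SNPs.
    """
    from cyvcf2 import VCF  # local import: cyvcf2 opens files at construction

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts_out: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        genotypes = variant.genotypes  # [[a0, a1, phased], ...]
        alleles_a = np.empty(len(samples), dtype=np.int16)
        alleles_b = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(genotypes):
            if len(gt) < 3:
                raise FormatError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}")
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise FormatError(
                    f"missing genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}")
            if not phased:
                raise FormatError(
                    f"unphased genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}; phased haplotypes required")
            alleles_a[i], alleles_b[i] = a, b
        base_id = variant.ID if variant.ID not in (None, ".") else \
            f"{variant.CHROM}:{variant.POS}"
        for k, alt in enumerate(variant.ALT):
            col = np.empty(2 * len(samples), dtype=np.int8)
            col[0::2] = (alleles_a == k + 1)
            col[1::2] = (alleles_b == k + 1)
            snp_ids.append(base_id if len(variant.ALT) == 1 else f"{base_id}_{alt}")
            chroms.append(variant.CHROM)
            positions.append(variant.POS)
            refs.append(variant.REF)
            alts_out.append(alt)
            columns.append(col)
    haplotypes = (np.stack(columns, axis=1) if columns
                  else np.zeros((2 * len(samples), 0), dtype=np.int8))
    pops = [None if populations is None else populations.get(s) for s in samples]
    return HaplotypePanel(snp_ids=snp_ids, chroms=chroms,
                          positions=np.array(positions, dtype=np.int64),
                          ref_alleles=refs, alt_alleles=alts_out,
                          samples=samples, populations=pops,
                          haplotypes=haplotypes)


def write_phased_vcf(path: str | Path, panel: HaplotypePanel) -> None:
    """Write a panel as a minimal phased VCF 4.2 (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.chroms):
            length = int(max((p for c, p in zip(panel.chroms, panel.positions)
                              if c == chrom), default=0)) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j in range(panel.n_snps):
            gts = []
            for i in range(panel.n_samples):
                a, b = panel.haplotypes[2 * i, j], panel.haplotypes[2 * i + 1, j]
                gts.append(f"{a}|{b}")
            fh.write("\t".join([
                panel.chroms[j], str(int(panel.positions[j])), panel.snp_ids[j],
                panel.ref_alleles[j], panel.alt_alleles[j], ".", "PASS", ".", "GT",
                *gts]) + "\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, df: pd.DataFrame,
                metadata: Mapping[str, object] | None = None) -> None:
    """Write a TSV with '# key=value' comment header lines recording provenance."""
    from . import __version__

    meta = {"apobecsig_version": __version__}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (comment lines skipped)."""
    df, _ = _read_tsv(path)
    return df
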