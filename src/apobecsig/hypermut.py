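"""Amplicon mutation counting with dinucleotide-context spectra.

Sanger-scale amplicons are globally aligned to their reference (full-length,
near-identical sequences, so a Needleman-Wunsch alignment with affine gaps
replaces a read mapper), every mismatch column is tallied by substitution
type, and cytosine mutations are resolved by their 5' dinucleotide context
(TC / CC / GC / AC) — the readout that exposes APOBEC3-style deamination
biases.

Strand modes: retroviral hypermutation appears as G->A on the viral genomic
strand but as C->T on the cDNA strand where the deamination chemistry
happened. ``strand_mode="cDNA"`` reports every substitution and context on
the reverse complement of the supplied orientation, so genomic-strand G->A
events are counted as C->T with reverse-complemented context.

Columns adjacent to alignment gaps (within a configurable window, default
±1) and columns containing ambiguity codes are excluded from counting, since
both are common alignment/chemistry artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CONTEXT_KEYS = ("TC", "CC", "GC", "AC")

SUBSTITUTION_TYPES = tuple(f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0    # cost of a gap of length 1
    gap_extend: float = -1.0  # additional cost per extra gapped base


@dataclass(frozen=True)
class AlignedPair:
    """A global alignment as two equal-length gapped strings."""

    reference: str  # gapped reference row
    query: str      # gapped query row
    score: float

    def __post_init__(self) -> None:
        if len(self.reference) != len(self.query):
            raise ValueError("aligned rows must have equal length")


def align_pairwise(query: str, reference: str,
                   scores: AlignScores = AlignScores()) -> AlignedPair:
    """Needleman-Wunsch global alignment with affine gap penalties.

    Deterministic: of the co-optimal alignments the aligner's first (high-road)
    traceback is returned. End gaps are penalized like internal gaps.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    aligner.wildcard = None
    alignment = aligner.align(reference.upper(), query.upper())[0]
    return AlignedPair(reference=str(alignment[0]), query=str(alignment[1]),
                       score=float(alignment.score))


@dataclass
class AmpliconMutationReport:
    """Substitution tallies over a set of aligned amplicons.

    ``rate_per_kb`` is 1000 x (count of ``rate_type`` substitutions) /
    (aligned non-gap, non-excluded reference bases). The context spectrum
    keys mutated cytosines of the ``rate_type`` by their 5' base (TC/CC/GC/AC,
    plus ``NC`` when the 5' base is unknown at a sequence start), so its
    counts sum to the ``rate_type`` count.
    """

    n_sequences: int
    aligned_bases: int
    substitution_counts: dict[str, int]
    rate_type: str
    context_spectrum: dict[str, int]
    trinucleotide_spectrum: dict[str, int] = field(default_factory=dict)
    strand_mode: str = "as-given"

    @property
    def rate_count(self) -> int:
        return self.substitution_counts.get(self.rate_type, 0)

    @property
    def rate_per_kb(self) -> float:
        if self.aligned_bases == 0:
            return float("nan")
        return 1000.0 * self.rate_count / self.aligned_bases


def _excluded_columns(ref_row: str, qry_row: str, gap_window: int) -> set[int]:
    """Column indexes within ``gap_window`` of any gap, or with ambiguity codes."""
    n = len(ref_row)
    excluded: set[int] = set()
    for i in range(n):
        if ref_row[i] == "-" or qry_row[i] == "-":
            for j in range(max(0, i - gap_window), min(n, i + gap_window + 1)):
                excluded.add(j)
        elif ref_row[i] not in "ACGT" or qry_row[i] not in "ACGT":
            excluded.add(i)
    return excluded


def count_mutations(alignments: Iterable[AlignedPair], reference: str,
                    strand_mode: str = "as-given", gap_window: int = 1,
                    rate_type: str = "C>T") -> AmpliconMutationReport:
    """Tally substitutions across alignments against one reference.

    In ``cDNA`` mode each alignment (and the reference) is reverse-complemented
    before counting, so spectra match an as-given run on reverse-complemented
    input exactly. ``gap_window`` columns on each side of every gap are
    excluded (0 disables). Contexts are read from the reference strand being
    reported.
    """
    if strand_mode not in ("as-given", "cDNA"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if rate_type not in SUBSTITUTION_TYPES:
        raise ValueError(f"unknown substitution type {rate_type!r}")
    reference = reference.upper()
    ref_len = len(reference)
    reported_ref = _revcomp(reference) if strand_mode == "cDNA" else reference

    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    context: dict[str, int] = {k: 0 for k in CONTEXT_KEYS}
    context["NC"] = 0
    trinuc: dict[str, int] = {}
    aligned_bases = 0
    n_sequences = 0
    rate_ref, rate_alt = rate_type[0], rate_type[2]

    for pair in alignments:
        n_sequences += 1
        ref_row, qry_row = pair.reference, pair.query
        if len(ref_row.replace("-", "")) != ref_len:
            raise ValueError(
                f"alignment reference length {len(ref_row.replace('-', ''))} "
                f"does not match supplied reference length {ref_len}")
        if strand_mode == "cDNA":
            ref_row, qry_row = _revcomp(ref_row), _revcomp(qry_row)
        excluded = _excluded_columns(ref_row, qry_row, gap_window)
        ref_pos = -1  # 0-based position in reported_ref
        for i, (rb, qb) in enumerate(zip(ref_row, qry_row)):
            if rb != "-":
                ref_pos += 1
            if i in excluded or rb == "-" or qb == "-":
                continue
            aligned_bases += 1
            if rb == qb:
                continue
            counts[f"{rb}>{qb}"] += 1
            if rb == rate_ref and qb == rate_alt:
                five = reported_ref[ref_pos - 1] if ref_pos >= 1 else "N"
                key = five + rb if five in "ACGT" else "NC"
                context[key] = context.get(key, 0) + 1
                three = (reported_ref[ref_pos + 1]
                         if ref_pos + 1 < len(reported_ref) else "N")
                tri = five + rb + three
                trinuc[tri] = trinuc.get(tri, 0) + 1
    return AmpliconMutationReport(
        n_sequences=n_sequences, aligned_bases=aligned_bases,
        substitution_counts=counts, rate_type=rate_type,
        context_spectrum=context, trinucleotide_spectrum=trinuc,
        strand_mode=strand_mode)


def count_amplicon_fasta(sequences: Sequence[str], reference: str,
                         strand_mode: str = "as-given", gap_window: int = 1,
                         rate_type: str = "C>T",
                         scores: AlignScores = AlignScores(),
                         ) -> AmpliconMutationReport:
    """Align each amplicon to the reference and tally (convenience wrapper)."""
    alignments = [align_pairwise(seq, reference, scores=scores)
                  for seq in sequences]
    return count_mutations(alignments, reference, strand_mode=strand_mode,
                           gap_window=gap_window, rate_type=rate_type)
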