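"""96-channel trinucleotide mutation spectra, motif-abundance weighting and
signature-category statistics.

Every somatic substitution is reported pyrimidine-centric: mutations whose
reference base is a purine are reverse-complemented so the mutated base is
always C or T, giving 96 channels (5' base x C/T ref x 3 alternates x 3' base),
labelled COSMIC-style as e.g. ``T[C>T]A``.

Signature categories follow the common single-channel definitions: APOBEC is
C->T in TCW motifs (W = A/T; an extended mode additionally counts C->G in TCW),
smoking is C->A in any motif, and ageing is C->T in CG motifs. Because TCW
excludes a 3' G, the default categories are mutually exclusive.

Motif-abundance weighting divides each channel's count by the frequency of its
trinucleotide in the reference and renormalizes, so that mutation loads at
rare motifs (notably TCG) are not under-read.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CATEGORIES = ("APOBEC", "smoking", "ageing")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_label(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def parse_channel(label: str) -> tuple[str, str, str, str]:
    """(five, ref, alt, three) from a ``N[R>A]N`` label."""
    if (len(label) != 7 or label[1] != "[" or label[3] != ">"
            or label[5] != "]"):
        raise ValueError(f"malformed channel label {label!r}")
    return label[0], label[2], label[4], label[6]


def _build_channels() -> list[str]:
    channels = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    channels.append((ref, alt, five, three))
    # alphabetical by (ref, alt, five, three) for byte-stable outputs
    channels.sort()
    return [channel_label(f, r, a, t) for r, a, f, t in channels]


#: The 96 pyrimidine-centric channels, ordered alphabetically by
#: (ref, alt, 5', 3').
CHANNELS_96: list[str] = _build_channels()

_PYRIMIDINES = frozenset("CT")


class ReferenceMismatchError(ValueError):
    """The reference base at a mutation's position does not match the record."""


def mutation_context(reference: Mapping[str, str] | str,
                     mutation: MutationRecord) -> str:
    """The 96-channel key of one mutation, strand-collapsed to the pyrimidine.

    ``reference`` is either the sequence of the mutation's chromosome or a
    mapping of chromosome name to sequence. Positions are 1-based; the first
    and last base of a sequence have no trinucleotide context and raise.
    """
    seq = reference if isinstance(reference, str) else reference[mutation.chrom]
    pos = mutation.pos
    if pos < 2 or pos > len(seq) - 1:
        raise ValueError(
            f"position {pos} of {mutation.chrom} has no trinucleotide context "
            f"(sequence length {len(seq)})")
    found = seq[pos - 1].upper()
    if found != mutation.ref_base:
        raise ReferenceMismatchError(
            f"sample {mutation.sample_id} {mutation.chrom}:{pos}: expected "
            f"reference base {mutation.ref_base}, found {found}")
    five, ref, alt, three = (seq[pos - 2].upper(), mutation.ref_base,
                             mutation.alt_base, seq[pos].upper())
    if ref not in _PYRIMIDINES:
        five, ref, alt, three = (three.translate(_COMPLEMENT),
                                 ref.translate(_COMPLEMENT),
                                 alt.translate(_COMPLEMENT),
                                 five.translate(_COMPLEMENT))
    return channel_label(five, ref, alt, three)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass
class TrinucleotideSpectrum:
    """96-channel counts with derived proportions.

    ``proportions`` are NaN (and :attr:`defined` is False) when the spectrum
    is empty.
    """

    counts: pd.Series
    n_total: int

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(CHANNELS_96, fill_value=0).astype(int)
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")
        if self.n_total != int(self.counts.sum()):
            raise ValueError("n_total must equal the sum of channel counts")

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def proportions(self) -> pd.Series:
        if not self.defined:
            return pd.Series(np.nan, index=CHANNELS_96)
        return self.counts / self.n_total


def build_spectrum(mutations: Iterable[MutationRecord],
                   reference: Mapping[str, str] | str) -> TrinucleotideSpectrum:
    """Bin mutations by trinucleotide context into a 96-channel spectrum."""
    counts = pd.Series(0, index=CHANNELS_96, dtype=int)
    n = 0
    for mutation in mutations:
        counts[mutation_context(reference, mutation)] += 1
        n += 1
    if n == 0:
        logger.warning("empty mutation list: spectrum proportions undefined")
    return TrinucleotideSpectrum(counts=counts, n_total=n)


# ---------------------------------------------------------------------------
# Reference motif frequencies
# ---------------------------------------------------------------------------

def _pyr_key(window: str) -> str:
    return window if window[1] in _PYRIMIDINES else _revcomp(window)


@dataclass
class ReferenceMotifFrequencies:
    """Trinucleotide motif frequencies over a reference.

    ``mode`` is ``collapsed`` (windows keyed pyrimidine-centric, 32 motifs;
    matches strand-collapsed mutation channels) or ``literal`` (the supplied
    strand verbatim, 64 motifs). In both modes the denominator is the number
    of trinucleotide windows, sequence length - 2 summed over sequences, so
    frequencies sum to 1.
    """

    freqs: pd.Series
    denominator: int
    mode: str

    def __getitem__(self, motif: str) -> float:
        return float(self.freqs.get(motif, 0.0))


def reference_motif_frequencies(reference: Mapping[str, str] | str,
                                mode: str = "collapsed",
                                ) -> ReferenceMotifFrequencies:
    if mode not in ("collapsed", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    sequences = [reference] if isinstance(reference, str) else list(reference.values())
    counts: dict[str, int] = {}
    denominator = 0
    for seq in sequences:
        seq = seq.upper()
        if len(seq) < 3:
            raise ValueError("reference sequence shorter than one trinucleotide")
        denominator += len(seq) - 2
        for i in range(len(seq) - 2):
            window = seq[i:i + 3]
            key = _pyr_key(window) if mode == "collapsed" else window
            counts[key] = counts.get(key, 0) + 1
    freqs = pd.Series(counts, dtype=float).sort_index() / denominator
    return ReferenceMotifFrequencies(freqs=freqs, denominator=denominator,
                                     mode=mode)


def weighted_spectrum(spectrum: TrinucleotideSpectrum,
                      motif_freqs: ReferenceMotifFrequencies | Mapping[str, float],
                      ) -> pd.Series:
    """Motif-abundance-adjusted channel frequencies.

    Each channel's count is divided by the reference frequency of its
    trinucleotide, and the adjusted counts are renormalized to sum to 1.
    A nonzero count at a zero-frequency motif is impossible and raises.
    """
    get = (motif_freqs.__getitem__ if isinstance(motif_freqs, ReferenceMotifFrequencies)
           else lambda m: float(motif_freqs.get(m, 0.0)))
    adjusted = pd.Series(0.0, index=CHANNELS_96)
    for label, count in spectrum.counts.items():
        if count == 0:
            continue
        five, ref, _, three = parse_channel(label)
        motif = five + ref + three
        freq = get(motif)
        if freq <= 0.0:
            raise ValueError(f"nonzero count at motif {motif} with zero "
                             f"reference frequency (impossible mutation)")
        adjusted[label] = count / freq
    total = adjusted.sum()
    if total == 0:
        return pd.Series(np.nan, index=CHANNELS_96)
    return adjusted / total


# ---------------------------------------------------------------------------
# Signature categories
# ---------------------------------------------------------------------------

def classify_category(channel: str, extended_apobec: bool = False) -> str | None:
    """Map a channel to APOBEC / smoking / ageing, or None.

    Default (group-comparison) definitions: APOBEC = C->T in TCW; smoking =
    C->A anywhere; ageing = C->T in CG motifs. ``extended_apobec`` adds C->G
    in TCW to the APOBEC category (the fuller TCW accounting). Categories are
    mutually exclusive in both modes.
    """
    five, ref, alt, three = parse_channel(channel)
    if ref == "C" and alt == "A":
        return "smoking"
    in_tcw = five == "T" and three in "AT"
    if ref == "C" and alt == "T":
        if in_tcw:
            return "APOBEC"
        if three == "G":
            return "ageing"
        return None
    if extended_apobec and ref == "C" and alt == "G" and in_tcw:
        return "APOBEC"
    return None


@dataclass(frozen=True)
class CategoryProportion:
    """One patient-by-timing-class cell of a signature category."""

    sample_id: str
    timing_class: str
    category: str
    proportion: float
    n_category: int
    n_mutations: int  # total mutations in the patient-timing cell


def per_patient_category_proportions(
        mutations: Sequence[MutationRecord],
        reference: Mapping[str, str] | str,
        timing_classes: Sequence[str] | None = None,
        min_count: int = 4,
        extended_apobec: bool = False,
        ) -> tuple[list[CategoryProportion], list[tuple[str, str, int]]]:
    """Per patient, per timing class: the proportion of each signature category.

    ``timing_classes`` is parallel to ``mutations`` (one class label each);
    when None a single "all" class is used. The proportion denominator is the
    total mutation count of the patient-timing cell; cells with fewer than
    ``min_count`` mutations are excluded and returned in the second element
    as (sample, timing class, n) tuples.
    """
    if timing_classes is None:
        timing_classes = ["all"] * len(mutations)
    if len(timing_classes) != len(mutations):
        raise ValueError("one timing class required per mutation")
    cells: dict[tuple[str, str], dict[str, int]] = {}
    totals: dict[tuple[str, str], int] = {}
    for mutation, cls in zip(mutations, timing_classes):
        key = (mutation.sample_id, cls)
        totals[key] = totals.get(key, 0) + 1
        category = classify_category(mutation_context(reference, mutation),
                                     extended_apobec=extended_apobec)
        if category is not None:
            cell = cells.setdefault(key, {})
            cell[category] = cell.get(category, 0) + 1
    proportions: list[CategoryProportion] = []
    excluded: list[tuple[str, str, int]] = []
    for key in sorted(totals):
        sample, cls = key
        total = totals[key]
        if total < min_count:
            excluded.append((sample, cls, total))
            logger.info("excluding %s/%s with %d < %d mutations",
                        sample, cls, total, min_count)
            continue
        for category in CATEGORIES:
            n_cat = cells.get(key, {}).get(category, 0)
            proportions.append(CategoryProportion(
                sample_id=sample, timing_class=cls, category=category,
                proportion=n_cat / total, n_category=n_cat, n_mutations=total))
    return proportions, excluded


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Welch's unequal-variance t-test between two groups of proportions."""

    t: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int


def compare_groups(group_a: Sequence[float],
                   group_b: Sequence[float]) -> GroupComparison:
    """Welch two-tailed t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("insufficient group size (need >= 2 values per group)")

    def sem(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / math.sqrt(len(v)))

    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: Welch statistic is 0/0; identical constants differ by 0
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(t=t, p=p, mean_a=float(a.mean()), mean_b=float(b.mean()),
                           sem_a=sem(a), sem_b=sem(b), n_a=len(a), n_b=len(b))


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p: float
    continuity: bool  # odds ratio used a 0.5 correction for a zero cell


def fisher_enrichment(table: Sequence[Sequence[int]]) -> FisherResult:
    """Fisher's exact test on a 2x2 table, two-sided.

    The two-sided P is the exact hypergeometric sum of all tables (with the
    observed margins) whose probability does not exceed the observed table's.
    The odds ratio is ad/bc, with a 0.5 continuity correction (flagged) when
    any cell is zero.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("cells must be non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has an all-zero margin")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    (a, b), (c, d) = arr
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        continuity = True
    else:
        odds = (a * d) / (b * c)
        continuity = False
    return FisherResult(odds_ratio=float(odds), p=float(p), continuity=continuity)
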