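"""Trinucleotide spectra, motif weighting, categories, group statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobecsig import signatures as sg
from apobecsig import simulate as sim
from apobecsig.io import MutationRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def mut(pos, ref, alt, sample="S1", chrom="chr1"):
    return MutationRecord(sample_id=sample, chrom=chrom, pos=pos,
                          ref_base=ref, alt_base=alt)


class TestMutationContext:
    def test_pyrimidine_read_off(self):
        assert sg.mutation_context("ATCAG", mut(3, "C", "T")) == "T[C>T]A"

    def test_purine_strand_collapse(self):
        assert sg.mutation_context("CTGAT", mut(3, "G", "A")) == "T[C>T]A"

    def test_first_position_has_no_context(self):
        with pytest.raises(ValueError, match="context"):
            sg.mutation_context("ATCAG", mut(1, "A", "C"))

    def test_reference_mismatch_names_sample_and_position(self):
        with pytest.raises(sg.ReferenceMismatchError, match="S1.*:3"):
            sg.mutation_context("AAAAA", mut(3, "C", "T"))

    def test_strand_collapse_involution(self, rng):
        """The mirrored mutation on the reverse complement hits the same channel."""
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=21))
            pos = int(rng.integers(2, 21))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rc_seq = seq.translate(_COMPLEMENT)[::-1]
            rc_pos = len(seq) + 1 - pos
            assert sg.mutation_context(seq, mut(pos, ref, alt)) == \
                sg.mutation_context(rc_seq, mut(rc_pos,
                                                ref.translate(_COMPLEMENT),
                                                alt.translate(_COMPLEMENT)))


class TestSpectrum:
    def test_four_distinct_channels(self):
        ref = "ATCAGTCGAA"
        muts = [mut(3, "C", "T"), mut(4, "A", "C"), mut(7, "C", "G"),
                mut(8, "G", "T")]
        spec = sg.build_spectrum(muts, ref)
        assert spec.n_total == 4
        assert (spec.proportions[spec.counts > 0] == 0.25).all()

    def test_duplicate_increments_channel(self):
        ref = "ATCAG"
        one = sg.build_spectrum([mut(3, "C", "T")], ref)
        two = sg.build_spectrum([mut(3, "C", "T")] * 2, ref)
        assert two.counts["T[C>T]A"] == one.counts["T[C>T]A"] + 1

    def test_empty_spectrum_flagged(self):
        spec = sg.build_spectrum([], "ACGT")
        assert not spec.defined and spec.proportions.isna().all()

    def test_pure_apobec_cohort_hits_tcw_channels_only(self, reference_10k):
        weights = {cls: {"APOBEC": 1.0, "smoking": 0.0, "ageing": 0.0,
                         "other": 0.0} for cls in sim.TIMING_CLASSES}
        config = sim.CohortConfig(n_patients=3, mean_mutations=80,
                                  reference_length=10_000,
                                  signature_weights=weights, rng_seed=31)
        mutations, *_ = sim.simulate_cohort(config, reference_10k)
        spec = sg.build_spectrum(mutations, reference_10k)
        allowed = {f"T[C>{alt}]{three}" for alt in "TG" for three in "AT"}
        nonzero = set(spec.counts[spec.counts > 0].index)
        assert nonzero <= allowed

    def test_proportions_sum_to_one(self, small_cohort, reference_10k):
        _, mutations, *_ = small_cohort
        spec = sg.build_spectrum(mutations, reference_10k)
        assert spec.proportions.sum() == pytest.approx(1.0, abs=1e-9)


class TestMotifFrequencies:
    def test_enumeration_literal(self):
        freqs = sg.reference_motif_frequencies("ATCAGT", mode="literal")
        assert freqs.denominator == 4
        for motif in ("ATC", "TCA", "CAG", "AGT"):
            assert freqs[motif] == pytest.approx(0.25)

    def test_homopolymer(self):
        assert sg.reference_motif_frequencies("AAAA", mode="literal")["AAA"] \
            == pytest.approx(1.0)

    def test_collapsed_mode_uses_pyrimidine_keys(self):
        freqs = sg.reference_motif_frequencies("ATCAGT", mode="collapsed")
        # AGT (purine-centred) collapses to ACT
        assert freqs["ACT"] == pytest.approx(0.25)
        assert freqs["AGT"] == 0.0

    def test_normalization_on_random_sequence(self, reference_10k):
        for mode in ("collapsed", "literal"):
            freqs = sg.reference_motif_frequencies(reference_10k, mode=mode)
            assert freqs.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert sg.reference_motif_frequencies(reference_10k).denominator \
            == len(reference_10k) - 2

    def test_too_short(self):
        with pytest.raises(ValueError):
            sg.reference_motif_frequencies("AC")


def _spectrum_from_counts(counts: dict) -> sg.TrinucleotideSpectrum:
    return sg.TrinucleotideSpectrum(counts=pd.Series(counts),
                                    n_total=sum(counts.values()))


class TestWeightedSpectrum:
    def test_hand_computed_toy(self):
        spec = _spectrum_from_counts({"T[C>T]A": 2, "A[C>T]A": 2})
        weighted = sg.weighted_spectrum(spec, {"TCA": 0.1, "ACA": 0.4})
        assert weighted["T[C>T]A"] == pytest.approx(0.8)
        assert weighted["A[C>T]A"] == pytest.approx(0.2)

    def test_uniform_frequencies_change_nothing(self):
        spec = _spectrum_from_counts({"T[C>T]A": 3, "A[C>G]C": 1,
                                      "G[T>A]T": 4})
        uniform = {f + r + t: 1 / 32 for f in "ACGT" for r in "CT"
                   for t in "ACGT"}
        weighted = sg.weighted_spectrum(spec, uniform)
        pd.testing.assert_series_equal(weighted, spec.proportions,
                                       check_names=False)

    def test_single_channel_is_one(self):
        spec = _spectrum_from_counts({"T[C>G]T": 5})
        assert sg.weighted_spectrum(spec, {"TCT": 0.003})["T[C>G]T"] \
            == pytest.approx(1.0)

    def test_zero_frequency_motif_is_impossible(self):
        spec = _spectrum_from_counts({"T[C>T]A": 1})
        with pytest.raises(ValueError, match="impossible"):
            sg.weighted_spectrum(spec, {"TCA": 0.0})

    def test_rare_motif_upweighted_five_fold(self):
        # TCG five times rarer than TCA with equal counts -> weighted 5:1
        spec = _spectrum_from_counts({"T[C>T]G": 10, "T[C>T]A": 10})
        weighted = sg.weighted_spectrum(spec, {"TCG": 0.02, "TCA": 0.10})
        assert weighted["T[C>T]G"] / weighted["T[C>T]A"] == pytest.approx(5.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.dictionaries(st.sampled_from(sg.CHANNELS_96),
                           st.integers(1, 50), min_size=1))
    def test_weighted_sums_to_one(self, counts):
        spec = _spectrum_from_counts(counts)
        freqs = {f + r + t: 1 / 32 for f in "ACGT" for r in "CT"
                 for t in "ACGT"}
        assert sg.weighted_spectrum(spec, freqs).sum() \
            == pytest.approx(1.0, abs=1e-9)


class TestCategories:
    @pytest.mark.parametrize("channel,category", [
        ("T[C>T]A", "APOBEC"), ("T[C>T]T", "APOBEC"),
        ("C[C>A]G", "smoking"), ("T[C>A]A", "smoking"),
        ("A[C>T]G", "ageing"), ("T[C>T]G", "ageing"),
        ("T[C>G]A", None), ("A[C>T]C", None), ("G[T>A]C", None),
    ])
    def test_default_definitions(self, channel, category):
        assert sg.classify_category(channel) == category

    def test_extended_mode_adds_cg_transversions_in_tcw(self):
        assert sg.classify_category("T[C>G]A", extended_apobec=True) == "APOBEC"
        assert sg.classify_category("T[C>G]G", extended_apobec=True) is None

    @pytest.mark.parametrize("extended", [False, True])
    def test_categories_mutually_exclusive(self, extended):
        for channel in sg.CHANNELS_96:
            category = sg.classify_category(channel, extended_apobec=extended)
            assert category in (None, "APOBEC", "smoking", "ageing")
            if category == "APOBEC":
                five, _, _, three = sg.parse_channel(channel)
                assert five == "T" and three in "AT"


class TestPerPatientProportions:
    REF = "ATCAGTCGAACCGATTCAAT"

    def _muts(self, n, sample="S1"):
        # all at pos 3 would be duplicates; positions of C[C>x]: use pos 3 TCA
        return [mut(3, "C", "T", sample=sample) for _ in range(n)]

    def test_three_mutations_excluded_four_retained(self):
        props3, excluded3 = sg.per_patient_category_proportions(
            self._muts(3), self.REF)
        assert props3 == [] and excluded3 == [("S1", "all", 3)]
        props4, excluded4 = sg.per_patient_category_proportions(
            self._muts(4), self.REF)
        assert excluded4 == [] and len(props4) == len(sg.CATEGORIES)

    def test_proportion_counting(self):
        # 10 clonal mutations, 4 of them APOBEC (T[C>T]A at pos 3)
        muts = ([mut(3, "C", "T")] * 4      # T[C>T]A: APOBEC
                + [mut(11, "C", "A")] * 3   # A[C>A]C: smoking (any motif)
                + [mut(7, "C", "T")] * 3)   # T[C>T]G: ageing
        props, _ = sg.per_patient_category_proportions(
            muts, self.REF, timing_classes=["clonal"] * 10)
        by_cat = {p.category: p for p in props}
        assert by_cat["APOBEC"].proportion == pytest.approx(0.4)
        assert by_cat["APOBEC"].n_mutations == 10
        assert by_cat["smoking"].proportion == pytest.approx(0.3)

    def test_cells_are_per_patient_per_class(self):
        muts = self._muts(4, "A") + self._muts(4, "B")
        classes = ["early"] * 4 + ["late"] * 4
        props, excluded = sg.per_patient_category_proportions(
            muts, self.REF, timing_classes=classes)
        cells = {(p.sample_id, p.timing_class) for p in props}
        assert cells == {("A", "early"), ("B", "late")}


class TestCompareGroups:
    def test_identical_groups(self):
        res = sg.compare_groups([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_planted_difference_detected(self, rng):
        a = rng.normal(0.3, 0.05, size=20)
        b = rng.normal(0.1, 0.05, size=20)
        assert sg.compare_groups(a, b).p < 0.001

    def test_insufficient_group_size(self):
        with pytest.raises(ValueError, match="insufficient"):
            sg.compare_groups([0.1], [0.2, 0.3])

    def test_type_i_error_calibration(self, rng):
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.0, 1.0, size=15)
            b = rng.normal(0.0, 1.0, size=15)
            if sg.compare_groups(a, b).p < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestFisher:
    def test_extreme_table_exact_value(self):
        # all-or-none 10/10 table: 2 of C(20,10) equally extreme tables
        res = sg.fisher_enrichment([[10, 0], [0, 10]])
        assert res.p == pytest.approx(2 / 184_756)
        assert res.continuity

    def test_balanced_table_is_one(self):
        res = sg.fisher_enrichment([[5, 5], [5, 5]])
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0) and not res.continuity

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            sg.fisher_enrichment([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            sg.fisher_enrichment([[1.5, 2], [3, 4]])
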