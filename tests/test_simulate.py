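"""Generator correctness: determinism, planted constraints, binomial bounds."""
import math

import numpy as np
import pytest
from scipy import stats

from apobecsig import linkage
from apobecsig import simulate as sim
from apobecsig.signatures import mutation_context, parse_channel


class TestReference:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_reference(2)

    def test_length_three_is_one_window(self):
        seq = sim.simulate_reference(3, rng_seed=0)
        assert len(seq) == 3 and set(seq) <= set("ACGT")

    def test_pure_gc_mixture(self):
        assert set(sim.simulate_reference(500, gc_fraction=1.0,
                                          rng_seed=1)) <= {"G", "C"}

    def test_gc_within_three_binomial_sd(self):
        n = 100_000
        seq = sim.simulate_reference(n, gc_fraction=0.5, rng_seed=2)
        gc = sum(seq.count(b) for b in "GC")
        assert abs(gc - 0.5 * n) <= 3 * math.sqrt(n * 0.25)

    def test_seed_determinism(self):
        assert sim.simulate_reference(1000, rng_seed=9) \
            == sim.simulate_reference(1000, rng_seed=9)


class TestCohort:
    def test_pure_ageing_mixture_lands_in_ncg(self, reference_10k):
        weights = {cls: {"APOBEC": 0.0, "smoking": 0.0, "ageing": 1.0,
                         "other": 0.0} for cls in sim.TIMING_CLASSES}
        config = sim.CohortConfig(n_patients=3, mean_mutations=40,
                                  reference_length=10_000,
                                  signature_weights=weights, rng_seed=5)
        mutations, *_ = sim.simulate_cohort(config, reference_10k)
        assert mutations
        for m in mutations:
            _, ref, _, three = parse_channel(
                mutation_context(reference_10k, m))
            assert ref == "C" and three == "G"

    def test_expected_af_algebra(self, reference_10k):
        # purity 1, CN 2, multiplicity 1: mean VAF must sit at 0.5
        config = sim.CohortConfig(
            n_patients=2, mean_mutations=150, reference_length=10_000,
            timing_fractions={"early_clonal": 0.0, "late_clonal": 1.0,
                              "subclonal": 0.0},
            purity_range=(1.0, 1.0), depth=10_000, amplified_fraction=0.0,
            rng_seed=6)
        mutations, _, _, truth = sim.simulate_cohort(config, reference_10k)
        vafs = np.array([m.vaf for m in mutations])
        # per-mutation sd ~ sqrt(0.25/depth); mean over n mutations
        tol = 3 * math.sqrt(0.25 / 10_000 / len(vafs))
        assert abs(vafs.mean() - 0.5) <= tol
        assert all(t.multiplicity == 1 and t.cancer_cell_fraction == 1.0
                   for t in truth)

    def test_truth_labels_parallel_and_mixture_recovered(self, reference_10k):
        config = sim.CohortConfig(n_patients=20, mean_mutations=500,
                                  reference_length=10_000, rng_seed=7)
        mutations, _, _, truth = sim.simulate_cohort(config, reference_10k)
        assert len(mutations) == len(truth)
        counts = {p: sum(t.process == p for t in truth) for p in sim.PROCESSES}
        n = len(truth)
        expected = [config.signature_weights["late_clonal"][p] * n
                    for p in sim.PROCESSES]
        chi = stats.chisquare([counts[p] for p in sim.PROCESSES], expected)
        assert chi.pvalue > 0.001

    def test_same_seed_identical_outputs(self, reference_10k):
        config = sim.CohortConfig(n_patients=4, mean_mutations=30,
                                  reference_length=10_000, rng_seed=8)
        out1 = sim.simulate_cohort(config, reference_10k)
        out2 = sim.simulate_cohort(config, reference_10k)
        assert out1 == out2

    def test_no_tcw_reference_is_an_error(self):
        with pytest.raises(ValueError, match="TCW"):
            sim.simulate_cohort(
                sim.CohortConfig(n_patients=2, mean_mutations=5,
                                 reference_length=60, rng_seed=0), "A" * 60)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.CohortConfig(signature_weights={
                cls: {"APOBEC": 0.5, "smoking": 0.5, "ageing": 0.5,
                      "other": 0.0} for cls in sim.TIMING_CLASSES})


class TestHaplotypePanel:
    def test_perfect_block_fully_correlated(self):
        panel = sim.simulate_haplotype_panel(
            200, [sim.BlockSpec(n_snps=4, target_r2=1.0)], rng_seed=10)
        for j in range(1, 4):
            res = linkage.r_squared(panel.column("blk0_snp0"),
                                    panel.column(f"blk0_snp{j}"))
            assert res.r2 == pytest.approx(1.0)

    def test_cross_block_independence(self):
        panel = sim.simulate_haplotype_panel(
            800, [sim.BlockSpec(n_snps=3, target_r2=0.9),
                  sim.BlockSpec(n_snps=3, target_r2=0.9)], rng_seed=11)
        values = [linkage.r_squared(panel.column(f"blk0_snp{i}"),
                                    panel.column(f"blk1_snp{j}")).r2
                  for i in range(3) for j in range(3)]
        assert np.mean(values) < 0.01

    def test_population_frequencies_recovered(self):
        labels = ["AFR"] * 400 + ["EAS"] * 400
        panel = sim.simulate_haplotype_panel(
            800, [sim.BlockSpec(n_snps=1, target_r2=1.0,
                                alt_freq={"AFR": 0.1, "EAS": 0.7})],
            population_labels=labels, rng_seed=12)
        col = panel.column("blk0_snp0")
        for label, p in (("AFR", 0.1), ("EAS", 0.7)):
            mask = np.array([pop == label
                             for pop in panel.haplotype_populations()])
            n = mask.sum()
            freq = col[mask].mean()
            assert abs(freq - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            sim.simulate_haplotype_panel(1, [sim.BlockSpec(1, 0.5)])


class TestSiteCalls:
    def test_error_free_homozygote_is_pure(self):
        calls = sim.simulate_site_calls(("I", "I"), depth=30, error_rate=0.0,
                                        rng_seed=13)
        by_site = {c.site_id: c for c in calls}
        assert by_site["site105"].base_counts["G"] == 30
        assert all(c.coverage == 30 for c in calls)

    def test_counts_sum_to_depth(self):
        for depth in (1, 17, 50):
            calls = sim.simulate_site_calls(("I", "II"), depth=depth,
                                            error_rate=0.1, rng_seed=14)
            assert all(sum(c.base_counts.values()) == depth for c in calls)

    def test_zero_depth_flagged_no_coverage(self):
        calls = sim.simulate_site_calls(("II", "II"), depth=0, error_rate=0.0)
        assert calls and all(c.no_coverage for c in calls)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            sim.simulate_site_calls(("I", "I"), depth=10, error_rate=0.3)


class TestAmplicons:
    def test_zero_rates_identity(self):
        ref = sim.simulate_reference(300, 0.6, rng_seed=15)
        out = sim.simulate_amplicons(ref, {}, n_sequences=5, rng_seed=16)
        assert all(s == ref for s in out.sequences)
        assert out.total_planted == 0

    def test_tc_rate_within_three_binomial_sd(self):
        ref = sim.simulate_reference(5000, 0.5, rng_seed=17)
        n_tc = sum(1 for i in range(1, len(ref))
                   if ref[i] == "C" and ref[i - 1] == "T")
        out = sim.simulate_amplicons(ref, {"TC": 0.01}, n_sequences=20,
                                     rng_seed=18)
        trials = 20 * n_tc
        expect = trials * 0.01
        assert abs(out.truth_per_context["TC"] - expect) \
            <= 3 * math.sqrt(trials * 0.01 * 0.99)
        assert out.truth_per_context["CC"] == 0

    def test_truth_counts_match_sequences(self):
        ref = sim.simulate_reference(400, 0.5, rng_seed=19)
        out = sim.simulate_amplicons(ref, {"TC": 0.05, "CC": 0.02},
                                     n_sequences=8, rng_seed=20)
        observed = sum(sum(1 for a, b in zip(ref, s) if a != b)
                       for s in out.sequences)
        assert observed == out.total_planted == sum(out.truth_per_sequence)

    def test_unknown_context_key_rejected(self):
        with pytest.raises(ValueError, match="context"):
            sim.simulate_amplicons("ACGT", {"TT": 0.1}, 1)


def test_study_bundle_is_consistent():
    config = sim.CohortConfig(n_patients=8, mean_mutations=20,
                              reference_length=8000, rng_seed=22)
    bundle = sim.simulate_study(config)
    samples = {m.sample_id for m in bundle.purity}
    assert set(bundle.carriers) == samples == set(bundle.diplotypes)
    assert sum(bundle.carriers.values()) == 4
    assert len(bundle.mutations) == len(bundle.truth)
    # carriers were planted with at least one haplotype-I copy
    for sample, (h1, h2) in bundle.diplotypes.items():
        assert bundle.carriers[sample] == ("I" in (h1, h2))
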