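"""Generator contracts: genome tiling, expected-ratio model, count noise,
allele-count series, fragment lengths and design expansion."""

import numpy as np
import pytest

import ctdna_stability as cs
from ctdna_stability.synthetic import HG19_AUTOSOMES, hard_length_weight


class TestMakeGenome:
    def test_exact_division_gives_exact_bin_count(self):
        g = cs.make_genome(100_000, {"1": 1_000_000})
        assert g.n_bins == 10
        _, start, end = g.bins()
        assert np.all(end - start == 100_000)

    def test_partial_last_bin_truncated(self):
        g = cs.make_genome(100_000, {"1": 1_050_000})
        assert g.n_bins == 11
        _, _, end = g.bins()
        assert end[-1] == 1_050_000
        _, start, _ = g.bins()
        assert (end - start)[-1] == 50_000

    def test_default_autosome_bin_count_matches_arithmetic(self):
        # independent oracle: ceiling sum over the stored length table
        expected = sum((length + 99_999) // 100_000
                       for length in HG19_AUTOSOMES.values())
        assert cs.make_genome(100_000).n_bins == expected

    @pytest.mark.parametrize("bad", [0, 999, -5])
    def test_small_bin_size_rejected(self, bad):
        with pytest.raises(ValueError):
            cs.make_genome(bad, {"1": 1_000_000})

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            cs.make_genome(100_000, {})


class TestExpectedBinRatio:
    def test_no_tumour_signal_is_flat(self, genome100k):
        truth = cs.onk6_truth(tumour_fraction=0.0)
        assert np.allclose(cs.expected_bin_ratio(truth, genome100k), 1.0)

    def test_uniform_gain_normalises_away(self):
        # c=4 everywhere at t=1: median rescale removes the global shift
        g = cs.make_genome(100_000, {"1": 1_000_000})
        seg = cs.SegmentSet(["1"], [0], [1_000_000], copy_number=[4])
        truth = cs.CnaTruth(seg, tumour_fraction=1.0)
        assert np.allclose(cs.expected_bin_ratio(truth, g), 1.0)

    def test_single_segment_matches_brute_force_oracle(self):
        g = cs.make_genome(100_000, {"1": 2_000_000})
        seg = cs.SegmentSet(["1"], [0], [300_000], copy_number=[3])
        truth = cs.CnaTruth(seg, tumour_fraction=0.5)
        # oracle: build the raw vector bin by bin and rescale by its median
        raw = np.array([(0.5 * (3 if s < 300_000 else 2) + 0.5 * 2) / 2
                        for s in range(0, 2_000_000, 100_000)])
        oracle = raw / np.median(raw)
        assert oracle[0] == 1.25  # pre-rescale value survives (median is 1)
        assert np.allclose(cs.expected_bin_ratio(truth, g), oracle)

    def test_median_is_exactly_one(self, onk6_ratio):
        assert np.median(onk6_ratio) == 1.0

    @pytest.mark.parametrize("copy_number,increasing", [(3, True), (1, False)])
    def test_monotone_in_tumour_fraction(self, genome100k, copy_number,
                                         increasing):
        seg = cs.SegmentSet(["8"], [0], [10_000_000],
                            copy_number=[copy_number])
        chrom, start, _ = genome100k.bins()
        idx = int(np.flatnonzero((chrom == "8") & (start == 0))[0])
        vals = []
        for t in (0.1, 0.3, 0.5, 0.8):
            truth = cs.CnaTruth(seg, tumour_fraction=t)
            r = cs.expected_bin_ratio(truth, genome100k)
            vals.append(r[idx])
        diffs = np.diff(vals)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)


class TestSimulateBinCounts:
    def test_total_matches_request_in_expectation(self, small_genome):
        ratio = np.ones(small_genome.n_bins)
        total = 1e5
        sums = [cs.simulate_bin_counts(small_genome, ratio, total, 0.02,
                                       seed).count.sum()
                for seed in range(120)]
        se = np.std(sums, ddof=1) / np.sqrt(len(sums))
        assert abs(np.mean(sums) - total) < 3 * se + 1e-9

    def test_flat_ratios_huge_depth_converge(self, small_genome):
        ratio = np.ones(small_genome.n_bins)
        prof = cs.simulate_bin_counts(small_genome, ratio, 1e8,
                                      dispersion=0.0, seed=7)
        mean = 1e8 / small_genome.n_bins
        assert np.all(np.abs(prof.count / mean - 1) < 0.01)

    def test_seeded_determinism(self, small_genome, onk6_ratio):
        ratio = np.linspace(0.5, 1.5, small_genome.n_bins)
        a = cs.simulate_bin_counts(small_genome, ratio, 1e5, 0.02, seed=42)
        b = cs.simulate_bin_counts(small_genome, ratio, 1e5, 0.02, seed=42)
        assert np.array_equal(a.count, b.count)

    def test_all_zero_ratio_rejected(self, small_genome):
        with pytest.raises(ValueError, match="zero"):
            cs.simulate_bin_counts(small_genome,
                                   np.zeros(small_genome.n_bins), 1e5, 0.02, 1)

    def test_negative_depth_rejected(self, small_genome):
        with pytest.raises(ValueError):
            cs.simulate_bin_counts(small_genome,
                                   np.ones(small_genome.n_bins), -1, 0.02, 1)


class TestSimulateWbcCounts:
    def test_normalised_median_is_one(self, small_genome):
        prof = cs.normalize(cs.simulate_wbc_counts(small_genome, 1e6, 0.02, 3))
        assert np.median(prof.ratio) == 1.0

    def test_no_false_cna_calls_at_high_depth(self, genome100k, onk6):
        # null WBC profiles: truth segments should classify NEUTRAL
        segments = onk6.segments
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            prof = cs.process_profile(
                cs.simulate_wbc_counts(genome100k, 1e7, 0.02, seed))
            seg = cs.classify_segments(cs.segment_medians(prof, segments))
            clean += bool(np.all(seg.seg_class == "NEUTRAL"))
        assert clean >= 0.95 * n_seeds


class TestSimulateAfSeries:
    def test_mean_af_matches_binomial_moments(self):
        mut = cs.MutationTruth([("8", 1, "C", "T", 0.2)], coverage=617)
        afs = []
        for seed in range(200):
            df = cs.simulate_af_series(mut, [0.0], decay_per_hour=0.0,
                                       seed=seed)
            afs.append(df["NBR_VARIANT_READS"].iloc[0]
                       / df["TOT_COUNT"].iloc[0])
        se = np.sqrt(0.2 * 0.8 / 617 / len(afs))
        assert abs(np.mean(afs) - 0.2) < 3 * se

    def test_zero_af_zero_error_gives_no_variant_reads(self):
        mut = cs.MutationTruth([("8", 1, "C", "T", 0.0)], coverage=500)
        df = cs.simulate_af_series(mut, [0, 24], error_rate=0.0, seed=1)
        assert (df["NBR_VARIANT_READS"] == 0).all()
        assert (df["NBR_BACKGROUND_READS"] == 0).all()
        assert (df["NBR_REF_READS"] == 500).all()

    def test_decay_halves_af_after_one_hour(self):
        mut = cs.MutationTruth([("8", 1, "C", "T", 0.4)], coverage=1000)
        afs = []
        for seed in range(200):
            df = cs.simulate_af_series(mut, [1.0], decay_per_hour=0.5,
                                       seed=seed)
            afs.append(df["NBR_VARIANT_READS"].iloc[0] / 1000)
        se = np.sqrt(0.2 * 0.8 / 1000 / len(afs))
        assert abs(np.mean(afs) - 0.2) < 3 * se

    def test_count_identity_and_empty_timepoints(self):
        mut = cs.MutationTruth([("8", 1, "C", "T", 0.2)], coverage=617)
        df = cs.simulate_af_series(mut, [0, 2, 4, 24], seed=5)
        total = (df["NBR_REF_READS"] + df["NBR_VARIANT_READS"]
                 + df["NBR_BACKGROUND_READS"])
        assert (total == df["TOT_COUNT"]).all()
        with pytest.raises(ValueError):
            cs.simulate_af_series(mut, [], seed=5)

    def test_duplicate_loci_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cs.MutationTruth([("8", 1, "C", "T", 0.2),
                              ("8", 1, "C", "G", 0.1)])


class TestFragmentLengths:
    def test_pure_cfdna_is_nucleosomal(self):
        model = cs.FragmentModel(contaminant_mass=0.0)
        lengths = cs.simulate_fragment_lengths(model, 5000, seed=1)
        assert np.all(lengths < 350)
        assert abs(np.mean(lengths) - 167) < 1.0

    def test_hard_weight_suppresses_long_fragments(self):
        model = cs.FragmentModel(contaminant_mass=0.3)
        observed = cs.simulate_fragment_lengths(
            model, 10_000, apply_observation_weight=True, seed=2)
        assert np.mean(observed > 350) == 0.0

    def test_unweighted_mixture_mass_matches_closed_form(self):
        from scipy import stats as sps
        model = cs.FragmentModel(contaminant_mass=0.3)
        raw = cs.simulate_fragment_lengths(model, 20_000, seed=3)
        # closed-form mass above 350 bp
        expected = 0.3 * sps.norm.sf(350, 2000, 500) \
            + 0.7 * sps.norm.sf(350, 167, 10)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(np.mean(raw > 350) - expected) < 3 * se

    def test_determinism_and_bad_model(self):
        model = cs.FragmentModel(contaminant_mass=0.2)
        a = cs.simulate_fragment_lengths(model, 100, seed=9)
        b = cs.simulate_fragment_lengths(model, 100, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            cs.FragmentModel(cfdna_sd=0.0)
        with pytest.raises(ValueError):
            cs.simulate_fragment_lengths(model, 0, seed=1)

    def test_weight_monotone_non_increasing(self):
        w = hard_length_weight(350)
        lengths = np.array([100.0, 349.9, 350.0, 350.1, 2000.0])
        vals = w(lengths)
        assert np.all(np.diff(vals) <= 0)


class TestExpandDesign:
    def test_main_design_yields_sixty_samples(self):
        df = cs.expand_design(5, [("EDTA", "RT"), ("EDTA", "COLD"),
                                  ("STRECK", "RT")], 4)
        assert len(df) == 60
        assert list(df.columns) == ["ID", "TUBE", "STORAGE", "TIMEPOINT"]
        assert not df.duplicated().any()

    def test_minimal_design(self):
        assert len(cs.expand_design(1, [("EDTA", "RT")], 1)) == 1

    def test_followup_design_is_twelve_rows(self):
        df = cs.expand_design(3, [("EDTA", "RT"), ("EDTA", "COLD")],
                              [0.0, 48.0])
        assert len(df) == 12
        assert set(df["TIMEPOINT"]) == {0.0, 48.0}

    def test_bad_vocabulary_rejected(self):
        with pytest.raises(ValueError, match="tube"):
            cs.expand_design(1, [("PAXGENE", "RT")], 1)
        with pytest.raises(ValueError, match="storage"):
            cs.expand_design(1, [("EDTA", "WARM")], 1)
        with pytest.raises(ValueError):
            cs.expand_design(1, [], 1)


class TestTumourFractionInversion:
    def test_recovers_t_from_expectation_profile(self, genome100k, onk6):
        ratio = cs.expected_bin_ratio(onk6, genome100k)
        chrom, start, end = genome100k.bins()
        prof = cs.process_profile(
            cs.BinProfile(chrom, start, end, ratio * 1000.0))
        seg = cs.segment_medians(prof, onk6.segments)
        t_hat = cs.estimate_tumour_fraction(seg)
        assert abs(t_hat - 0.5) < 1e-6

    def test_requires_non_neutral_segment(self):
        seg = cs.SegmentSet(["1"], [0], [100], copy_number=[2],
                            median_log2=[0.0])
        with pytest.raises(ValueError):
            cs.estimate_tumour_fraction(seg)
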