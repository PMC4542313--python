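import math

import numpy as np
import pytest

from archseq import (
    CallingConfig,
    CloneSpec,
    ErrorModel,
    SimSampleSpec,
    call_hotspot,
    call_sample,
    estimate_error_rate,
    fp_probability,
    npm1_mutation_a_vaf,
    simulate_npm1_reads,
    simulate_reads,
    vaf_to_cell_fraction,
)
from archseq.counting import SiteCounts, pileup_counts

CONTIG = "JAK2_V617"


def _codon_counts(variants=(0, 0, 0), depth=1000, ref="GTC", alt="T"):
    counts = []
    for i, (r, v) in enumerate(zip(ref, variants)):
        nucs = {"A": 0, "C": 0, "G": 0, "T": 0}
        nucs[ref[i]] = depth - v
        alt_base = alt if alt != ref[i] else "A"
        nucs[alt_base] += v
        counts.append(SiteCounts(CONTIG, 150 + i, ref[i], nucs, raw_depth=depth))
    return counts


class TestThresholdCalling:
    def test_vaf_at_threshold_is_called_inclusively(self):
        call = call_hotspot(_codon_counts((0, 8, 0), depth=1000))
        assert call.vaf == pytest.approx(0.008)
        assert call.called and call.adequate_coverage

    def test_vaf_below_threshold_not_called(self):
        call = call_hotspot(_codon_counts((0, 7, 0), depth=1000))
        assert call.vaf == pytest.approx(0.007)
        assert not call.called

    def test_depth_999_flagged_inadequate_even_at_huge_vaf(self):
        call = call_hotspot(_codon_counts((0, 500, 0), depth=999))
        assert not call.adequate_coverage
        assert not call.called

    def test_every_codon_position_needs_adequate_depth(self):
        counts = _codon_counts((0, 50, 0), depth=2000)
        counts[2] = SiteCounts(CONTIG, 152, "C", {"A": 0, "C": 900, "G": 0, "T": 0}, raw_depth=900)
        call = call_hotspot(counts)
        assert not call.adequate_coverage

    def test_reports_maximizing_position_and_alt(self):
        counts = _codon_counts((3, 40, 10), depth=2000)
        call = call_hotspot(counts)
        assert call.position == 151
        assert call.vaf == pytest.approx(40 / 2000)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            call_hotspot([])

    def test_calling_is_deterministic(self):
        counts = _codon_counts((0, 20, 0))
        c1 = call_hotspot(counts)
        c2 = call_hotspot(counts)
        assert c1 == c2


class TestFalsePositiveModel:
    def test_zero_error_rate_gives_zero_probability(self):
        assert fp_probability(0.0, 5000) == 0.0

    @pytest.mark.parametrize("e,depth", [(1e-3, 1000), (5e-4, 2000)])
    def test_matches_monte_carlo_oracle(self, e, depth):
        n_draws = 2_000_000
        draws = np.random.default_rng(2024).binomial(depth, e, n_draws)
        k = math.ceil(0.008 * depth)
        phat = float((draws >= k).mean())
        se = math.sqrt(max(phat, 1e-9) * (1 - phat) / n_draws)
        assert abs(fp_probability(e, depth, 0.008) - phat) <= 3 * se + 1e-9

    def test_monotone_in_error_rate_and_threshold(self):
        es = [1e-4, 5e-4, 1e-3, 5e-3]
        fps = [fp_probability(e, 3000, 0.008) for e in es]
        assert fps == sorted(fps)
        thresholds = [0.004, 0.008, 0.016, 0.032]
        fps_t = [fp_probability(1e-3, 3000, t) for t in thresholds]
        assert fps_t == sorted(fps_t, reverse=True)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            fp_probability(-0.1, 1000)
        with pytest.raises(ValueError):
            fp_probability(1e-3, 0)


class TestErrorRateEstimation:
    def test_error_free_negatives_estimate_zero(self, panel, clean_err):
        sample = simulate_reads(SimSampleSpec("s", 40, (), depth=500, seed=6), panel, clean_err)
        counts = pileup_counts(list(sample.blocks.values()), panel.sites())
        est = estimate_error_rate(counts)
        assert est.e == 0.0 and est.ci_low == 0.0

    def test_recovers_generating_rate_within_99pct_ci(self, panel):
        e = 2e-3
        err = ErrorModel(sub_error_rate=e, bq_pass_fraction=1.0, mq_pass_fraction=1.0)
        sample = simulate_reads(SimSampleSpec("s", 40, (), depth=25_000, seed=21), panel, err)
        counts = pileup_counts(list(sample.blocks.values()), panel.sites())
        est = estimate_error_rate(counts, confidence=0.99)
        assert est.pooled_depth >= 1_000_000
        assert est.ci_low <= e <= est.ci_high

    def test_hotspot_alternates_excluded_from_numerator(self):
        sc = SiteCounts(CONTIG, 151, "T", {"A": 0, "C": 12, "G": 0, "T": 988}, raw_depth=1000)
        est = estimate_error_rate([sc], exclude_alts={(CONTIG, 151): {"C"}})
        assert est.e == 0.0

    def test_zero_pooled_depth_rejected(self):
        sc = SiteCounts(CONTIG, 151, "T", {"A": 0, "C": 0, "G": 0, "T": 0})
        with pytest.raises(ValueError):
            estimate_error_rate([sc])


class TestNpm1Detector:
    def test_worked_example_four_in_3466(self, panel, clean_err):
        block = simulate_npm1_reads(3466, 4, clean_err, seed=1, panel=panel)
        call = npm1_mutation_a_vaf(block, panel.get("NPM1 L287"))
        assert call.filtered_depth == 3466
        assert round(call.vaf, 4) == 0.0012
        assert not call.called  # below the 0.008 threshold

    def test_no_insertions_means_zero_vaf(self, panel, clean_err):
        block = simulate_npm1_reads(200, 0, clean_err, seed=3, panel=panel)
        call = npm1_mutation_a_vaf(block, panel.get("NPM1 L287"))
        assert call.vaf == 0.0

    def test_insertion_outside_window_not_counted(self, panel, clean_err, header):
        hs = panel.get("NPM1 L287")
        block = simulate_npm1_reads(100, 5, clean_err, seed=2, panel=panel)
        # displace the recorded insertions 20 bp downstream of the canonical point
        block.insertions = [
            (row, after + 20, seq) for row, after, seq in block.insertions
        ]
        call = npm1_mutation_a_vaf(block, hs)
        assert call.vaf == 0.0
        # same conclusion through the SAM representation
        segs = block.to_alignments(header)
        assert npm1_mutation_a_vaf(segs, hs).vaf == 0.0

    def test_wrong_inserted_sequence_rejected_unless_relaxed(self, panel, clean_err):
        hs = panel.get("NPM1 L287")
        block = simulate_npm1_reads(100, 3, clean_err, seed=4, panel=panel)
        block.insertions = [(row, after, "AAAA") for row, after, seq in block.insertions]
        strict = npm1_mutation_a_vaf(block, hs, CallingConfig())
        assert strict.vaf == 0.0
        relaxed = npm1_mutation_a_vaf(block, hs, CallingConfig(npm1_require_seq=False))
        assert relaxed.vaf == pytest.approx(3 / 100)
        assert relaxed.alt == "AAAA"

    def test_zero_spanning_reads_is_undefined(self, panel):
        hs = panel.get("NPM1 L287")
        with pytest.raises(ValueError, match="undefined"):
            npm1_mutation_a_vaf([], hs)

    def test_block_and_segment_detectors_agree(self, panel, header):
        err = ErrorModel(sub_error_rate=1e-3, bq_pass_fraction=0.9, mq_pass_fraction=0.9)
        block = simulate_npm1_reads(800, 12, err, seed=15, panel=panel)
        hs = panel.get("NPM1 L287")
        c1 = npm1_mutation_a_vaf(block, hs)
        c2 = npm1_mutation_a_vaf(block.to_alignments(header), hs)
        assert c1.vaf == c2.vaf and c1.filtered_depth == c2.filtered_depth


class TestCellFraction:
    def test_threshold_vaf_maps_to_1p6_percent_of_cells(self):
        assert vaf_to_cell_fraction(0.008, "heterozygous") == pytest.approx(0.016)

    def test_half_vaf_heterozygous_is_full_clonality(self):
        assert vaf_to_cell_fraction(0.5, "heterozygous") == 1.0

    def test_homozygous_is_identity(self):
        assert vaf_to_cell_fraction(0.25, "homozygous") == 0.25

    def test_heterozygous_vaf_above_half_is_domain_error(self):
        with pytest.raises(ValueError):
            vaf_to_cell_fraction(0.6, "heterozygous")


def test_pipeline_calls_spiked_clone_and_nothing_else(panel):
    hs = panel.get("SRSF2 P95")
    clone = CloneSpec(hs, "T", 0.05, position=hs.positions[1])
    spec = SimSampleSpec("s77", 80, (clone,), depth=3000, seed=33)
    sample = simulate_reads(spec, panel, ErrorModel())
    calls = call_sample(sample)
    assert len(calls) == 15
    called = {c.hotspot_label for c in calls if c.called}
    assert called == {"SRSF2 P95"}
    srsf2 = next(c for c in calls if c.hotspot_label == "SRSF2 P95")
    assert srsf2.vaf == pytest.approx(0.05, rel=0.2)
    assert srsf2.fp_prob < 1e-5
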