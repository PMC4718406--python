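import io

import numpy as np
import pytest
from scipy import stats

from nucparticle.peakcall import PeakCall
from nucparticle.site_profile import FeatureAnchor
from nucparticle.synthetic_data import (
    DEPLETED,
    HIGH_DIGESTION,
    LOW_DIGESTION,
    WILDTYPE,
    ConditionSpec,
    DigestionSpec,
    build_model,
    evaluate_recovery,
    make_synthetic_genome,
    simulate_fragments,
)


class TestBuildModel:
    def test_plus_strand_array_arithmetic(self):
        feats = [FeatureAnchor(id="g", chrom="c", anchor_pos=10_000, strand="+")]
        model = build_model({"c": 50_000}, feats, plus_one_offset=60, repeat_length=154)
        by_index = {n.index_in_array: n.center for n in model.nucleosomes}
        assert by_index[1] == 10_060
        assert by_index[2] == 10_214
        assert by_index[-1] == 10_000 - 150 - 60

    def test_minus_strand_centers_decrease(self):
        feats = [FeatureAnchor(id="g", chrom="c", anchor_pos=10_000, strand="-")]
        model = build_model({"c": 50_000}, feats)
        by_index = {n.index_in_array: n.center for n in model.nucleosomes}
        assert by_index[1] == 10_000 - 60
        assert by_index[2] == 10_000 - 60 - 154
        assert by_index[-1] == 10_000 + 150 + 60

    def test_every_feature_gets_an_array(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=20, n_chroms=2)
        model = build_model(chrom_lengths, feats)
        assert len(model.nucleosomes) == 20 * 11  # 10 downstream + one upstream
        assert {f.id for f in feats} == {n.feature_id for n in model.nucleosomes}

    def test_arrays_past_chromosome_end_trimmed(self):
        feats = [FeatureAnchor(id="g", chrom="c", anchor_pos=500, strand="+")]
        model = build_model({"c": 1000}, feats)
        assert all(0 <= n.center <= 1000 for n in model.nucleosomes)
        assert len(model.nucleosomes) < 11


class TestSimulateFragments:
    def test_fixed_seed_gives_byte_identical_sam(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=4)
        model = build_model(chrom_lengths, feats)
        outs = []
        for _ in range(2):
            reads = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 20.0, seed=99)
            buf = io.StringIO()
            reads.write_sam(buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_zero_occupancy_leaves_only_background(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=4)
        model = build_model(chrom_lengths, feats)
        cond = ConditionSpec(label="depleted", occupancy_scale=0.0)
        reads = simulate_fragments(model, cond, LOW_DIGESTION, 50.0, seed=1)
        assert all(c == 0 for c in reads.fragment_counts.values())
        expected_bg = model.background_rate * sum(chrom_lengths.values()) / 1000
        assert reads.n_fragments == pytest.approx(expected_bg, rel=0.5)

    def test_high_digestion_shifts_fragment_lengths_down(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=10)
        model = build_model(chrom_lengths, feats)
        low = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 40.0, seed=2)
        high = simulate_fragments(model, WILDTYPE, HIGH_DIGESTION, 40.0, seed=3)
        assert high.lengths.mean() < low.lengths.mean()
        _, p = stats.ttest_ind(low.lengths, high.lengths, equal_var=False)
        assert p < 1e-6

    def test_depth_linearity_of_planted_mass(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=10)
        model = build_model(chrom_lengths, feats, background_rate=0.0)
        shallow = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 25.0, seed=4)
        deep = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 50.0, seed=5)
        ratio = deep.n_fragments / shallow.n_fragments
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_sam_output_is_valid_proper_pairs_under_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        chrom_lengths, feats = make_synthetic_genome(n_genes=4)
        model = build_model(chrom_lengths, feats)
        reads = simulate_fragments(model, WILDTYPE, LOW_DIGESTION, 10.0, seed=6)
        path = tmp_path / "sim.sam"
        reads.write_sam(path)
        n_left = 0
        with pysam.AlignmentFile(str(path), "r") as af:
            for rec in af:
                assert rec.is_paired and rec.is_proper_pair
                if rec.template_length > 0:
                    n_left += 1
                    assert rec.template_length == rec.next_reference_start \
                        + 50 - rec.reference_start  # mate end - leftmost 5' = TLEN
        assert n_left == reads.n_fragments

    def test_invalid_digestion_and_condition_specs_rejected(self):
        with pytest.raises(ValueError):
            DigestionSpec(level="low", fragment_mean=0)
        with pytest.raises(ValueError):
            ConditionSpec(label="x", fuzziness_scale=0)


class TestEvaluateRecovery:
    def test_peaks_exactly_at_centers_give_full_recovery(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=6)
        model = build_model(chrom_lengths, feats)
        peaks = [
            PeakCall(chrom=n.chrom, summit_pos=n.center, summit_value=50.0)
            for n in model.nucleosomes
        ]
        report = evaluate_recovery(peaks, model, tolerance_bp=10)
        assert report.recovery_fraction == 1.0
        assert report.false_positives_per_kb == 0.0

    def test_shifted_peaks_recover_nothing(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=6)
        model = build_model(chrom_lengths, feats)
        peaks = [
            PeakCall(chrom=n.chrom, summit_pos=n.center + 50, summit_value=50.0)
            for n in model.nucleosomes
        ]
        report = evaluate_recovery(peaks, model, tolerance_bp=10)
        assert report.recovery_fraction == 0.0
        assert report.n_false_positive == len(peaks)

    def test_empty_peak_list_reports_zeros(self):
        chrom_lengths, feats = make_synthetic_genome(n_genes=2)
        model = build_model(chrom_lengths, feats)
        report = evaluate_recovery([], model)
        assert report.recovery_fraction == 0.0
        assert report.n_peaks == 0


class TestPhenotypeDirection:
    def test_depleted_condition_flattens_the_tss_profile(self, tmp_path):
        """Occupancy down + fuzziness up must lower array peaks and raise
        troughs in the TSS-aligned normalised cumulative profile."""
        from conftest import simulate_to_tracks
        from nucparticle import cumulative_profile, kernel_smooth

        profiles = {}
        for cond, seed in ((WILDTYPE, 11), (DEPLETED, 12)):
            model, feats, _, raw = simulate_to_tracks(
                n_genes=40, condition=cond, seed=seed
            )
            kde = {c: kernel_smooth(t) for c, t in raw.items()}
            profiles[cond.label] = cumulative_profile(kde, feats)
        wt, dep = profiles["wildtype"], profiles["depleted"]

        def value_at(profile, bp):
            return profile.normalised[np.argmin(np.abs(profile.offsets - bp))]

        for j in (2, 3, 4):
            peak_bp = 60 + (j - 1) * 154
            trough_bp = peak_bp + 77
            assert value_at(dep, peak_bp) < value_at(wt, peak_bp)
            assert value_at(dep, trough_bp) > value_at(wt, trough_bp)
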