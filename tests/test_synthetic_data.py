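"""Synthetic generators and the packaged reference dataset."""

import math

import numpy as np
import pytest

from wobblescan import screen_quant as sq
from wobblescan import synthetic_data as sd
from wobblescan import trace_quant as tq
from wobblescan.errors import SpecError, TraceFormatError


class TestTraceSpecValidation:
    def test_fractions_must_sum_to_one(self):
        spec = sd.SyntheticTraceSpec("ACGT", mixed_positions={1: {"C": 0.6, "T": 0.6}})
        with pytest.raises(SpecError):
            spec.validate()

    def test_sigma_must_fit_spacing(self):
        with pytest.raises(SpecError):
            sd.SyntheticTraceSpec("ACGT", peak_sigma=15.0, peak_spacing=12).validate()

    def test_non_dna_sequence_rejected(self):
        with pytest.raises(SpecError):
            sd.SyntheticTraceSpec("ACGU").validate()


class TestTraceSimulation:
    def test_deterministic_given_seed(self):
        spec = sd.SyntheticTraceSpec("GATTACA", seed=13)
        a, b = sd.simulate_trace(spec), sd.simulate_trace(spec)
        for base in "ACGT":
            np.testing.assert_array_equal(a.channels[base], b.channels[base])
        assert a.called_bases == b.called_bases

    def test_even_mixture_exact_without_noise(self):
        spec = sd.SyntheticTraceSpec(
            "AAAATAAAA",
            mixed_positions={4: {"T": 0.5, "C": 0.5}},
            noise_sd=0.0,
            quantize=False,
        )
        chrom = sd.simulate_trace(spec)
        assert tq.estimate_inosine_fraction(tq.integrate_peak(chrom, 4)) == 0.5

    def test_peak_locations_evenly_spaced(self):
        chrom = sd.simulate_trace(sd.SyntheticTraceSpec("ACGTACGT", peak_spacing=10))
        assert list(np.diff(chrom.peak_locations)) == [10] * 7


class TestAbifWriter:
    def test_round_trip_identity(self):
        chrom, _ = sd.simulate_reference_trace("AGA", 0.0, seed=21)
        back = tq.read_abif(sd.write_abif(chrom))
        for base in "ACGT":
            np.testing.assert_array_equal(back.channels[base], np.asarray(chrom.channels[base]))
        np.testing.assert_array_equal(back.peak_locations, chrom.peak_locations)
        assert back.called_bases == chrom.called_bases
        assert back.channel_order == chrom.channel_order

    def test_empty_chromatogram_rejected(self):
        channels = {b: np.zeros(10) for b in "ACGT"}
        chrom = tq.Chromatogram(channels, [], "")
        with pytest.raises(TraceFormatError):
            sd.write_abif(chrom)

    def test_overflowing_signal_rejected(self):
        channels = {b: np.zeros(10) for b in "ACGT"}
        channels["A"][5] = 1e6
        chrom = tq.Chromatogram(channels, [5], "A")
        with pytest.raises(TraceFormatError, match="16-bit"):
            sd.write_abif(chrom)


class TestScreenSimulation:
    def test_zero_noise_recovers_exactly(self):
        spec = sd.SyntheticScreenSpec(true_re=7.6, n_replicates=3, replicate_sd=0.0)
        for m in sd.simulate_screen(spec):
            if m.construct == sq.SAMPLE:
                assert sq.normalize_measurement(
                    m.value, spec.ref0_value, spec.ref100_value
                ) == pytest.approx(7.6)

    def test_zero_true_re_sits_at_ref0(self):
        spec = sd.SyntheticScreenSpec(true_re=0.0, n_replicates=5, replicate_sd=0.0)
        samples = [m.value for m in sd.simulate_screen(spec) if m.construct == sq.SAMPLE]
        assert samples == [spec.ref0_value] * 5

    def test_standard_error_bound(self):
        spec = sd.SyntheticScreenSpec(true_re=20.0, n_replicates=12, replicate_sd=0.5, seed=3)
        samples = [m.value for m in sd.simulate_screen(spec) if m.construct == sq.SAMPLE]
        normalized = [
            sq.normalize_measurement(v, spec.ref0_value, spec.ref100_value)
            for v in samples
        ]
        assert abs(np.mean(normalized) - 20.0) <= 0.5

    def test_reproducible(self):
        spec = sd.SyntheticScreenSpec(true_re=5.0, seed=99)
        assert sd.simulate_screen(spec) == sd.simulate_screen(spec)


class TestReferenceDataset:
    def test_completeness(self, dataset):
        assert len(dataset) == 15
        modified = [r.anticodon for r in dataset if r.modification_fraction > 0]
        assert sorted(modified) == ["AAG", "ACG", "AUG"]
        assert dataset.row("ACG").modification_fraction == 1.0
        assert dataset.row("AUG").modification_fraction == 0.5
        assert dataset.row("AAG").modification_fraction == 0.15

    def test_known_cells(self, dataset):
        assert dataset.row("AGA").re["U"].value == 19.7
        assert dataset.row("AUU").re["C"].status == "censored"
        assert dataset.row("AAA").re["A"].status == "not_evaluated"
        assert dataset.row("ACG").codon == "CGU"

    def test_every_targeted_codon_is_u_ending_and_measured(self, dataset):
        for row in dataset:
            assert row.codon.endswith("U")
            assert row.re["U"].is_measured

    def test_flattened_table_marks_censoring(self, reference_re_table):
        sub = reference_re_table.query("anticodon == 'AUU'")
        assert bool(sub.loc[sub.codon == "AAC", "below_lod"].iloc[0])
        assert not bool(sub.loc[sub.codon == "AAU", "below_lod"].iloc[0])

    def test_screen_generator_recovers_all_fixture_rows(self, dataset):
        # push every measured condition through the screen stage and demand
        # agreement within 3 standard errors
        table = sd.simulate_reference_screen_table(seed=17)
        re_df = sq.analyze_screen_table(table)
        lookup = {(r.anticodon, r.codon): r for r in re_df.itertuples(index=False)}
        se = 0.5 / math.sqrt(12)
        from wobblescan import genetic_code as gc

        for row in dataset:
            box = gc.codon_box(row.codon)
            for codon in box.members:
                cell = row.re[codon.third]
                if not cell.is_measured:
                    continue
                got = lookup[(row.anticodon, codon.bases)]
                assert abs(got.mean - cell.value) <= 3 * se, (row.anticodon, codon.bases)
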