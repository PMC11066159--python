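"""Trace parsing, anticodon localization, peak quantification, inosine calls."""

import struct

import numpy as np
import pytest

from wobblescan import genetic_code as gc
from wobblescan import synthetic_data as sd
from wobblescan import trace_quant as tq
from wobblescan.errors import (
    DomainError,
    LocalizationError,
    NoSignalError,
    TraceFormatError,
)


def _simple_chrom(**overrides):
    n = 60
    channels = {b: np.zeros(n) for b in "ACGT"}
    x = np.arange(n, dtype=float)
    channels["T"] = 100.0 * np.exp(-((x - 30) ** 2) / 8.0)
    kwargs = dict(
        channels=channels, peak_locations=[10, 30, 50], called_bases="ATA"
    )
    kwargs.update(overrides)
    return tq.Chromatogram(**kwargs)


class TestChromatogramValidation:
    def test_unequal_channel_lengths(self):
        channels = {b: np.zeros(10) for b in "ACGT"}
        channels["G"] = np.zeros(9)
        with pytest.raises(TraceFormatError):
            tq.Chromatogram(channels, [2], "A")

    def test_peaks_must_increase_within_bounds(self):
        with pytest.raises(TraceFormatError):
            _simple_chrom(peak_locations=[10, 10, 50])
        with pytest.raises(TraceFormatError):
            _simple_chrom(peak_locations=[10, 30, 500])

    def test_calls_match_peaks(self):
        with pytest.raises(TraceFormatError):
            _simple_chrom(called_bases="AT")


class TestAbifReader:
    def test_bad_magic(self):
        with pytest.raises(TraceFormatError, match="ABIF"):
            tq.read_abif(b"XXXX" + b"\x00" * 200)

    def test_missing_required_tag_named(self):
        # minimal ABIF carrying only a FWO_ tag: the reader must name the
        # first missing DATA tag
        entry = struct.pack(
            ">4sIHHIIII", b"FWO_", 1, 2, 1, 4,
            4, int.from_bytes(b"GATC", "big"), 0,
        )
        header = (b"ABIF" + struct.pack(
            ">H4sI2H3I", 101, b"tdir", 1, 1023, 28, 1, 28, 128
        )).ljust(128, b"\x00")
        with pytest.raises(TraceFormatError, match="DATA9"):
            tq.read_abif(header + entry)

    def test_channel_order_mapping(self):
        chrom, _ = sd.simulate_reference_trace("AAU", 0.0, seed=19)
        reordered = tq.Chromatogram(
            channels=chrom.channels,
            peak_locations=chrom.peak_locations,
            called_bases=chrom.called_bases,
            channel_order="TCGA",
        )
        back = tq.read_abif(sd.write_abif(reordered))
        assert back.channel_order == "TCGA"
        for b in "ACGT":
            np.testing.assert_array_equal(back.channels[b], np.asarray(chrom.channels[b]))


class TestXmlAndCsvReaders:
    def test_xml_round_trip_matches_abif(self):
        chrom, _ = sd.simulate_reference_trace("AAA", 0.0, seed=7)
        from_abif = tq.read_abif(sd.write_abif(chrom))
        from_xml = tq.read_trace_xml(tq.write_trace_xml(chrom))
        for b in "ACGT":
            np.testing.assert_array_equal(from_xml.channels[b], from_abif.channels[b])
        np.testing.assert_array_equal(from_xml.peak_locations, from_abif.peak_locations)
        assert from_xml.called_bases == from_abif.called_bases

    def test_xml_missing_element(self):
        with pytest.raises(TraceFormatError):
            tq.read_trace_xml("<trace><channel base='A'>1 2</channel></trace>")

    def test_xml_unequal_arrays(self):
        doc = (
            "<trace>"
            "<channel base='A'>1 2 3</channel><channel base='C'>1 2</channel>"
            "<channel base='G'>1 2 3</channel><channel base='T'>1 2 3</channel>"
            "<peak_locations>1</peak_locations><called_bases>A</called_bases>"
            "</trace>"
        )
        with pytest.raises(TraceFormatError):
            tq.read_trace_xml(doc)

    def test_xml_empty_arrays(self):
        doc = (
            "<trace>"
            "<channel base='A'> </channel><channel base='C'> </channel>"
            "<channel base='G'> </channel><channel base='T'> </channel>"
            "<peak_locations>1</peak_locations><called_bases>A</called_bases>"
            "</trace>"
        )
        with pytest.raises(TraceFormatError):
            tq.read_trace_xml(doc)

    def test_csv_round_trip(self, tmp_path):
        chrom, _ = sd.simulate_reference_trace("ACA", 0.0, seed=11)
        path = tmp_path / "trace.csv"
        tq.write_trace_csv(chrom, path)
        back = tq.read_trace_csv(path)
        for b in "ACGT":
            np.testing.assert_allclose(back.channels[b], np.asarray(chrom.channels[b]))
        assert back.called_bases == chrom.called_bases


class TestLocalization:
    def test_constructed_offset_recovered(self):
        chrom, reference = sd.simulate_reference_trace("AUG", 0.0, seed=2)
        locus = tq.locate_anticodon(chrom, reference)
        start = len(sd.SYNTHETIC_FLANK_LEFT)
        assert locus.anticodon_window == (start, start + 1, start + 2)
        assert locus.trace_index == start + 2
        assert locus.orientation == "reverse_complement"

    def test_miscalled_flank_base_recovered_by_alignment(self):
        chrom, reference = sd.simulate_reference_trace("AUG", 0.0, seed=2)
        exact = tq.locate_anticodon(chrom, reference)
        calls = list(chrom.called_bases)
        flank_pos = len(sd.SYNTHETIC_FLANK_LEFT) - 5
        calls[flank_pos] = "A" if calls[flank_pos] != "A" else "G"
        chrom.called_bases = "".join(calls)
        fallback = tq.locate_anticodon(chrom, reference)
        assert fallback == exact

    def test_context_absent(self):
        chrom, _ = sd.simulate_reference_trace("AUG", 0.0, seed=2)
        bogus = "A" * 14 + "cat" + "G" * 14
        with pytest.raises(LocalizationError):
            tq.locate_anticodon(chrom, bogus)

    def test_ambiguous_context_rejected(self):
        unit = sd.SYNTHETIC_FLANK_LEFT + "CAT" + sd.SYNTHETIC_FLANK_RIGHT
        spec = sd.SyntheticTraceSpec(sequence=unit + unit, noise_sd=0.0)
        chrom = sd.simulate_trace(spec)
        reference = sd.SYNTHETIC_FLANK_LEFT + "cat" + sd.SYNTHETIC_FLANK_RIGHT
        with pytest.raises(LocalizationError, match="2 times"):
            tq.locate_anticodon(chrom, reference)

    def test_reference_must_mark_one_triplet(self):
        chrom, _ = sd.simulate_reference_trace("AUG", 0.0, seed=2)
        with pytest.raises(LocalizationError):
            tq.locate_anticodon(chrom, "ACGT" * 10)  # nothing marked

    def test_insufficient_flank(self):
        chrom, _ = sd.simulate_reference_trace("AUG", 0.0, seed=2)
        with pytest.raises(LocalizationError, match="flank"):
            tq.locate_anticodon(chrom, "ACGTACG" + "cat" + "ACGTACG")


class TestOrientation:
    def test_sequenced_triplet_is_dna_of_targeted_codon(self, dataset):
        # the sequenced strand is the reverse complement of the tRNA, so the
        # anticodon reads out as the DNA spelling of its targeted codon and
        # position 34 lands on the triplet's third base
        for row in dataset:
            chrom, reference = sd.simulate_reference_trace(row.anticodon, 0.0, seed=3)
            locus = tq.locate_anticodon(chrom, reference)
            triplet = chrom.called_bases[
                locus.anticodon_window[0] : locus.anticodon_window[2] + 1
            ]
            assert triplet == gc.rna_to_dna(row.codon)
            # and the 34 base of an unmodified A34 anticodon reads T
            assert chrom.called_bases[locus.trace_index] == "T"


class TestPeakIntegration:
    def test_clean_t_peak(self):
        chrom = _simple_chrom()
        areas = tq.integrate_peak(chrom, 1)
        assert areas["T"] > 0
        assert areas["C"] == 0.0

    def test_identical_channels_give_equal_areas(self):
        n = 60
        x = np.arange(n, dtype=float)
        peak = 100.0 * np.exp(-((x - 30) ** 2) / 8.0)
        channels = {"A": np.zeros(n), "G": np.zeros(n), "T": peak.copy(), "C": peak.copy()}
        chrom = tq.Chromatogram(channels, [10, 30, 50], "ATA")
        areas = tq.integrate_peak(chrom, 1)
        assert abs(areas["T"] - areas["C"]) < 1e-9

    def test_flat_channel_integrates_to_zero(self):
        chrom = _simple_chrom()
        chrom.channels["G"] = np.full(chrom.n_samples, 7.0)
        areas = tq.integrate_peak(chrom, 1)
        assert areas["G"] == 0.0

    def test_boundary_window_truncated_with_warning(self):
        chrom = _simple_chrom(peak_locations=[2, 30, 50], called_bases="ATA")
        with pytest.warns(UserWarning, match="truncated"):
            tq.integrate_peak(chrom, 0)

    def test_invalid_index(self):
        with pytest.raises(DomainError):
            tq.integrate_peak(_simple_chrom(), 7)


class TestInosineEstimation:
    def test_pure_t_is_unmodified(self, clean_trace):
        chrom, _ = clean_trace(0.0)
        assert tq.estimate_inosine_fraction(tq.integrate_peak(chrom, 10)) == 0.0

    def test_pure_c_is_fully_modified(self, clean_trace):
        chrom, _ = clean_trace(1.0)
        estimate = tq.estimate_inosine_fraction(tq.integrate_peak(chrom, 10))
        # neighbouring T peaks leak vanishing Gaussian tails into the window
        assert estimate == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("fraction", [0.0, 0.05, 0.15, 0.5, 1.0])
    def test_estimator_exact_on_noise_free_traces(self, clean_trace, fraction):
        chrom, _ = clean_trace(fraction)
        estimate = tq.estimate_inosine_fraction(tq.integrate_peak(chrom, 10))
        assert estimate == pytest.approx(fraction, abs=1e-6)

    def test_mixed_peak_with_default_noise(self):
        chrom, reference = sd.simulate_reference_trace("AAG", 0.15, seed=42)
        locus = tq.locate_anticodon(chrom, reference)
        estimate = tq.estimate_inosine_fraction(
            tq.integrate_peak(chrom, locus.trace_index)
        )
        assert estimate == pytest.approx(0.15, abs=0.03)

    def test_no_signal_error(self):
        with pytest.raises(NoSignalError):
            tq.estimate_inosine_fraction(tq.PeakAreas({"A": 1, "C": 0, "G": 0, "T": 0}))

    def test_monotone_in_generating_fraction(self):
        estimates = []
        for f in (0.0, 0.1, 0.25, 0.5, 0.75, 1.0):
            chrom, reference = sd.simulate_reference_trace("AAG", f, seed=9)
            locus = tq.locate_anticodon(chrom, reference)
            estimates.append(
                tq.estimate_inosine_fraction(tq.integrate_peak(chrom, locus.trace_index))
            )
        assert estimates == sorted(estimates)

    def test_height_method_agrees_on_clean_trace(self, clean_trace):
        chrom, _ = clean_trace(0.3)
        by_height = tq.estimate_inosine_fraction(
            tq.integrate_peak(chrom, 10, method="height")
        )
        assert by_height == pytest.approx(0.3, abs=1e-6)


class TestModificationCall:
    def test_strong_signal_called(self):
        call = tq.call_modification(0.50, 0.01, 0.005)
        assert call.modified

    def test_baseline_level_not_called(self):
        assert not tq.call_modification(0.01, 0.01, 0.005).modified

    def test_three_sigma_gate(self):
        # passes the absolute threshold but not the noise gate
        assert not tq.call_modification(0.06, 0.05, 0.01).modified

    def test_input_validation(self):
        with pytest.raises(DomainError):
            tq.call_modification(1.5, 0.0, 0.0)

    def test_background_stats_exclude_locus(self):
        chrom, reference = sd.simulate_reference_trace("ACG", 1.0, seed=4)
        locus = tq.locate_anticodon(chrom, reference)
        mean, sdev = tq.background_fraction_stats(chrom, exclude=locus.anticodon_window)
        assert 0.0 <= mean < 0.05
        assert sdev >= 0.0
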