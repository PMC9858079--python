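"""Delineation: R detection, P/T windows, zero-crossing bounds, segments."""

import numpy as np
import pytest

import ecgwave as ew
from ecgwave.records import EcgRecord
from tests.conftest import fiducial_errors, match_fiducials


class TestDetectRPeaks:
    def test_clean_record_all_beats_found(self, clean_record_72):
        record, truth = clean_record_72
        peaks = ew.detect_r_peaks(record)
        assert peaks.size == len(truth.beats)
        tol = int(0.025 * record.fs)
        for p, r in zip(peaks, truth.r_peaks):
            assert abs(p - r) <= tol

    def test_flat_signal_yields_no_peaks(self):
        rec = EcgRecord(np.zeros(2000), fs=360.0)
        assert ew.detect_r_peaks(rec).size == 0

    def test_peaks_strictly_increasing_with_refractory(self, clean_records_by_rate):
        for bpm, (record, _) in clean_records_by_rate.items():
            peaks = ew.detect_r_peaks(record)
            assert np.all(np.diff(peaks) >= int(0.2 * record.fs))

    def test_snr10_recall_and_precision(self):
        """At 10 dB broadband SNR, R detection stays >= 0.95 on both
        recall and precision with a 50 ms tolerance."""
        tp = fp = fn = 0
        for seed in (1, 2, 3):
            record, truth = ew.synthesize_record(72, 10.0, seed=seed)
            noisy = ew.add_noise(record,
                                 ew.NoiseSpec.broadband_for_snr(record, 10.0,
                                                                seed=seed + 50))
            cleaned = ew.preprocess(noisy)
            peaks = ew.detect_r_peaks(cleaned)
            tol = int(0.05 * record.fs)
            gt = truth.r_peaks
            matched = set()
            for p in peaks:
                hits = [g for g in gt if abs(g - p) <= tol and g not in matched]
                if hits:
                    matched.add(hits[0])
                    tp += 1
                else:
                    fp += 1
            fn += len(gt) - len(matched)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestLocatePT:
    def test_clean_peaks_within_25ms(self, clean_record_72):
        record, truth = clean_record_72
        pt = ew.locate_p_t_peaks(record, truth.r_peaks)
        tol = int(0.025 * record.fs)
        for (p_peak, t_peak), beat in zip(pt, truth.beats):
            assert abs(p_peak - beat.P_peak) <= tol
            assert abs(t_peak - beat.T_peak) <= tol

    def test_t_farther_than_p_iff_center_farther(self, clean_record_72):
        record, truth = clean_record_72
        pt = ew.locate_p_t_peaks(record, truth.r_peaks)
        template = ew.BeatTemplateSpec()
        expect = template.t.center > -template.p.center
        for (p_peak, t_peak), r in zip(pt, truth.r_peaks):
            assert ((t_peak - r) > (r - p_peak)) == expect

    def test_edge_beat_window_dropped(self):
        # an R peak 10 samples from the start cannot host a P window
        x = np.zeros(2000)
        x[10] = 1.0
        x[1000] = 1.0
        rec = EcgRecord(x, fs=360.0)
        pt = ew.locate_p_t_peaks(rec, np.array([10, 1000]))
        assert pt[0] is None


class TestFindWaveBounds:
    def test_hand_traced_example(self):
        x = np.array([0.0, 0.2, 0.9, 0.2, 0.0, -0.1])
        assert ew.find_wave_bounds(x, 2) == (0, 4)

    def test_gaussian_bump_bracketed(self):
        t = np.linspace(-1, 1, 201)
        g = np.exp(-(t**2) / 0.005)
        g[np.abs(g) < 1e-4] = 0.0
        on, off = ew.find_wave_bounds(g, 100)
        assert np.all(g[on + 1:off] > 0)
        assert g[on] == 0 and g[off] == 0

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        peak = int(np.argmax(np.abs(x)))
        assert ew.find_wave_bounds(x, peak) == ew.find_wave_bounds(-x, peak)

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            ew.find_wave_bounds(np.zeros(10), 5)

    def test_exhaustive_scan_oracle(self):
        """Backward/forward scans agree with a brute-force search over
        all indices for random signals."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(size=rng.integers(20, 2000))
            peak = int(rng.integers(1, x.size - 1))
            if x[peak] == 0:
                continue
            on, off = ew.find_wave_bounds(x, peak)
            s = np.sign(x[peak])
            cross = np.flatnonzero((x == 0) | (np.sign(x) != s))
            before = cross[cross < peak]
            after = cross[cross > peak]
            assert on == (before[-1] if before.size else 0)
            assert off == (after[0] if after.size else x.size - 1)


class TestFindQrsBounds:
    def test_synthetic_beat_qrs_on_within_25ms(self, clean_record_72):
        record, truth = clean_record_72
        tol = int(0.025 * record.fs)
        for beat in truth.beats:
            on, off = ew.find_qrs_bounds(record.samples, beat.P_off, beat.Q,
                                         beat.S, beat.T_on)
            assert abs(on - beat.QRS_on) <= tol
            assert abs(off - beat.QRS_off) <= tol

    def test_single_crossing_found_by_both_rules(self):
        x = np.concatenate([np.full(10, 1.0), np.full(10, -1.0)])
        # crossing (far index) at 10 in both windows
        on, _ = ew.find_qrs_bounds(x, p_off=5, q=15, s=16, t_on=19)
        assert on == 10
        x2 = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])
        _, off = ew.find_qrs_bounds(x2, p_off=0, q=2, s=5, t_on=15)
        assert off == 10

    def test_no_crossing_falls_back_to_window_boundary(self):
        x = np.ones(30)
        on, off = ew.find_qrs_bounds(x, p_off=2, q=10, s=15, t_on=25)
        assert on == 9 and off == 16

    def test_invalid_window_order_rejected(self):
        with pytest.raises(ValueError):
            ew.find_qrs_bounds(np.ones(30), 10, 5, 15, 25)


class TestDelineateBeats:
    @pytest.mark.parametrize("bpm", [40, 72, 140])
    def test_clean_records_fiducials_within_20ms(self, clean_records_by_rate, bpm):
        record, truth = clean_records_by_rate[bpm]
        annotations = ew.delineate_beats(record)
        assert len(annotations) >= len(truth.beats) - 1  # edge beats may drop
        errs = fiducial_errors(annotations, truth, record.fs)
        tol = int(0.020 * record.fs)
        assert errs.size > 0
        assert np.mean(errs <= tol) >= 0.95

    def test_every_annotation_ordered(self, clean_records_by_rate):
        for record, _ in clean_records_by_rate.values():
            for ann in ew.delineate_beats(record):
                assert ann.is_ordered()

    def test_empty_record_returns_no_beats(self):
        rec = EcgRecord(np.zeros(4000), fs=360.0)
        assert ew.delineate_beats(rec) == []

    def test_translation_equivariance(self, clean_record_72):
        record, truth = clean_record_72
        k = 37
        shifted = EcgRecord(np.concatenate([np.zeros(k), record.samples]),
                            fs=record.fs, record_id=record.record_id,
                            label=record.label)
        base = ew.delineate_beats(record, r_peaks=truth.r_peaks)
        moved = ew.delineate_beats(shifted, r_peaks=truth.r_peaks + k)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            for name in ew.synthetic.FIDUCIAL_NAMES:
                assert getattr(b, name) == getattr(a, name) + k

    def test_amplitude_scale_invariance(self, clean_record_72):
        record, _ = clean_record_72
        scaled = record.with_samples(record.samples * 3.7)
        base = ew.delineate_beats(record)
        big = ew.delineate_beats(scaled)
        assert [a.as_dict() for a in base] == [a.as_dict() for a in big]


class TestExtractWaveSegments:
    def test_qrs_segments_contain_beat_maximum(self, clean_record_72):
        record, truth = clean_record_72
        annotations = ew.delineate_beats(record)
        segments = ew.extract_wave_segments(record, annotations, "QRS")
        assert len(segments) == len(annotations)
        pairs = match_fiducials(annotations, truth, record.fs)
        for seg, (ann, beat) in zip(segments, pairs):
            peak_value = record.samples[beat.R]
            assert np.sum(seg.samples == peak_value) == 1

    def test_p_segment_lengths_match_bounds(self, clean_record_72):
        record, _ = clean_record_72
        annotations = ew.delineate_beats(record)
        for seg, ann in zip(ew.extract_wave_segments(record, annotations, "P"),
                            annotations):
            assert len(seg) == ann.P_off - ann.P_on

    def test_segments_carry_rhythm_label(self, clean_records_by_rate):
        record, _ = clean_records_by_rate[140]
        annotations = ew.delineate_beats(record)
        for seg in ew.extract_wave_segments(record, annotations, "T"):
            assert seg.label == "tachycardia"

    def test_wave_cutpoints_never_overlap(self, clean_record_72):
        record, _ = clean_record_72
        for ann in ew.delineate_beats(record):
            assert ann.P_off <= ann.QRS_on < ann.QRS_off <= ann.T_on

    def test_unknown_wave_kind_rejected(self, clean_record_72):
        record, _ = clean_record_72
        with pytest.raises(ValueError):
            ew.extract_wave_segments(record, [], "U")
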