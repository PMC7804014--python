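"""Annotation model, selection-table I/O, features, and the SNR statistic."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from bluefin.annotations import (
    Annotation,
    mean_duration,
    measure_features,
    measure_snr,
    read_selection_table,
    write_selection_table,
)
from bluefin.spectrogram import stft_power

FS = 250.0


def _records():
    return [
        Annotation(10.5, 22.5, 17.0, 29.0, "Bm-Ant-Z", site_year="Casey 2014"),
        Annotation(30.0, 31.0, 20.0, 30.0, "Bp-20Hz"),
        Annotation(40.25, 43.75, 15.0, 100.0, "Bp-20Plus"),
    ]


class TestSelectionTables:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "sel.txt"
        originals = _records()
        write_selection_table(originals, path)
        loaded = read_selection_table(path)
        assert loaded == originals

    def test_rewrite_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_selection_table(_records(), p1)
        write_selection_table(read_selection_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_columns_located_by_header_not_position(self, tmp_path):
        path = tmp_path / "permuted.txt"
        path.write_text(
            "Classification\tHigh Freq (Hz)\tBegin Time (s)\tLow Freq (Hz)\tEnd Time (s)\n"
            "Bm-Ant-Z\t29.0\t10.5\t17.0\t22.5\n"
        )
        (ann,) = read_selection_table(path)
        assert ann.begin == 10.5 and ann.end == 22.5
        assert ann.duration == pytest.approx(12.0)
        assert ann.label == "Bm-Ant-Z"

    def test_missing_column_error_names_it(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Begin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tClassification\n")
        with pytest.raises(ValueError, match=r"High Freq \(Hz\)"):
            read_selection_table(path)

    def test_malformed_number_error_names_row(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "Begin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)\tClassification\n"
            "10.0\t12.0\t17.0\t29.0\tBm-Ant-A\n"
            "oops\t12.0\t17.0\t29.0\tBm-Ant-A\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_selection_table(path)


class TestAnnotationModel:
    def test_invalid_boxes_rejected(self):
        with pytest.raises(ValueError):
            Annotation(5.0, 5.0, 17.0, 29.0, "Bm-Ant-A")
        with pytest.raises(ValueError):
            Annotation(0.0, 1.0, 29.0, 17.0, "Bm-Ant-A")
        with pytest.raises(ValueError):
            Annotation(0.0, 1.0, 17.0, 29.0, "Bm-Ant-Q")


class TestMeasureFeatures:
    def test_pure_tone_frequency_percentiles_collapse(self):
        # boxcar window + exact bin frequency: all energy lands in one bin
        from bluefin.spectrogram import SpectrogramParams

        bin_hz = 250.0 / 256.0
        tone = 27 * bin_hz
        t = np.arange(int(20 * FS)) / FS
        audio = np.sin(2 * np.pi * tone * t)
        ann = Annotation(2.0, 18.0, 15.0, 35.0, "Bm-Ant-A")
        feats = measure_features(
            ann, audio, FS, SpectrogramParams(window="boxcar")
        )
        assert feats.defined
        assert abs(feats.f5 - tone) <= bin_hz
        assert abs(feats.f95 - tone) <= bin_hz

    def test_uniform_energy_box_t90_is_ninety_percent(self):
        """Constant-envelope tone: cumulative energy is linear in time, so the
        5th-95th percentile span is 0.9 of the box duration."""
        t = np.arange(int(40 * FS)) / FS
        audio = np.sin(2 * np.pi * 25.0 * t)
        ann = Annotation(4.0, 36.0, 20.0, 30.0, "Bp-20Hz")
        feats = measure_features(ann, audio, FS)
        assert feats.t90 == pytest.approx(0.9 * 32.0, abs=1.1)  # one hop

    def test_matches_brute_force_percentiles(self, rng):
        """Features equal an independent cumulative-sum computation."""
        audio = rng.standard_normal(int(30 * FS))
        ann = Annotation(3.0, 27.0, 10.0, 60.0, "Unidentified")
        feats = measure_features(ann, audio, FS)

        power, times, freqs = stft_power(audio, FS)
        it = (times >= ann.begin) & (times <= ann.end)
        jf = (freqs >= ann.f_low) & (freqs <= ann.f_high)
        box = power[np.ix_(it, jf)]

        def crossing(marginal, coords, q):
            c = np.cumsum(marginal)
            return np.interp(q * c[-1], c, coords)

        t5 = crossing(box.sum(axis=1), times[it], 0.05)
        t95 = crossing(box.sum(axis=1), times[it], 0.95)
        f5 = crossing(box.sum(axis=0), freqs[jf], 0.05)
        f95 = crossing(box.sum(axis=0), freqs[jf], 0.95)
        assert feats.t90 == pytest.approx(t95 - t5, rel=1e-9)
        assert feats.f5 == pytest.approx(f5, rel=1e-9)
        assert feats.f95 == pytest.approx(f95, rel=1e-9)

    def test_feature_nesting_invariant(self, rng):
        audio = rng.standard_normal(int(30 * FS))
        ann = Annotation(5.0, 20.0, 12.0, 50.0, "Unidentified")
        feats = measure_features(ann, audio, FS)
        assert ann.f_low <= feats.f5 <= feats.f95 <= ann.f_high
        assert 0 < feats.t90 <= ann.duration

    def test_zero_energy_box_flagged_undefined(self):
        audio = np.zeros(int(30 * FS))
        ann = Annotation(5.0, 10.0, 17.0, 29.0, "Bm-Ant-A")
        feats = measure_features(ann, audio, FS)
        assert not feats.defined


class TestMeasureSnr:
    def _tone_in_noise(self, amp, seed=5, dur=60.0, f=22.0):
        rng = np.random.default_rng(seed)
        n = int(dur * FS)
        audio = 0.5 * rng.standard_normal(n)
        t = np.arange(int(10 * FS)) / FS
        i0 = int(25 * FS)
        audio[i0 : i0 + t.size] += amp * np.sin(2 * np.pi * f * t)
        return audio, Annotation(25.0, 35.0, 17.0, 29.0, "Bm-Ant-A")

    def test_matches_independent_evaluation(self):
        """The statistic equals the formula re-evaluated from scratch on the
        same samples: 20*log10((Z_sn - Z_n)^2 / sqrt(var_n))."""
        audio, ann = self._tone_in_noise(2.0)
        m = measure_snr(ann, audio, FS)
        assert m.defined

        sos = butter(4, [17.0, 29.0], btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, audio)
        d = ann.duration
        seg = lambda a, b: x[int(round(a * FS)) : int(round(b * FS))]
        z_sn = np.sqrt(np.mean(seg(25.0, 35.0) ** 2))
        noise = np.concatenate(
            [seg(25.0 - 1.0 - d / 2, 25.0 - 1.0), seg(35.0 + 1.0, 35.0 + 1.0 + d / 2)]
        )
        z_n = np.sqrt(np.mean(noise**2))
        var_n = np.var(noise**2)
        expected = 20.0 * np.log10((z_sn - z_n) ** 2 / np.sqrt(var_n))
        assert m.snr_db == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_tone_amplitude(self):
        values = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            audio, ann = self._tone_in_noise(amp)
            values.append(measure_snr(ann, audio, FS).snr_db)
        assert np.all(np.diff(values) > 0)

    def test_all_zero_audio_flagged_undefined(self):
        ann = Annotation(25.0, 35.0, 17.0, 29.0, "Bm-Ant-A")
        m = measure_snr(ann, np.zeros(int(60 * FS)), FS)
        assert not m.defined
        assert np.isnan(m.snr_db)

    def test_insufficient_context_is_an_error(self):
        ann = Annotation(0.5, 10.5, 17.0, 29.0, "Bm-Ant-A")
        with pytest.raises(ValueError, match="insufficient context"):
            measure_snr(ann, np.random.default_rng(0).standard_normal(int(12 * FS)), FS)

    def test_edge_windows_shrink_with_warning(self):
        audio, ann = self._tone_in_noise(2.0, dur=60.0)
        # annotation near the start: only ~2 s of context before, needs 6
        ann2 = Annotation(3.0, 13.0, 17.0, 29.0, "Bm-Ant-A")
        with pytest.warns(UserWarning, match="shrunk"):
            measure_snr(ann2, audio, FS)


class TestMeanDuration:
    def test_constant_and_simple_means(self):
        anns = [Annotation(0, 13, 17, 29, "Bm-Ant-A") for _ in range(3)]
        assert mean_duration(anns) == pytest.approx(13.0)
        anns = [
            Annotation(0, 2, 17, 29, "Bm-Ant-A"),
            Annotation(5, 8, 17, 29, "Bm-Ant-A"),
        ]
        assert mean_duration(anns) == pytest.approx(2.5)

    def test_matches_numpy_mean_on_random_durations(self, rng):
        durations = rng.uniform(0.5, 20.0, size=100)
        anns = [Annotation(0.0, d, 17.0, 29.0, "Bm-Ant-Z") for d in durations]
        assert mean_duration(anns) == pytest.approx(float(np.mean(durations)))

    def test_label_filter_and_empty_error(self):
        anns = [Annotation(0, 2, 17, 29, "Bm-Ant-A"), Annotation(0, 4, 20, 30, "Bp-20Hz")]
        assert mean_duration(anns, labels=["Bp-20Hz"]) == pytest.approx(4.0)
        with pytest.raises(ValueError, match="no annotations"):
            mean_duration(anns, labels=["Bm-D"])
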