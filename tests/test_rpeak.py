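import numpy as np
import pytest

from hrvemotion.denoise import denoise_ecg
from hrvemotion.rpeak import (
    compute_rri,
    detect_rpeaks,
    make_qrs_template,
    similarity_trace,
)
from tests.conftest import match_counts


class TestTemplate:
    def test_n3_endpoints_and_crest(self):
        tpl = make_qrs_template(3)
        np.testing.assert_allclose(tpl.values, [-1.0, 1.0, -1.0], atol=1e-12)

    def test_n15_midpoint_is_one(self):
        tpl = make_qrs_template(15)
        assert tpl.values[7] == pytest.approx(1.0)
        assert tpl.values[0] == pytest.approx(-1.0)
        assert tpl.values[-1] == pytest.approx(-1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_qrs_template(2)


class TestSimilarity:
    def test_self_correlation_is_one(self):
        tpl = make_qrs_template(15)
        trace = similarity_trace(tpl.values, tpl)
        assert trace.max() == pytest.approx(1.0)
        assert np.argmax(trace) == 7  # centered alignment

    def test_zero_signal_scores_zero(self):
        tpl = make_qrs_template(15)
        trace = similarity_trace(np.zeros(100), tpl)
        np.testing.assert_array_equal(trace, 0.0)

    def test_embedded_template_located(self):
        tpl = make_qrs_template(15)
        x = np.zeros(500)
        k = 203  # center position of the embedded template
        x[k - 7 : k + 8] = tpl.values
        trace = similarity_trace(x, tpl)
        assert np.argmax(trace) == k

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        trace = similarity_trace(rng.normal(size=1000), make_qrs_template(15))
        assert np.all(trace <= 1 + 1e-12) and np.all(trace >= -1 - 1e-12)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            similarity_trace(np.zeros(5), make_qrs_template(15))


class TestDetect:
    def test_flat_signal_no_peaks(self):
        res = detect_rpeaks(np.zeros(1000))
        assert res.peak_indices.size == 0

    def test_peak_count_bounded_by_runs(self, noisy_ecg_10db):
        rec, _ = noisy_ecg_10db
        res = detect_rpeaks(denoise_ecg(rec).denoised, fs=rec.fs)
        assert res.peak_indices.size == len(res.candidate_runs)
        assert np.all(np.diff(res.peak_indices) > 0)
        for p, (start, stop) in zip(res.peak_indices, res.candidate_runs):
            assert start <= p < stop

    def test_recovery_at_10db(self, noisy_ecg_10db):
        rec, truth = noisy_ecg_10db
        den = denoise_ecg(rec)
        res = detect_rpeaks(den.denoised, fs=rec.fs)
        tol = int(round(0.02 * rec.fs))
        _, sens, ppv = match_counts(truth, res.peak_indices, tol)
        assert sens >= 59 / 60
        assert ppv >= 0.99

    def test_clean_signal_full_recovery(self, clean_ecg):
        rec, truth = clean_ecg
        res = detect_rpeaks(rec.samples, fs=rec.fs)
        _, sens, _ = match_counts(truth, res.peak_indices, 1)
        assert sens == 1.0


class TestRRI:
    def test_uniform_peaks(self):
        rri = compute_rri(np.array([0, 256, 512]), fs=256)
        np.testing.assert_allclose(rri.intervals, [1.0, 1.0])

    def test_short_interval_dropped(self):
        rri = compute_rri(np.array([0, 25, 281]), fs=256, bounds=(0.3, 2.0))
        np.testing.assert_allclose(rri.intervals, [281 / 256])
        assert rri.intervals.size == rri.n_beats - 1

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            compute_rri(np.array([100]), fs=256)

    def test_all_intervals_within_bounds(self, noisy_ecg_10db):
        rec, _ = noisy_ecg_10db
        res = detect_rpeaks(denoise_ecg(rec).denoised, fs=rec.fs)
        rri = compute_rri(res, rec.fs)
        assert np.all((rri.intervals >= 0.3) & (rri.intervals <= 2.0))
        assert rri.intervals.sum() <= rec.duration

    def test_fs_invariance(self, clean_ecg):
        # same waveform at doubled rate: intervals agree within one sample
        from hrvemotion.io import ECGRecord
        from hrvemotion.synthetic import SynthSpec, synth_ecg

        spec = SynthSpec(duration=60.0, snr_db=None, seed=3, fs=512.0,
                         modulations={"LF": (0.03, 0.08)}, rr_jitter_s=0.0)
        rec512, _ = synth_ecg(spec)
        rec256, _ = clean_ecg
        rri256 = compute_rri(detect_rpeaks(rec256.samples, fs=256), 256)
        rri512 = compute_rri(detect_rpeaks(rec512.samples, fs=512), 512)
        n = min(rri256.intervals.size, rri512.intervals.size)
        assert abs(rri256.intervals.size - rri512.intervals.size) <= 1
        np.testing.assert_allclose(rri256.intervals[:n], rri512.intervals[:n],
                                   atol=1 / 256)
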