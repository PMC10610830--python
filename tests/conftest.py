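import numpy as np
import pytest

from hrvemotion.synthetic import SynthSpec, synth_ecg


@pytest.fixture(scope="session")
def clean_ecg():
    """A noise-free 60 s ECG with LF-modulated RR and exact peak truth."""
    spec = SynthSpec(duration=60.0, snr_db=None, seed=3,
                     modulations={"LF": (0.03, 0.08)}, rr_jitter_s=0.0)
    record, peaks = synth_ecg(spec)
    return record, peaks


@pytest.fixture(scope="session")
def noisy_ecg_10db():
    """A 120 s ECG at 10 dB SNR with HR in the 60-80 bpm range."""
    spec = SynthSpec(duration=120.0, snr_db=10.0, seed=1, mean_hr_bpm=70.0,
                     modulations={"LF": (0.03, 0.08), "HF2": (0.02, 0.30)})
    record, peaks = synth_ecg(spec)
    return record, peaks


def match_counts(true_peaks, detected, tol):
    """(true positives, sensitivity, positive predictivity) at +/- tol samples."""
    true_peaks = np.asarray(true_peaks)
    detected = np.asarray(detected)
    tp = sum(1 for p in detected if np.min(np.abs(true_peaks - p)) <= tol)
    sens = tp / true_peaks.size if true_peaks.size else 0.0
    ppv = tp / detected.size if detected.size else 0.0
    return tp, sens, ppv
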