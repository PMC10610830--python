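"""Wavelet denoising of raw ECG with a hard/soft compromise threshold.

The signal is decomposed with a discrete wavelet transform (default sym8,
5 levels, symmetric extension), the noise scale is estimated from the
finest-level detail coefficients, a single global threshold is applied to
all detail levels with a semi-soft shrinkage rule, and the signal is
reconstructed. The approximation branch is left untouched so the large
slow-wave content (baseline, T waves) survives.

Two threshold conventions are supported. ``universal`` is the standard
delta * sqrt(2 ln H) rule; ``as_printed`` is delta * 2 * ln H, which grows
much faster with record length and over-smooths long signals. Similarly the
shrinkage rule defaults to the usual semi-soft form
sign(w) * (|w| - theta/2) for |w| >= theta; a ``literal`` variant
sign(w) * |w - theta/2| is kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import DenoiseParams, ECGRecord


@dataclass
class DenoiseResult:
    denoised: np.ndarray
    theta: float
    delta: float


def estimate_noise_delta(detail_coeffs: np.ndarray) -> float:
    """Noise scale delta = mean(|w|) / 0.6745 from detail coefficients.

    0.6745 is the normal distribution's third-quartile constant; the
    estimate is robust to the sparse large coefficients contributed by QRS
    complexes.
    """
    w = np.asarray(detail_coeffs, dtype=float)
    if w.size == 0:
        raise ValueError("empty coefficient sequence")
    return float(np.mean(np.abs(w)) / 0.6745)


def compute_threshold(delta: float, H: int, mode: str = "universal") -> float:
    """Threshold theta from the noise scale and the signal length H."""
    if H < 2:
        raise ValueError(f"signal length must be >= 2, got {H}")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if mode == "universal":
        return float(delta * np.sqrt(2.0 * np.log(H)))
    if mode == "as_printed":
        return float(delta * 2.0 * np.log(H))
    raise ValueError(f"unknown threshold mode {mode!r}")


def compromise_shrink(w, theta: float, mode: str = "semisoft"):
    """Semi-soft shrinkage: zero below theta, magnitude reduced by theta/2 above.

    Halfway between hard thresholding (which keeps coefficients intact and
    leaves noise spikes) and soft thresholding (which biases large
    coefficients by the full theta). Vectorized over ``w``.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    w = np.asarray(w, dtype=float)
    keep = np.abs(w) >= theta
    if mode == "semisoft":
        shrunk = np.sign(w) * (np.abs(w) - 0.5 * theta)
    elif mode == "literal":
        shrunk = np.sign(w) * np.abs(w - 0.5 * theta)
    else:
        raise ValueError(f"unknown shrink mode {mode!r}")
    return np.where(keep, shrunk, 0.0)


def denoise_ecg(record: ECGRecord, params: DenoiseParams | None = None) -> DenoiseResult:
    """Denoise an ECG record; output has the same length as the input."""
    params = params or DenoiseParams()
    params.validate()
    x = record.samples
    if x.size < 2 ** params.level:
        raise ValueError(
            f"signal of length {x.size} too short for {params.level}-level decomposition"
        )
    coeffs = pywt.wavedec(x, params.wavelet, level=params.level, mode="symmetric")
    # coeffs[0] approximation, coeffs[-1] finest detail
    delta = estimate_noise_delta(coeffs[-1])
    theta = compute_threshold(delta, x.size, mode=params.threshold_mode)
    new_coeffs = [coeffs[0]] + [
        compromise_shrink(c, theta, mode=params.shrink_mode) for c in coeffs[1:]
    ]
    denoised = pywt.waverec(new_coeffs, params.wavelet, mode="symmetric")[: x.size]
    return DenoiseResult(denoised=denoised, theta=theta, delta=delta)
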