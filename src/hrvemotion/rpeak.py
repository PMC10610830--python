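"""R-peak detection by normalized cross-correlation with a half-sine QRS
template, and RR-interval (HRV) series extraction.

The template is sin(t) sampled on [1.5*pi, 3.5*pi]: a symmetric positive
hump flanked by two negative lobes, mimicking the Q-R-S deflection. The
similarity trace is a sliding *normalized* cross-correlation (window and
template mean-removed and unit-normalized), so the detection threshold is
an amplitude-free shape score in [-1, 1]. Contiguous runs of samples whose
similarity exceeds the threshold are candidate QRS groups; each surviving
run yields one peak at its median index. Runs failing a QRS-conformity
check (implausible width, or no locally large signal excursion) are
dropped, and RR intervals outside physiologic bounds are removed together
with the offending beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RPeakParams


@dataclass
class QRSTemplate:
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RPeakResult:
    peak_indices: np.ndarray                       # strictly increasing, samples
    similarity: np.ndarray                         # same length as the signal
    candidate_runs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RRISeries:
    """RR intervals in seconds plus the time of each accepted beat."""

    intervals: np.ndarray          # seconds, len == len(beat_times) - 1
    beat_times: np.ndarray         # seconds

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


def make_qrs_template(n: int = 15) -> QRSTemplate:
    """n samples of sin(t) over [1.5*pi, 3.5*pi], endpoints included."""
    if n < 3:
        raise ValueError(f"template needs >= 3 samples, got {n}")
    t = np.linspace(1.5 * np.pi, 3.5 * np.pi, n)
    return QRSTemplate(values=np.sin(t))


def similarity_trace(signal: np.ndarray, template: QRSTemplate) -> np.ndarray:
    """Sliding normalized cross-correlation, centered alignment.

    Output index i scores the window centered at sample i (template length
    is odd by default; for even lengths the window starts at i - n//2).
    Windows with zero variance score 0. Edge positions where the full
    window does not fit score 0.
    """
    x = np.asarray(signal, dtype=float)
    n = len(template)
    if x.size < n:
        raise ValueError(f"signal ({x.size}) shorter than template ({n})")
    tpl = template.values - template.values.mean()
    tnorm = np.linalg.norm(tpl)
    windows = np.lib.stride_tricks.sliding_window_view(x, n)
    wmean = windows.mean(axis=1, keepdims=True)
    centered = windows - wmean
    wnorm = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = centered @ tpl / (wnorm * tnorm)
    corr[~np.isfinite(corr)] = 0.0
    out = np.zeros_like(x)
    half = n // 2
    out[half : half + corr.size] = corr
    return out


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, idx.size, 2)]


def detect_rpeaks(
    signal: np.ndarray,
    template: QRSTemplate | None = None,
    params: RPeakParams | None = None,
    fs: float | None = None,
) -> RPeakResult:
    """Detect R-peaks in a (denoised) ECG signal.

    Each contiguous run of similarity > threshold is a candidate QRS group;
    the peak is placed at the run's median index (lower median for
    even-length runs). Conformity filter: run length within
    [min_run, max_run_factor * template length]; the signal's local maximum
    inside the run at least ``amp_fraction`` of the record's
    ``amp_percentile``-th absolute-amplitude percentile; and, when ``fs``
    is given, a ``refractory_s`` non-maximum suppression that keeps only
    the largest-amplitude candidate among any closer than the refractory
    interval (T waves can satisfy both shape and amplitude criteria, but
    always fall inside the refractory window of their QRS).
    """
    params = params or RPeakParams()
    params.validate()
    if template is None:
        template = make_qrs_template(params.template_len)
    x = np.asarray(signal, dtype=float)
    simi = similarity_trace(x, template)
    runs = _runs_above(simi > params.threshold)
    amp_floor = params.amp_fraction * np.percentile(np.abs(x), params.amp_percentile)
    max_run = int(params.max_run_factor * len(template))
    candidates = []  # (peak index, run, local max amplitude)
    for start, stop in runs:
        length = stop - start
        if length < params.min_run or length > max_run:
            continue
        local_max = x[start:stop].max()
        if local_max < amp_floor:
            continue
        idx = np.arange(start, stop)
        peak = int(idx[(len(idx) - 1) // 2])  # lower median
        candidates.append((peak, (start, stop), float(local_max)))
    if fs is not None and params.refractory_s > 0 and candidates:
        refractory = params.refractory_s * fs
        kept: list = []
        for cand in candidates:
            if kept and cand[0] - kept[-1][0] < refractory:
                if cand[2] > kept[-1][2]:
                    kept[-1] = cand
            else:
                kept.append(cand)
        candidates = kept
    return RPeakResult(
        peak_indices=np.asarray([c[0] for c in candidates], dtype=np.int64),
        similarity=simi,
        candidate_runs=[c[1] for c in candidates],
    )


def compute_rri(
    peaks: RPeakResult | np.ndarray,
    fs: float,
    bounds: tuple[float, float] = (0.3, 2.0),
) -> RRISeries:
    """Successive R-peak differences in seconds, with plausibility filtering.

    An interval outside [min_s, max_s] is removed together with the beat
    that produced it (spurious extra detections make too-short intervals;
    artifacts make too-long ones), scanning left to right. All surviving
    intervals lie within bounds and number exactly ``n_beats - 1``.
    """
    idx = peaks.peak_indices if isinstance(peaks, RPeakResult) else np.asarray(peaks)
    if idx.size < 2:
        raise ValueError("need at least 2 peaks to form an interval")
    if fs <= 0:
        raise ValueError("fs must be positive")
    lo, hi = bounds
    times = np.asarray(idx, dtype=float) / fs
    accepted = [times[0]]
    for t in times[1:]:
        rr = t - accepted[-1]
        if lo <= rr <= hi:
            accepted.append(t)
    beat_times = np.asarray(accepted)
    return RRISeries(intervals=np.diff(beat_times), beat_times=beat_times)
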