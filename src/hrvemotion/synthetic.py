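"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, all deterministic under a seed:

* ``synth_ecg`` — an integrate-and-fire beat model whose instantaneous RR
  interval is a mean plus band-limited sinusoids (the autonomic LF/HF
  modulations); each beat is stamped with a QRS-like half-sine wavelet
  plus smaller P and T bumps, and white noise is added at a chosen SNR.
  Exact R-peak sample indices are returned.
* ``synth_level_corpus`` — symbolic level sequences with known patterns
  planted into chosen emotions' bands at a chosen rate, for mining tests.
* ``synth_labeled_dataset`` — a labeled multi-class ECG corpus in which
  each emotion carries a distinct profile of per-band RR modulation
  amplitudes, strong enough for the full pipeline to separate classes.

The ECG morphology is deliberately simple (symmetric QRS, Gaussian P/T):
realistic enough to exercise template detection non-trivially, not an
electrophysiological simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alq import LEVELS, LevelSequence, sliding_subsequences
from .bands import BAND_NAMES
from .io import ECGRecord
from .rpeak import make_qrs_template
from .rules import Transaction

# band-center modulation frequencies (Hz) used by the labeled generator
BAND_TONE_HZ = {"LF": 0.08, "HF1": 0.20, "HF2": 0.30, "HF3": 0.38}


@dataclass
class SynthSpec:
    """Study conditions for the synthetic generators.

    Defaults describe a 120 s single-lead recording at 256 Hz, 70 bpm mean
    heart rate, RR modulated by one sinusoid per band (driven-band
    amplitude 50 ms, background bands 12 ms), white noise at 20 dB SNR,
    and a small beat-to-beat RR jitter (3 ms) that spreads energy across
    all bands.
    """

    duration: float = 120.0
    fs: float = 256.0
    mean_hr_bpm: float = 70.0
    # band -> (modulation amplitude in s, frequency in Hz)
    modulations: dict = field(default_factory=dict)
    rr_jitter_s: float = 0.003
    snr_db: float | None = 20.0
    qrs_amp: float = 1.0
    p_amp: float = 0.15
    t_amp: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        mean_rr = 60.0 / self.mean_hr_bpm
        total_mod = sum(a for a, _f in self.modulations.values())
        if mean_rr - total_mod <= 0.1:
            raise ValueError("modulation amplitudes drive RR non-positive")
        if self.duration * self.mean_hr_bpm / 60.0 < 10:
            raise ValueError("spec yields fewer than 10 beats")
        for band, (_a, f) in self.modulations.items():
            if band in BAND_NAMES:
                from .bands import BAND_EDGES
                lo, hi = BAND_EDGES[band]
                if not lo <= f < hi:
                    raise ValueError(
                        f"{band} modulation frequency {f} Hz outside [{lo}, {hi})")


def _beat_times(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Iterated interval model: t_{k+1} = t_k + RR(t_k)."""
    mean_rr = 60.0 / spec.mean_hr_bpm
    mods = [(a, f, rng.uniform(0, 2 * np.pi)) for a, f in spec.modulations.values()]
    times = [0.5]  # first beat away from the record edge
    while True:
        t = times[-1]
        rr = mean_rr + sum(a * np.sin(2 * np.pi * f * t + ph) for a, f, ph in mods)
        if spec.rr_jitter_s > 0:
            rr += rng.normal(0.0, spec.rr_jitter_s)
        rr = max(rr, 0.2)
        nxt = t + rr
        if nxt >= spec.duration - 0.5:
            break
        times.append(nxt)
    return np.asarray(times)


def synth_ecg(
    spec: SynthSpec | None = None, rng: np.random.Generator | None = None,
) -> tuple[ECGRecord, np.ndarray]:
    """Synthesize one ECG record; returns (record, true R-peak indices)."""
    spec = spec or SynthSpec()
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    x = np.zeros(n)
    beats = _beat_times(spec, rng)
    # QRS stamp: the half-sine template scaled to ~58 ms at any rate
    tpl_len = int(round(spec.fs * 15 / 256))
    tpl_len += 1 - tpl_len % 2  # odd length so the crest is a single sample
    tpl = make_qrs_template(max(tpl_len, 7)).values
    half = tpl.size // 2
    peak_indices = []
    for tb in beats:
        center = int(round(tb * spec.fs))
        start = center - half
        stop = start + tpl.size
        if start < 0 or stop > n:
            continue
        x[start:stop] += spec.qrs_amp * tpl
        peak_indices.append(center)
    # P and T bumps around each stamped beat
    idx = np.arange(n)
    for tb in beats:
        center = int(round(tb * spec.fs))
        if center - half < 0 or center + half >= n:
            continue
        for offset_s, width_s, amp in ((-0.18, 0.025, spec.p_amp),
                                       (0.22, 0.05, spec.t_amp)):
            c = center + offset_s * spec.fs
            lo = max(0, int(c - 4 * width_s * spec.fs))
            hi = min(n, int(c + 4 * width_s * spec.fs) + 1)
            if lo < hi:
                x[lo:hi] += amp * np.exp(
                    -0.5 * ((idx[lo:hi] - c) / (width_s * spec.fs)) ** 2)
    if spec.snr_db is not None and np.isfinite(spec.snr_db):
        p_signal = float(np.mean(x ** 2))
        p_noise = p_signal / 10 ** (spec.snr_db / 10)
        x = x + rng.normal(0.0, np.sqrt(p_noise), size=n)
    record = ECGRecord(x, fs=spec.fs, subject_id="synth",
                       stimulus_id=f"seed{spec.seed}")
    return record, np.asarray(peak_indices, dtype=np.int64)


def synth_level_corpus(
    planted: dict[str, dict[str, tuple[tuple[str, ...], float]]],
    n_recordings: int = 50,
    seq_len: int = 40,
    window_lengths=(2, 3, 4, 5),
    seed: int = 0,
) -> tuple[dict[str, dict[str, list[Transaction]]], list[dict]]:
    """Symbolic corpora with planted patterns.

    ``planted`` maps emotion -> band -> (symbol tuple, insertion rate);
    every emotion gets ``n_recordings`` i.i.d.-uniform background sequences
    per band, and its pattern overwrites a random stretch of the sequence
    in a ``rate`` fraction of recordings (lengths preserved). Returns the
    per-emotion per-band transactions plus a ground-truth rule list.
    """
    rng = np.random.default_rng(seed)
    bands = sorted({b for spec in planted.values() for b in spec})
    corpora: dict[str, dict[str, list[Transaction]]] = {}
    truth = []
    for emotion in sorted(planted):
        corpora[emotion] = {}
        for band in bands:
            transactions = []
            pattern_rate = planted[emotion].get(band)
            for _ in range(n_recordings):
                symbols = list(rng.choice(list(LEVELS), size=seq_len))
                if pattern_rate is not None:
                    pattern, rate = pattern_rate
                    if rng.random() < rate:
                        pos = rng.integers(0, seq_len - len(pattern) + 1)
                        symbols[pos : pos + len(pattern)] = list(pattern)
                seq = LevelSequence("".join(symbols), band=band,
                                    emotion_label=emotion)
                transactions.append(bag_to_transaction(
                    sliding_subsequences(seq, window_lengths), emotion))
            corpora[emotion][band] = transactions
            if pattern_rate is not None:
                truth.append({"emotion": emotion, "band": band,
                              "pattern": tuple(pattern_rate[0]),
                              "rate": pattern_rate[1]})
    return corpora, truth


def bag_to_transaction(bag, emotion: str | None = None) -> Transaction:
    """A recording/band bag as a mining transaction with adjacency pairs."""
    pairs = set()
    for L, windows in bag.ordered.items():
        for a, b in zip(windows[:-1], windows[1:]):
            pairs.add((a, b))
    items = frozenset(bag.items)
    if not items:
        items = frozenset({("F",) * 2})  # degenerate recording: sentinel window
    return Transaction(items=items, emotion_label=emotion,
                       adjacent_pairs=frozenset(pairs))


def class_signatures(
    emotions: tuple[str, ...],
    strong_amp_s: float = 0.05,
    weak_amp_s: float = 0.012,
) -> dict[str, dict[str, tuple[float, float]]]:
    """One distinct dominant band per emotion, cycling through the 4 bands."""
    out = {}
    for k, emotion in enumerate(emotions):
        strong = BAND_NAMES[k % len(BAND_NAMES)]
        out[emotion] = {
            band: ((strong_amp_s if band == strong else weak_amp_s),
                   BAND_TONE_HZ[band])
            for band in BAND_NAMES
        }
    return out


def synth_labeled_dataset(
    emotions: tuple[str, ...] = ("joy", "anger", "sadness", "relaxation"),
    n_per_class: int = 50,
    duration: float = 120.0,
    fs: float = 256.0,
    snr_db: float | None = 20.0,
    seed: int = 0,
    signatures: dict | None = None,
) -> tuple[list[ECGRecord], list[str]]:
    """A balanced labeled ECG corpus with per-emotion band signatures."""
    if len(emotions) < 2:
        raise ValueError("need at least 2 emotions")
    rng = np.random.default_rng(seed)
    signatures = signatures or class_signatures(emotions)
    records: list[ECGRecord] = []
    labels: list[str] = []
    for emotion in emotions:
        for i in range(n_per_class):
            spec = SynthSpec(
                duration=duration, fs=fs,
                mean_hr_bpm=float(rng.uniform(65, 75)),
                modulations=dict(signatures[emotion]),
                snr_db=snr_db,
                seed=seed,
            )
            rec, _peaks = synth_ecg(spec, rng=rng)
            rec.subject_id = f"{emotion}{i:03d}"
            rec.stimulus_id = emotion
            records.append(rec)
            labels.append(emotion)
    return records, labels
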