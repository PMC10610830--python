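"""Amplitude level quantization (ALQ): symbolic encoding of band-signal
extrema.

Each band signal is reduced to the sequence of its crest/trough amplitudes
(signed values at local maxima and minima). Each amplitude is then mapped
to one of six levels by its magnitude relative to the band's maximum
absolute amplitude Amax:

    A  [0.8, 1.0]   B  [0.6, 0.8)   C  [0.4, 0.6)
    D  [0.2, 0.4)   E  [0.1, 0.2)   F  [0.0, 0.1)

(half-open bins, top bin closed, so every ratio in [0, 1] gets a symbol).
Sliding windows of lengths 2-5 over the level sequence produce the
subsequence bag that feeds rule mining and feature matching.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

LEVELS = "ABCDEF"
# lower bin edges for A..F in order of decreasing magnitude
_BIN_LOWER = (0.8, 0.6, 0.4, 0.2, 0.1, 0.0)


@dataclass
class ExtremaSequence:
    amplitudes: np.ndarray      # signed values, alternating crest/trough
    amax: float                 # max |amplitude|, 0 for an empty sequence


@dataclass
class LevelSequence:
    symbols: str
    band: str = ""
    emotion_label: str | None = None

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class SubsequenceBag:
    """Multiset of sliding-window symbol tuples from one level sequence.

    ``ordered`` keeps, per window length, the tuples in start-position
    order; adjacency (consecutive start positions) is needed for
    potential-rule mining. ``total`` is the window count LE.
    """

    items: Counter = field(default_factory=Counter)
    ordered: dict[int, list[tuple[str, ...]]] = field(default_factory=dict)
    total: int = 0
    band: str = ""

    def distinct(self) -> set[tuple[str, ...]]:
        return set(self.items)


def extract_extrema(samples: np.ndarray, band: str = "") -> ExtremaSequence:
    """Crest/trough amplitudes: values where the first difference changes sign.

    Plateaus contribute a single extremum at the plateau midpoint. A
    constant (or monotone) signal yields an empty sequence.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return ExtremaSequence(amplitudes=np.empty(0), amax=0.0)
    d = np.diff(x)
    sign = np.sign(d)
    # indices and signs of nonzero slopes; zeros (plateaus) are bridged
    nz = np.flatnonzero(sign)
    amps: list[float] = []
    kinds: list[int] = []  # +1 crest, -1 trough
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            # extremum on the (possibly flat) stretch between slopes a and b
            idx = (a + 1 + b) // 2  # midpoint of plateau [a+1, b]
            kind = 1 if sign[a] > 0 else -1
            amps.append(float(x[idx]))
            kinds.append(kind)
    # merge consecutive same-type extrema, keeping the larger magnitude
    merged_a: list[float] = []
    merged_k: list[int] = []
    for amp, kind in zip(amps, kinds):
        if merged_k and merged_k[-1] == kind:
            if abs(amp) > abs(merged_a[-1]):
                merged_a[-1] = amp
        else:
            merged_a.append(amp)
            merged_k.append(kind)
    arr = np.asarray(merged_a)
    amax = float(np.max(np.abs(arr))) if arr.size else 0.0
    return ExtremaSequence(amplitudes=arr, amax=amax)


def quantize_symbol(ratio: float) -> str:
    """Map a magnitude ratio in [0, 1] to its level symbol."""
    if not 0 <= ratio <= 1 + 1e-12:
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    for symbol, lower in zip(LEVELS, _BIN_LOWER):
        if ratio >= lower:
            return symbol
    return "F"


def quantize_levels(
    ex: ExtremaSequence, band: str = "", emotion_label: str | None = None,
    encode_polarity: bool = False,
) -> LevelSequence:
    """Quantize extrema magnitudes relative to Amax into the A-F alphabet.

    An empty extrema sequence yields an empty level sequence. With
    ``encode_polarity`` each symbol carries a +/- suffix for crest/trough
    (off by default; the level alone follows |amplitude|).
    """
    if ex.amplitudes.size == 0:
        return LevelSequence(symbols="", band=band, emotion_label=emotion_label)
    if ex.amax <= 0:
        raise ValueError("Amax must be positive for a non-empty sequence")
    ratios = np.abs(ex.amplitudes) / ex.amax
    symbols = []
    for r, a in zip(ratios, ex.amplitudes):
        s = quantize_symbol(min(float(r), 1.0))
        if encode_polarity:
            s += "+" if a >= 0 else "-"
        symbols.append(s)
    return LevelSequence(symbols="".join(symbols), band=band,
                         emotion_label=emotion_label)


def sliding_subsequences(
    seq: LevelSequence | str, lengths: Iterable[int] = (2, 3, 4, 5),
) -> SubsequenceBag:
    """All contiguous windows of the given lengths, stride 1.

    LE (``total``) = sum over lengths L of max(0, len(seq) - L + 1).
    """
    symbols: Sequence[str]
    band = ""
    if isinstance(seq, LevelSequence):
        symbols, band = seq.symbols, seq.band
    else:
        symbols = seq
    bag = SubsequenceBag(band=band)
    for L in sorted(set(lengths)):
        windows = [tuple(symbols[i : i + L]) for i in range(len(symbols) - L + 1)]
        bag.ordered[L] = windows
        bag.items.update(windows)
        bag.total += len(windows)
    return bag
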