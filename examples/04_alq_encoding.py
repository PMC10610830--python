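"""Amplitude level quantization: band signal -> A-F symbol sequence.

Extrema of a band signal are quantized by magnitude relative to the band
maximum, then cut into sliding windows of lengths 2-5.
"""

import numpy as np

from hrvemotion import extract_extrema, quantize_levels, sliding_subsequences

t = np.linspace(0, 10, 400)
band = np.sin(2 * np.pi * 0.5 * t) * (0.3 + 0.7 * np.exp(-0.2 * t))

extrema = extract_extrema(band, band="HF1")
levels = quantize_levels(extrema, band="HF1")
bag = sliding_subsequences(levels, lengths=(2, 3, 4, 5))

print(f"{extrema.amplitudes.size} extrema, Amax = {extrema.amax:.3f}")
print(f"level sequence: {levels.symbols}")
print(f"windows: LE = {bag.total} "
      f"({len(bag.distinct())} distinct patterns)")
print("Early crests sit near Amax (symbol A); as the envelope decays the")
print("symbols walk down the alphabet. The window bag is what rule mining")
print("and feature matching consume.")
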