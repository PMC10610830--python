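"""Quantize valence-arousal ratings to the 17 named emotions.

Shows nearest-neighbor label assignment and the semantic-distance
diagnostic that flags confusable emotion pairs.
"""

from hrvemotion.emotions import (
    confusable_pairs,
    default_map,
    quantize_emotion,
    rescale_rating,
)

emap = default_map()

# a DREAMER-style rating on the 1-5 scale
valence_raw, arousal_raw = 4.5, 3.8
v = rescale_rating(valence_raw, (1, 5))
a = rescale_rating(arousal_raw, (1, 5))
label = quantize_emotion(v, a, emap)
print(f"rating (valence {valence_raw}, arousal {arousal_raw}) on 1-5 "
      f"-> ({v:+.2f}, {a:+.2f}) on [-1, 1] -> {label!r}")

print("\nconfusable pairs (distance < 0.25):")
for x, y, d in confusable_pairs(emap, threshold=0.25):
    print(f"  {x} - {y}: {d:.2f}")
print("Close pairs are where nearest-neighbor labels (and hence the")
print("classifier) most easily confuse one emotion with another.")
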