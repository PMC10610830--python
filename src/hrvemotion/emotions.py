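"""Mapping valence-arousal self-ratings to named emotions.

Seventeen emotion categories are placed in the two-dimensional
valence-arousal (circumplex) space; a rating is quantized to the nearest
emotion by Euclidean distance. The coordinates shipped here are a
synthetic, approximate circumplex placement on [-1, 1]^2 intended for
testing and as a template — studies should supply their own map (CSV with
``name,valence,arousal`` columns) calibrated to their stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EMOTION_NAMES = (
    "surprise", "sadness", "anxiety", "passion", "joy", "shame", "hope",
    "tired", "fear", "disgust", "anger", "gratitude", "intimacy", "trust",
    "pain", "confidence", "relaxation",
)

# Synthetic approximate circumplex placement (valence, arousal) on [-1, 1]^2.
_DEFAULT_COORDS = {
    "surprise": (0.40, 0.85),
    "passion": (0.75, 0.75),
    "joy": (0.85, 0.55),
    "anger": (-0.75, 0.75),
    "fear": (-0.70, 0.60),
    "anxiety": (-0.55, 0.45),
    "disgust": (-0.80, 0.35),
    "pain": (-0.85, 0.10),
    "shame": (-0.55, -0.25),
    "sadness": (-0.70, -0.45),
    "tired": (-0.25, -0.70),
    "hope": (0.55, 0.30),
    "gratitude": (0.60, 0.10),
    "confidence": (0.72, -0.08),
    "trust": (0.65, -0.30),
    "intimacy": (0.50, -0.50),
    "relaxation": (0.40, -0.65),
}


@dataclass
class EmotionMap:
    entries: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("emotion map must be non-empty")
        for name, (v, a) in self.entries.items():
            if not (np.isfinite(v) and np.isfinite(a)):
                raise ValueError(f"non-finite coordinates for {name!r}")

    @property
    def names(self) -> list[str]:
        return sorted(self.entries)


def default_map() -> EmotionMap:
    """The shipped 17-emotion test map (synthetic placements, see module doc)."""
    return EmotionMap(dict(_DEFAULT_COORDS))


def load_map(path: str | Path) -> EmotionMap:
    df = pd.read_csv(path)
    entries = {str(r["name"]): (float(r["valence"]), float(r["arousal"]))
               for _, r in df.iterrows()}
    if len(entries) != len(df):
        raise ValueError("duplicate emotion names in map")
    return EmotionMap(entries)


def save_map(emap: EmotionMap, path: str | Path) -> None:
    rows = [{"name": n, "valence": v, "arousal": a}
            for n, (v, a) in sorted(emap.entries.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def quantize_emotion(valence: float, arousal: float, emap: EmotionMap) -> str:
    """Nearest emotion by Euclidean distance; ties break alphabetically."""
    best_name = None
    best_d = np.inf
    for name in emap.names:  # alphabetical: first hit wins ties
        v, a = emap.entries[name]
        d = (valence - v) ** 2 + (arousal - a) ** 2
        if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and best_name is None):
            best_d = d
            best_name = name
    return best_name


def rescale_rating(
    value: float, source_range: tuple[float, float],
    target_range: tuple[float, float] = (-1.0, 1.0),
) -> float:
    """Affine rescale of a rating (e.g. a 1-5 scale) onto the map's range."""
    s0, s1 = source_range
    t0, t1 = target_range
    if s1 == s0:
        raise ValueError("degenerate source range")
    return t0 + (value - s0) * (t1 - t0) / (s1 - s0)


def pairwise_semantic_distance(emap: EmotionMap) -> pd.DataFrame:
    """Symmetric table of Euclidean distances between emotion coordinates."""
    names = emap.names
    coords = np.asarray([emap.entries[n] for n in names])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return pd.DataFrame(dist, index=names, columns=names)


def confusable_pairs(
    emap: EmotionMap, threshold: float = 0.25,
) -> list[tuple[str, str, float]]:
    """Emotion pairs closer than the threshold — likely to be confused.

    Semantically close pairs (e.g. gratitude vs confidence at distance
    ~0.22 in the shipped map) are where classification errors concentrate.
    """
    table = pairwise_semantic_distance(emap)
    names = list(table.index)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float(table.loc[a, b])
            if d < threshold:
                out.append((a, b, d))
    return sorted(out, key=lambda t: t[2])
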