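"""ALQ feature extraction: matching windowed symbol sequences against the
standard rule set.

Per band, four statistics summarize how strongly a recording's symbolic
amplitude patterns resemble the mined rules:

    MA  match count: windows equal to some rule pattern (each occurrence)
    TC  total strength: sum of matched rules' strengths over occurrences
    FR  match frequency: MA / LE (LE = total window count)
    PR  polynomial rate: distinct matched patterns of length >= 2 / MA

Across the four bands (LF, HF1, HF2, HF3) this yields the 16-dimensional
feature vector fed to the classifier. Column order is fixed:
LF_MA, LF_TC, LF_FR, LF_PR, HF1_MA, ..., HF3_PR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alq import SubsequenceBag
from .bands import BAND_NAMES
from .rules import RuleSet

FEATURE_STATS = ("MA", "TC", "FR", "PR")
FEATURE_COLUMNS = tuple(f"{band}_{stat}" for band in BAND_NAMES
                        for stat in FEATURE_STATS)


@dataclass
class BandFeatures:
    MA: int
    TC: float
    FR: float
    PR: float


def match_features(
    bag: SubsequenceBag, ruleset: RuleSet, pr_mode: str = "distinct",
) -> BandFeatures:
    """Match one band's window bag against one band's rule set.

    A window occurrence matches a rule iff its tuple belongs to the rule's
    pattern itemset; an occurrence matching several rules counts once in MA
    but contributes every matched strength to TC. ``pr_mode`` selects the
    polynomial-rate definition: ``distinct`` (default) counts distinct
    matched patterns of length >= 2; ``length_sum`` uses the alternative
    sum over lengths of (count at length i - count at the shortest length).
    0/0 cases yield FR = PR = 0.
    """
    if ruleset.band and bag.band and ruleset.band != bag.band:
        raise ValueError(f"band mismatch: bag {bag.band!r} vs rules {ruleset.band!r}")
    # index: window tuple -> summed strength of all rules it matches
    strength_of: dict[tuple, float] = {}
    for rule in ruleset.rules:
        for pattern in rule.match_patterns():
            strength_of[pattern] = strength_of.get(pattern, 0.0) + rule.strength
    ma = 0
    tc = 0.0
    matched_long: set[tuple] = set()
    matched_len_counts: dict[int, int] = {}
    for window, count in bag.items.items():
        s = strength_of.get(window)
        if s is None:
            continue
        ma += count
        tc += s * count
        if len(window) >= 2:
            matched_long.add(window)
        matched_len_counts[len(window)] = (
            matched_len_counts.get(len(window), 0) + count)
    le = bag.total
    fr = ma / le if le > 0 else 0.0
    if ma == 0:
        pr = 0.0
    elif pr_mode == "distinct":
        pr = len(matched_long) / ma
    elif pr_mode == "length_sum":
        base = matched_len_counts.get(1, 0)  # matched singleton windows
        pr = sum(matched_len_counts[L] - base for L in sorted(matched_len_counts)) / ma
    else:
        raise ValueError(f"unknown pr_mode {pr_mode!r}")
    return BandFeatures(MA=ma, TC=tc, FR=fr, PR=pr)


def match_features_naive(bag: SubsequenceBag, ruleset: RuleSet) -> BandFeatures:
    """Literal double-loop matching (reference oracle; O(windows x rules))."""
    ma = 0
    tc = 0.0
    matched_long: set[tuple] = set()
    windows = [w for L in sorted(bag.ordered) for w in bag.ordered[L]]
    if not windows:  # bag built without ordered lists
        windows = [w for w, c in bag.items.items() for _ in range(c)]
    for window in windows:
        hit = False
        for rule in ruleset.rules:
            if window in rule.match_patterns():
                hit = True
                tc += rule.strength
        if hit:
            ma += 1
            if len(window) >= 2:
                matched_long.add(window)
    le = bag.total
    return BandFeatures(
        MA=ma, TC=tc,
        FR=ma / le if le else 0.0,
        PR=len(matched_long) / ma if ma else 0.0,
    )


def feature_vector(per_band: dict[str, BandFeatures]) -> np.ndarray:
    """Flatten per-band features into the fixed 16-column order."""
    missing = [b for b in BAND_NAMES if b not in per_band]
    if missing:
        raise ValueError(f"missing band(s): {missing}")
    out = []
    for band in BAND_NAMES:
        f = per_band[band]
        out.extend([f.MA, f.TC, f.FR, f.PR])
    return np.asarray(out, dtype=float)


def build_feature_matrix(
    recordings: list[dict[str, SubsequenceBag]],
    rulesets: dict[str, RuleSet],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """One 16-feature row per recording, with an optional ``label`` column.

    ``recordings`` maps band name -> SubsequenceBag per recording;
    ``rulesets`` maps band name -> the standard RuleSet for that band.
    """
    rows = []
    for bags in recordings:
        per_band = {}
        for band in BAND_NAMES:
            if band not in bags:
                raise ValueError(f"recording missing band {band!r}")
            per_band[band] = match_features(bags[band], rulesets[band])
        rows.append(feature_vector(per_band))
    df = pd.DataFrame(np.asarray(rows).reshape(-1, len(FEATURE_COLUMNS)),
                      columns=list(FEATURE_COLUMNS))
    if labels is not None:
        df["label"] = list(labels)
    return df
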