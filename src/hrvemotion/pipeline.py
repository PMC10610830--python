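"""End-to-end orchestration: raw ECG corpus -> emotion classification.

The stages, in order: wavelet denoising, template R-peak detection, RR
plausibility filtering, 4 Hz spline resampling, wavelet-packet band split,
extrema quantization to the A-F alphabet, sliding-window subsequence bags,
per-emotion rule mining with universal-rule removal (on the training
recordings only, so no label information leaks into test features), ALQ
feature matching, and logistic-regression evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alq import extract_extrema, quantize_levels, sliding_subsequences
from .bands import BAND_NAMES, decompose_bands, resample_rri
from .classify import EvalReport, train_and_evaluate
from .denoise import denoise_ecg
from .features import build_feature_matrix
from .io import ECGRecord, PipelineConfig
from .rpeak import compute_rri, detect_rpeaks, make_qrs_template
from .rules import RuleSet, filter_universal, mine_emotion_rules
from .synthetic import bag_to_transaction


def process_recording(record: ECGRecord, config: PipelineConfig | None = None):
    """One recording -> per-band subsequence bags (dict band -> bag)."""
    config = config or PipelineConfig()
    den = denoise_ecg(record, config.denoise)
    template = make_qrs_template(config.rpeak.template_len)
    peaks = detect_rpeaks(den.denoised, template, config.rpeak, fs=record.fs)
    rri = compute_rri(peaks, record.fs,
                      bounds=(config.rpeak.rr_min_s, config.rpeak.rr_max_s))
    uniform = resample_rri(rri, fs_u=config.bands.fs_resample)
    band_signals = decompose_bands(uniform, config.bands)
    bags = {}
    for band in BAND_NAMES:
        ex = extract_extrema(band_signals[band].samples, band=band)
        seq = quantize_levels(ex, band=band,
                              encode_polarity=config.alq.encode_polarity)
        bags[band] = sliding_subsequences(seq, config.alq.window_lengths)
    return bags


def mine_rulesets(
    bags_per_recording: list[dict],
    labels: list[str],
    config: PipelineConfig | None = None,
) -> dict[str, RuleSet]:
    """Per-band standard rule sets from a labeled corpus of bags."""
    config = config or PipelineConfig()
    m = config.mining
    emotions = sorted(set(labels))
    rulesets = {}
    for band in BAND_NAMES:
        per_emotion = {}
        for emotion in emotions:
            transactions = [
                bag_to_transaction(bags[band], emotion)
                for bags, lab in zip(bags_per_recording, labels) if lab == emotion
            ]
            per_emotion[emotion] = mine_emotion_rules(
                transactions,
                min_support=m.min_support,
                min_reliability=m.min_reliability,
                correlation_threshold=m.correlation_threshold,
                correlation_mode=m.correlation_mode,
                max_itemset_size=m.max_itemset_size,
            )
        rulesets[band] = filter_universal(per_emotion, emotions, band=band)
    return rulesets


@dataclass
class ExperimentResult:
    report: EvalReport
    rulesets: dict
    feature_matrix: "object"        # pandas DataFrame, all recordings
    train_indices: np.ndarray
    test_indices: np.ndarray


def run_experiment(
    records: list[ECGRecord],
    labels: list[str],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Full train/test experiment on a labeled ECG corpus.

    Recordings are stratified-split by label; rules are mined on the
    training portion only; features for all recordings are matched against
    those rules; the classifier is fit on train and scored on test.
    """
    config = config or PipelineConfig()
    bags = [process_recording(r, config) for r in records]
    return run_experiment_from_bags(bags, labels, config, seed=seed)


def run_experiment_from_bags(
    bags: list[dict],
    labels: list[str],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """As :func:`run_experiment`, starting from per-recording band bags.

    Useful when the signal-processing front end is shared between several
    label assignments (e.g. a shuffled-label control).
    """
    from sklearn.model_selection import train_test_split

    config = config or PipelineConfig()
    labels_arr = np.asarray(labels)
    indices = np.arange(len(bags))
    train_idx, test_idx = train_test_split(
        indices, train_size=config.classifier.train_fraction,
        stratify=labels_arr, random_state=seed)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    rulesets = mine_rulesets([bags[i] for i in train_idx],
                             list(labels_arr[train_idx]), config)
    df = build_feature_matrix(bags, rulesets, labels=list(labels_arr))
    X = df.drop(columns="label").to_numpy()
    y = df["label"].to_numpy()
    params = config.classifier
    params.seed = seed
    report = train_and_evaluate(X[train_idx], y[train_idx],
                                X[test_idx], y[test_idx], params=params)
    return ExperimentResult(report=report, rulesets=rulesets,
                            feature_matrix=df,
                            train_indices=train_idx, test_indices=test_idx)
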