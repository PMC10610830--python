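"""Reading ECG signals and affect ratings; pipeline configuration.

Supports plain CSV (one signal per column) and MAT v5 containers following
the DREAMER layout (per-subject structs holding per-film-clip ECG arrays and
valence/arousal/dominance self-ratings, ECG sampled at 256 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import yaml

DREAMER_FS = 256.0


@dataclass
class ECGRecord:
    """A uniformly sampled single-lead ECG trace.

    Amplitudes are stored as float64 regardless of source precision; sample
    index ``i`` corresponds to time ``i / fs`` seconds.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("ECG record needs a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite ECG sample at index {bad}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RatingRecord:
    """A valence/arousal (optionally dominance) self-rating for one stimulus."""

    subject_id: str
    stimulus_id: str
    valence: float
    arousal: float
    dominance: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.valence) and np.isfinite(self.arousal)):
            raise ValueError("valence/arousal must be finite")


@dataclass
class DenoiseParams:
    wavelet: str = "sym8"
    level: int = 5
    # "universal": theta = delta*sqrt(2 ln H); "as_printed": theta = delta*2*ln H
    threshold_mode: str = "universal"
    # "semisoft": sign(w)(|w|-0.5*theta); "literal": sign(w)*|w-0.5*theta|
    shrink_mode: str = "semisoft"

    def validate(self) -> None:
        if self.threshold_mode not in ("universal", "as_printed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.shrink_mode not in ("semisoft", "literal"):
            raise ValueError(f"unknown shrink_mode {self.shrink_mode!r}")
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")


@dataclass
class RPeakParams:
    template_len: int = 15
    threshold: float = 0.3          # similarity threshold TH
    rr_min_s: float = 0.3           # plausibility bounds: 30-200 bpm
    rr_max_s: float = 2.0
    min_run: int = 2                # QRS-conformity: run length bounds
    max_run_factor: float = 2.0     # max run = factor * template length
    amp_fraction: float = 0.4       # of the record's 98th-percentile amplitude
    amp_percentile: float = 98.0
    refractory_s: float = 0.25      # non-max suppression window (needs fs)

    def validate(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("similarity threshold must be in (0, 1)")
        if not 0 < self.rr_min_s < self.rr_max_s:
            raise ValueError("need 0 < rr_min_s < rr_max_s")
        if self.template_len < 3:
            raise ValueError("template length must be >= 3")


@dataclass
class BandParams:
    fs_resample: float = 4.0
    wavelet: str = "db10"
    level: int | None = None        # None: smallest level with node bw <= 0.05 Hz
    max_level: int = 12
    beat_domain: bool = False       # decompose raw per-beat RRI (edges in cycles/beat)

    def validate(self) -> None:
        if self.fs_resample < 1:
            raise ValueError("resample rate must be >= 1 Hz")
        if self.fs_resample <= 2 * 0.4:
            raise ValueError("resample rate must exceed twice the 0.4 Hz band edge")


@dataclass
class ALQParams:
    window_lengths: tuple[int, ...] = (2, 3, 4, 5)
    encode_polarity: bool = False

    def validate(self) -> None:
        if any(w < 1 for w in self.window_lengths):
            raise ValueError("window lengths must be positive")


@dataclass
class MiningParams:
    min_support: float = 0.10
    min_reliability: float = 0.60
    correlation_threshold: float = 0.30
    correlation_mode: str = "joint"  # or "lift"
    max_itemset_size: int | None = 2

    def validate(self) -> None:
        if not 0 < self.min_support <= 1:
            raise ValueError("min_support must be in (0, 1]")
        if not 0 <= self.min_reliability <= 1:
            raise ValueError("min_reliability must be in [0, 1]")
        if self.correlation_mode not in ("joint", "lift"):
            raise ValueError(f"unknown correlation_mode {self.correlation_mode!r}")


@dataclass
class ClassifierParams:
    train_fraction: float = 0.8
    folds: int = 5
    seed: int = 0
    C: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-6

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with the published defaults.

    Defaults: sym8 / 5-level denoising, similarity threshold 0.3, db10
    wavelet-packet band split, sliding windows of length 2-5, 80/20 split.
    """

    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    rpeak: RPeakParams = field(default_factory=RPeakParams)
    bands: BandParams = field(default_factory=BandParams)
    alq: ALQParams = field(default_factory=ALQParams)
    mining: MiningParams = field(default_factory=MiningParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    use_baseline: bool = False      # DREAMER neutral-clip segments ignored by default

    def validate(self) -> None:
        for section in (self.denoise, self.rpeak, self.bands, self.alq,
                        self.mining, self.classifier):
            section.validate()


_SECTIONS = {f.name: f for f in dataclasses.fields(PipelineConfig)
             if f.name != "use_baseline"}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config, applying defaults for absent keys.

    The file holds nested sections (``denoise:``, ``rpeak:``, ...) whose keys
    mirror the parameter dataclasses. Unknown keys or out-of-range values
    raise ``ValueError``. ``None`` or an empty file yields all defaults.
    """
    cfg = PipelineConfig()
    if path is None:
        cfg.validate()
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    for section_name, values in data.items():
        if section_name == "use_baseline":
            cfg.use_baseline = bool(values)
            continue
        if section_name not in _SECTIONS:
            raise ValueError(f"unknown config section {section_name!r}")
        section = getattr(cfg, section_name)
        valid = {f.name for f in dataclasses.fields(section)}
        for key, value in (values or {}).items():
            if key not in valid:
                raise ValueError(f"unknown key {section_name}.{key}")
            if isinstance(value, list):
                value = tuple(value)
            setattr(section, key, value)
    cfg.validate()
    return cfg


def read_ecg_csv(path: str | Path, fs: float) -> list[ECGRecord]:
    """Read one ECG record per numeric column of a CSV file.

    A header row is optional. Any non-finite cell aborts with an error that
    names the offending row.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    # no-header files: first row parses as numbers -> re-read headerless
    if all(_is_number(c) for c in df.columns):
        df = pd.read_csv(path, header=None)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    records = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        if values.size == 0:
            raise ValueError(f"{path}: column {col!r} is empty")
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValueError(
                f"{path}: column {col!r} has a non-numeric value at row {int(bad[0])}"
            )
        records.append(ECGRecord(values, fs=fs, subject_id=str(path.stem),
                                 stimulus_id=str(col)))
    return records


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_dreamer_container(
    path: str | Path, use_baseline: bool = False
) -> tuple[list[ECGRecord], list[RatingRecord]]:
    """Read a DREAMER-layout MAT v5 container.

    Expected layout: top-level variable ``DREAMER`` with field ``Data``, a
    cell of per-subject structs, each with ``ECG`` (struct of ``stimuli``
    and ``baseline`` cells of samples-by-2-channel arrays) and
    ``ScoreValence`` / ``ScoreArousal`` / ``ScoreDominance`` column vectors.
    Returns one ECGRecord per subject x stimulus x channel at 256 Hz, and
    one paired RatingRecord per subject x stimulus. By default the
    film-clip ("stimuli") segments are used and baselines are skipped.
    """
    mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    if "DREAMER" not in mat:
        raise ValueError(f"{path}: no DREAMER variable in container")
    root = mat["DREAMER"]
    data = _segments(_field(root, "Data", path, "root"))
    ecgs: list[ECGRecord] = []
    ratings: list[RatingRecord] = []
    for si, subj in enumerate(data):
        subject_id = f"S{si:02d}"
        ecg = _field(subj, "ECG", path, subject_id)
        segments = _segments(
            _field(ecg, "baseline" if use_baseline else "stimuli", path, subject_id))
        valence = np.atleast_1d(np.asarray(
            _field(subj, "ScoreValence", path, subject_id), dtype=float)).ravel()
        arousal = np.atleast_1d(np.asarray(
            _field(subj, "ScoreArousal", path, subject_id), dtype=float)).ravel()
        dominance = (np.atleast_1d(np.asarray(subj.ScoreDominance,
                                              dtype=float)).ravel()
                     if hasattr(subj, "ScoreDominance") else None)
        if valence.size != len(segments) or arousal.size != len(segments):
            raise ValueError(
                f"{path}: subject {si} has {len(segments)} stimuli but "
                f"{valence.size} valence / {arousal.size} arousal ratings"
            )
        for ti, seg in enumerate(segments):
            arr = np.atleast_2d(np.asarray(seg, dtype=np.float64))
            if arr.shape[0] < arr.shape[1]:
                arr = arr.T
            stim_id = f"V{ti:02d}"
            for ch in range(arr.shape[1]):
                ecgs.append(ECGRecord(arr[:, ch], fs=DREAMER_FS,
                                      subject_id=subject_id,
                                      stimulus_id=f"{stim_id}c{ch}"))
            ratings.append(RatingRecord(
                subject_id=subject_id, stimulus_id=stim_id,
                valence=float(valence[ti]), arousal=float(arousal[ti]),
                dominance=float(dominance[ti]) if dominance is not None else None,
            ))
    return ecgs, ratings


def _field(struct, name: str, path, context: str):
    if not hasattr(struct, name):
        raise ValueError(f"{path}: {context} missing field {name!r}")
    return getattr(struct, name)


def _segments(obj) -> list:
    """A squeezed MAT cell as a list of entries (single entries unwrapped)."""
    arr = np.asarray(obj)
    if arr.dtype == object:
        return [a for a in arr.ravel()]
    return [obj]  # a lone numeric array or struct after squeezing


def write_ecg_csv(records: Sequence[ECGRecord], path: str | Path) -> None:
    """Write records as one column per signal (ragged records NaN-padded)."""
    n = max(r.samples.size for r in records)
    cols = {}
    for i, r in enumerate(records):
        name = f"{r.subject_id}_{r.stimulus_id}" if r.subject_id else f"sig{i}"
        col = np.full(n, np.nan)
        col[: r.samples.size] = r.samples
        cols[name] = col
    pd.DataFrame(cols).to_csv(path, index=False)


def write_ratings_csv(ratings: Sequence[RatingRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in ratings]).to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> list[RatingRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        dom = row.get("dominance")
        out.append(RatingRecord(
            subject_id=str(row["subject_id"]), stimulus_id=str(row["stimulus_id"]),
            valence=float(row["valence"]), arousal=float(row["arousal"]),
            dominance=None if dom is None or pd.isna(dom) else float(dom),
        ))
    return out
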