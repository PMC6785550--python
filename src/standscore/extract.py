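"""Per-event, per-muscle feature extraction over a collection of recordings.

Ties together event trimming, the time-domain features, and the spectral
back-ends into one raw FeatureMatrix with prefixed column names
(``cwt_*``, ``stft_*``, ``fft_*`` plus the two time-domain features), from
which named feature sets (time-only, FFT-only, CWT-only, combined) are cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EmgRecording, StandingEvent, trim_event
from .pipeline import FeatureMatrix, TIME_FEATURES, assemble, participant_power_norm
from .simulate import SyntheticDataset
from .spectral_features import (cwt_scalogram, default_cwt_freqs,
                                fft_summary_features, instantaneous_features,
                                stft_spectrogram)
from .time_features import time_feature_vector

__all__ = ["ExtractionConfig", "extract_trace_features", "extract_dataset",
           "feature_subset", "FEATURE_SETS"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the feature-extraction stage.

    ``trim_s`` seconds are dropped at each end of every event before any
    feature is computed.  ``cwt_time_stride`` subsamples the per-sample CWT
    frames before the instantaneous-feature summaries; the scalogram is
    smooth at the stride scales used here.
    """

    trim_s: float = 5.0
    methods: tuple[str, ...] = ("time", "cwt", "fft")
    cwt_n_bins: int = 120
    cwt_f_min: float = 4.0
    cwt_f_max: float = 500.0
    cwt_time_stride: int = 4
    stft_window_s: float = 0.3


def extract_trace_features(x: np.ndarray, fs: float,
                           config: ExtractionConfig = ExtractionConfig()
                           ) -> dict[str, float]:
    """All requested features of one already-trimmed single-muscle trace."""
    out: dict[str, float] = {}
    if "time" in config.methods:
        out.update(time_feature_vector(x, fs))
    if "fft" in config.methods:
        out.update(fft_summary_features(x, fs))
    if "stft" in config.methods:
        tf = stft_spectrogram(x, fs, window_s=config.stft_window_s)
        out.update(instantaneous_features(tf).as_dict(prefix="stft_"))
    if "cwt" in config.methods:
        freqs = default_cwt_freqs(fs, config.cwt_f_min, config.cwt_f_max,
                                  config.cwt_n_bins)
        tf = cwt_scalogram(x, fs, freqs, time_stride=config.cwt_time_stride)
        out.update(instantaneous_features(tf).as_dict(prefix="cwt_"))
    return out


def extract_dataset(dataset,
                    config: ExtractionConfig = ExtractionConfig(),
                    power_norm: bool = True) -> FeatureMatrix:
    """Raw FeatureMatrix over every (event, muscle) of a dataset.

    ``dataset`` is a :class:`~standscore.simulate.SyntheticDataset` or an
    iterable of (EmgRecording, StandingEvent) pairs.  Labels are the
    assistance categories of the events.  Total power is normalized within
    participant and muscle when ``power_norm`` is set.
    """
    if isinstance(dataset, SyntheticDataset):
        pairs = [(se.recording, se.event) for se in dataset.events]
    else:
        pairs = list(dataset)
    rows: dict[tuple[str, str, str], dict[str, float]] = {}
    labels: dict[str, str] = {}
    for rec, ev in pairs:
        window = trim_event(rec, ev, trim_s=config.trim_s)
        labels[ev.event_id] = ev.label.category
        muscle_cols = [i for i in range(window.shape[1])
                       if i != rec.artifact_channel]
        for lbl, col in zip(rec.channel_labels, muscle_cols):
            rows[(rec.participant_id, ev.event_id, lbl)] = \
                extract_trace_features(window[:, col], rec.fs, config)
    fm = assemble(rows, labels)
    if power_norm and "total_power" in fm.df.columns:
        fm = participant_power_norm(fm)
    return fm


FEATURE_SETS = ("time", "fft", "stft", "cwt", "combined")


def feature_subset(fm: FeatureMatrix, name: str) -> FeatureMatrix:
    """Cut a named feature set out of a full raw matrix.

    "time" keeps the two time-domain features; "fft"/"stft"/"cwt" keep one
    spectral back-end's columns; "combined" is time + CWT.
    """
    cols = list(fm.df.columns)
    if name == "time":
        keep = [c for c in cols if c in TIME_FEATURES]
    elif name in ("fft", "stft", "cwt"):
        keep = [c for c in cols if c.startswith(f"{name}_")]
    elif name == "combined":
        keep = [c for c in cols
                if c in TIME_FEATURES or c.startswith("cwt_")]
    else:
        raise ValueError(f"unknown feature set {name!r}; "
                         f"choose from {FEATURE_SETS}")
    if not keep:
        raise ValueError(f"feature set {name!r}: no matching columns in "
                         f"{cols}")
    return FeatureMatrix(df=fm.df[keep], y=fm.y, stage=fm.stage,
                         meta={**fm.meta, "feature_set": name})
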