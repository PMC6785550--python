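"""Domain types and file I/O for multichannel standing-EMG recordings.

A recording is a samples-by-channels matrix in microvolts at a fixed sampling
rate (2000 Hz in the acquisition setup this package targets), with one label
per muscle channel drawn from the fixed side x muscle vocabulary, and an
optional paraspinal artifact channel that registers the epidural stimulation
pulses.  Standing events are annotated time windows over a recording, each
carrying the external-assistance status of hips and knees plus the
stimulation program in effect.

Two on-disk dialects are supported for signals: an HDF5 container
(``/samples``, ``/fs``, ``/labels`` datasets) and CSV with a JSON sidecar.
Event annotations are rows in a CSV or JSON file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

MUSCLES = ("SOL", "MG", "VL", "RF", "GL", "TA", "MH", "IL")
SIDES = ("L", "R")
#: the 16 side+muscle channel labels, e.g. "L SOL"
CHANNEL_VOCAB = tuple(f"{s} {m}" for m in MUSCLES for s in SIDES)
ARTIFACT_LABEL = "ARTIFACT"

ASSISTED = "assisted"
INDEPENDENT = "independent"


class FormatError(ValueError):
    """Malformed signal-file header or structure."""


class DataError(ValueError):
    """Non-finite or otherwise invalid sample data."""


@dataclass(frozen=True)
class AssistanceLabel:
    """External-assistance status of hips and each knee during a standing event.

    Maps onto one of four event categories: both assisted; hips assisted with
    knees independent; fully independent; or one knee assisted with the
    contralateral knee independent.
    """

    hips: str
    knee_left: str
    knee_right: str

    def __post_init__(self) -> None:
        for v in (self.hips, self.knee_left, self.knee_right):
            if v not in (ASSISTED, INDEPENDENT):
                raise ValueError(f"assistance value must be "
                                 f"'{ASSISTED}' or '{INDEPENDENT}', got {v!r}")

    @property
    def category(self) -> str:
        """One of 'assisted', 'hips_assisted_knees_independent',
        'independent', 'one_knee_assisted'."""
        knees = (self.knee_left, self.knee_right)
        if knees == (ASSISTED, ASSISTED):
            if self.hips == ASSISTED:
                return "assisted"
            # hips independent with both knees assisted does not occur in the
            # labelling scheme; fold it into the assisted category
            return "assisted"
        if knees == (INDEPENDENT, INDEPENDENT):
            return ("independent" if self.hips == INDEPENDENT
                    else "hips_assisted_knees_independent")
        return "one_knee_assisted"

    @classmethod
    def assisted(cls) -> "AssistanceLabel":
        return cls(ASSISTED, ASSISTED, ASSISTED)

    @classmethod
    def independent(cls) -> "AssistanceLabel":
        return cls(INDEPENDENT, INDEPENDENT, INDEPENDENT)


@dataclass
class EmgRecording:
    """Multichannel EMG samples (microvolts) with channel metadata."""

    samples: np.ndarray          # [n_samples, n_channels]
    fs: float                    # Hz
    channel_labels: list[str]    # muscle channels, excludes artifact channel
    artifact_channel: int | None = None
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n_expected = len(self.channel_labels) + (self.artifact_channel is not None)
        if self.samples.shape[1] != n_expected:
            raise FormatError(
                f"{self.samples.shape[1]} sample columns but "
                f"{len(self.channel_labels)} labels"
                + (" + artifact channel" if self.artifact_channel is not None else ""))
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if not np.isfinite(self.samples).all():
            raise DataError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Samples of one muscle channel by label."""
        muscle_cols = [i for i in range(self.samples.shape[1])
                       if i != self.artifact_channel]
        idx = muscle_cols[self.channel_labels.index(label)]
        return self.samples[:, idx]

    @property
    def artifact_signal(self) -> np.ndarray:
        if self.artifact_channel is None:
            raise ValueError("recording has no artifact channel")
        return self.samples[:, self.artifact_channel]


@dataclass
class StandingEvent:
    """A labeled standing window within a recording, with stimulation metadata."""

    event_id: str
    start_s: float
    end_s: float
    label: AssistanceLabel
    stim_amplitude_v: float = float("nan")
    stim_frequency_hz: float = float("nan")
    electrode_config: str = ""
    recording_ref: str = ""

    def __post_init__(self) -> None:
        if not self.end_s >= self.start_s + 10:
            raise ValueError(
                f"event {self.event_id}: duration must be at least 10 s, "
                f"got [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PulseTrain:
    """Stimulation onset times (seconds, ascending) and the nominal pulse rate."""

    onset_times: np.ndarray
    nominal_rate_hz: float

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.onset_times.size and np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return self.onset_times.size

    def rate_estimate(self) -> float:
        """Median reciprocal inter-onset interval; NaN with < 2 onsets."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(1.0 / np.diff(self.onset_times)))

    def check_regularity(self, tol: float = 0.2) -> bool:
        """True when every inter-pulse interval lies within ``tol`` (fractional)
        of the nominal period.  Interleaved programs jitter the effective rate,
        hence the generous default of 20%."""
        if len(self) < 2:
            return True
        period = 1.0 / self.nominal_rate_hz
        ipi = np.diff(self.onset_times)
        return bool(np.all(np.abs(ipi - period) <= tol * period))


# ---------------------------------------------------------------------------
# signal file I/O


def save_recording(path: str | Path, rec: EmgRecording) -> None:
    """Write a recording in the canonical dialect inferred from the suffix
    (.h5/.hdf5 container, or .csv with a .json sidecar)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=rec.samples)
            f.create_dataset("fs", data=float(rec.fs))
            f.create_dataset("labels",
                             data=np.array(rec.channel_labels, dtype="S32"))
            f.attrs["participant_id"] = rec.participant_id
            if rec.artifact_channel is not None:
                f.attrs["artifact_channel"] = int(rec.artifact_channel)
    elif path.suffix == ".csv":
        cols = list(rec.channel_labels)
        if rec.artifact_channel is not None:
            cols.insert(rec.artifact_channel, ARTIFACT_LABEL)
        # %.17g preserves float64 exactly across the text round trip
        pd.DataFrame(rec.samples, columns=cols).to_csv(
            path, index=False, float_format="%.17g")
        sidecar = {"fs": rec.fs, "channel_labels": rec.channel_labels,
                   "participant_id": rec.participant_id,
                   "artifact_channel": rec.artifact_channel}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise FormatError(f"unsupported signal dialect: {path.suffix}")


def load_recording(path: str | Path) -> EmgRecording:
    """Load and validate a recording written by :func:`save_recording`.

    Raises :class:`FormatError` on a malformed header and :class:`DataError`
    on non-finite samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for key in ("samples", "fs", "labels"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset /{key}")
            samples = f["samples"][()]
            fs = float(f["fs"][()])
            labels = [s.decode() for s in f["labels"][()]]
            art = f.attrs.get("artifact_channel")
            art = int(art) if art is not None else None
            pid = str(f.attrs.get("participant_id", ""))
    elif path.suffix == ".csv":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FormatError(f"{path}: missing JSON sidecar")
        meta = json.loads(sidecar_path.read_text())
        try:
            fs = float(meta["fs"])
            labels = list(meta["channel_labels"])
        except KeyError as e:
            raise FormatError(f"{path}: sidecar missing {e}") from e
        art = meta.get("artifact_channel")
        pid = meta.get("participant_id", "")
        df = pd.read_csv(path, float_precision="round_trip")
        expected = list(labels)
        if art is not None:
            expected.insert(art, ARTIFACT_LABEL)
        if list(df.columns) != expected:
            raise FormatError(f"{path}: columns {list(df.columns)} do not match "
                              f"sidecar labels {expected}")
        samples = df.to_numpy(dtype=float)
    else:
        raise FormatError(f"unsupported signal dialect: {path.suffix}")
    return EmgRecording(samples=samples, fs=fs, channel_labels=labels,
                        artifact_channel=art, participant_id=pid)


def save_events(path: str | Path, events: Sequence[StandingEvent]) -> None:
    rows = []
    for ev in events:
        rows.append({"event_id": ev.event_id, "start_s": ev.start_s,
                     "end_s": ev.end_s, "hips": ev.label.hips,
                     "knee_left": ev.label.knee_left,
                     "knee_right": ev.label.knee_right,
                     "stim_amplitude_v": ev.stim_amplitude_v,
                     "stim_frequency_hz": ev.stim_frequency_hz,
                     "electrode_config": ev.electrode_config,
                     "recording_ref": ev.recording_ref})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_events(path: str | Path) -> list[StandingEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(StandingEvent(
            event_id=str(r["event_id"]), start_s=float(r["start_s"]),
            end_s=float(r["end_s"]),
            label=AssistanceLabel(r["hips"], r["knee_left"], r["knee_right"]),
            stim_amplitude_v=float(r.get("stim_amplitude_v", np.nan)),
            stim_frequency_hz=float(r.get("stim_frequency_hz", np.nan)),
            electrode_config=str(r.get("electrode_config", "") or ""),
            recording_ref=str(r.get("recording_ref", "") or "")))
    return events


# ---------------------------------------------------------------------------
# segmentation


def trim_event(rec: EmgRecording, ev: StandingEvent,
               trim_s: float = 5.0) -> np.ndarray:
    """Samples of ``rec`` within the event window after discarding ``trim_s``
    seconds at each end.

    Raw standing events run 40-70 s; dropping the initial and final 5 s
    removes transition transients, leaving a 30-60 s analysis window.
    Boundaries are half-open ``[start+trim, end-trim)`` converted by
    ``floor(t * fs)``.
    """
    if ev.duration_s <= 2 * trim_s:
        raise ValueError(
            f"event {ev.event_id}: duration {ev.duration_s:.1f} s too short "
            f"for {trim_s} s trims")
    i0 = int(np.floor((ev.start_s + trim_s) * rec.fs))
    i1 = int(np.floor((ev.end_s - trim_s) * rec.fs))
    if i1 > rec.n_samples:
        raise ValueError(f"event {ev.event_id} extends past end of recording")
    return rec.samples[i0:i1]


# ---------------------------------------------------------------------------
# stimulation-onset detection


def detect_pulse_onsets(artifact_signal: np.ndarray, fs: float,
                        mad_k: float = 8.0,
                        nominal_rate_hz: float | None = None) -> PulseTrain:
    """Detect stimulation pulse onsets from the paraspinal artifact channel.

    The rectified signal is thresholded at ``median + mad_k * MAD``; each
    suprathreshold crossing opens a refractory window (0.4 of the nominal
    period when a rate is supplied, otherwise 2 ms) during which further
    crossings are absorbed into the same pulse.  Returns an empty train with
    a warning when nothing crosses the threshold.
    """
    x = np.abs(np.asarray(artifact_signal, dtype=float))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    thresh = med + mad_k * max(mad, 1e-12)
    above = x > thresh
    if not above.any():
        warnings.warn("no suprathreshold artifact crossings; empty pulse train")
        return PulseTrain(np.empty(0), nominal_rate_hz or float("nan"))
    if nominal_rate_hz:
        refractory = int(round(0.4 / nominal_rate_hz * fs))
    else:
        refractory = max(int(round(0.002 * fs)), 1)
    onsets: list[int] = []
    idx = np.flatnonzero(above)
    for j in idx:
        if not onsets or j - onsets[-1] > refractory:
            onsets.append(j)
    onset_times = np.array(onsets) / fs
    train = PulseTrain(onset_times, nominal_rate_hz or float("nan"))
    if nominal_rate_hz is None and len(train) >= 2:
        train = PulseTrain(onset_times, train.rate_estimate())
    return train
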