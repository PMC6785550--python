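"""Synthetic epidural-stimulation EMG generator.

Epidural stimulation of the lumbosacral cord at 15-60 Hz evokes a
stimulus-locked compound response in each leg muscle after every pulse.  The
generator models a single-muscle EMG trace as a train of such evoked
responses: a Morlet-like kernel (Gaussian-windowed cosine) repeated at the
stimulation rate, with per-pulse lognormal amplitude variability, an overall
activity envelope that is either constant (continuous activation) or
rhythmically bursting, plus band-limited Gaussian background noise.

The kernel's central frequency controls the sharpness of the evoked-response
peaks: sharper (higher-frequency) responses push spectral power upward and
increase both the level and the frame-to-frame modulation of the
instantaneous median frequency, which is the mechanism separating
assisted-like from independent-like activity in this model.  Shipped class
presets are fictional calibrations chosen to reproduce the qualitative
feature orderings between standing conditions; they are not estimates of any
patient's data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import (AssistanceLabel, EmgRecording, PulseTrain, StandingEvent,
                 save_events, save_recording)

__all__ = [
    "EvokedKernel", "ClassPreset", "HeterogeneityModel", "SyntheticEvent",
    "SyntheticDataset", "evoked_kernel_waveform", "generate_event",
    "generate_dataset", "default_presets",
]


@dataclass(frozen=True)
class EvokedKernel:
    """Single evoked-response waveform: a Gaussian-windowed cosine.

    ``duration_s`` is the full response length (the Gaussian window has
    sigma = duration_s / 6, so the waveform decays to near zero at the
    ends); the default of 40 ms matches the window between successive
    stimulation pulses at typical rates, where the discrete stimulus-locked
    responses live.  ``central_frequency_hz`` sets the oscillation under
    the window and is therefore a pure peak-sharpness control: higher
    central frequency means a spikier, more multiphasic response with more
    power in high-frequency bins.
    """

    central_frequency_hz: float
    duration_s: float = 0.04
    amplitude_uv: float = 100.0

    def __post_init__(self) -> None:
        if not 10.0 <= self.central_frequency_hz <= 200.0:
            raise ValueError("central_frequency_hz must lie in [10, 200]")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude_uv must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def sigma_s(self) -> float:
        return self.duration_s / 6.0


def evoked_kernel_waveform(kernel: EvokedKernel, fs: float) -> np.ndarray:
    """Sampled kernel, centered, truncated at ``duration_s``."""
    half = int(round(kernel.duration_s / 2 * fs))
    if 2 * half + 1 < 8:
        raise ValueError("kernel too short for the sampling rate "
                         "(duration_s * fs must be >= 8 samples)")
    t = np.arange(-half, half + 1) / fs
    return (kernel.amplitude_uv
            * np.cos(2 * np.pi * kernel.central_frequency_hz * t)
            * np.exp(-t**2 / (2 * kernel.sigma_s**2)))


@dataclass(frozen=True)
class RhythmicEnvelope:
    """Raised-cosine burst envelope: bursts at ``burst_rate_hz`` occupying a
    ``duty`` fraction of each cycle, with a small baseline between bursts."""

    burst_rate_hz: float = 1.0
    duty: float = 0.5
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.duty < 1:
            raise ValueError("duty must lie in (0, 1)")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        phase = (t * self.burst_rate_hz) % 1.0
        burst = 0.5 * (1 - np.cos(2 * np.pi * phase / self.duty))
        burst = np.where(phase < self.duty, burst, 0.0)
        return self.baseline + (1 - self.baseline) * burst


@dataclass(frozen=True)
class ClassPreset:
    """Generator parameters for one activity class."""

    name: str
    kernel: EvokedKernel
    amplitude_cv: float = 0.0        # per-pulse amplitude coefficient of variation
    envelope: RhythmicEnvelope | None = None   # None = constant envelope
    gain: float = 1.0
    noise_rms_uv: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def default_presets() -> dict[str, ClassPreset]:
    """Fictional class calibrations for the three canonical activity types.

    independent_like: smooth, low-frequency evoked responses, steady
    amplitude, stronger overall activity.  assisted_continuous: sharper
    responses, more per-pulse variability, weaker activity.
    assisted_bursting: as continuous but gated by a 1 Hz raised-cosine burst
    envelope (alternation of bursts and near-silence).
    """
    return {
        "independent_like": ClassPreset(
            name="independent_like",
            kernel=EvokedKernel(central_frequency_hz=20.0),
            amplitude_cv=0.1, envelope=None, gain=1.2, noise_rms_uv=8.0),
        "assisted_continuous": ClassPreset(
            name="assisted_continuous",
            kernel=EvokedKernel(central_frequency_hz=40.0),
            amplitude_cv=0.35, envelope=None, gain=0.8, noise_rms_uv=8.0),
        "assisted_bursting": ClassPreset(
            name="assisted_bursting",
            kernel=EvokedKernel(central_frequency_hz=40.0),
            amplitude_cv=0.6,
            envelope=RhythmicEnvelope(burst_rate_hz=1.0, duty=0.5),
            gain=0.8, noise_rms_uv=8.0),
    }


PRESET_TO_LABEL = {
    "independent_like": AssistanceLabel.independent,
    "assisted_continuous": AssistanceLabel.assisted,
    "assisted_bursting": AssistanceLabel.assisted,
}


@dataclass
class SyntheticEvent:
    """One generated standing event with its ground truth."""

    recording: EmgRecording
    event: StandingEvent
    pulse_train: PulseTrain
    truth: dict


def _bandlimited_noise(n: int, fs: float, rms: float,
                       rng: np.random.Generator,
                       band: tuple[float, float] = (10.0, 500.0)) -> np.ndarray:
    """Gaussian noise band-limited to the surface-EMG band, scaled to ``rms``."""
    if rms <= 0:
        return np.zeros(n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    w = sosfiltfilt(sos, rng.standard_normal(n))
    w *= rms / max(np.sqrt(np.mean(w**2)), 1e-30)
    return w


def synthesize_trace(preset: ClassPreset, stim_rate_hz: float, duration_s: float,
                     fs: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single-channel trace and the pulse onset times used to build it."""
    if duration_s < 10:
        raise ValueError("duration_s must be at least 10 s")
    if not 10.0 <= stim_rate_hz <= 60.0:
        raise ValueError("stim_rate_hz must lie in [10, 60]")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    onset_times = np.arange(0.01, duration_s, 1.0 / stim_rate_hz)
    g = evoked_kernel_waveform(preset.kernel, fs)
    half = (len(g) - 1) // 2
    if preset.amplitude_cv > 0:
        sigma = np.sqrt(np.log1p(preset.amplitude_cv**2))
        amps = rng.lognormal(mean=0.0, sigma=sigma, size=len(onset_times))
    else:
        amps = np.ones(len(onset_times))
    x = np.zeros(n)
    centers = np.round(onset_times * fs).astype(int)
    for c, a in zip(centers, amps):
        i0, i1 = c - half, c + half + 1
        j0, j1 = max(i0, 0), min(i1, n)
        x[j0:j1] += a * g[j0 - i0:len(g) - (i1 - j1)]
    env = np.ones(n) if preset.envelope is None else preset.envelope(t)
    x = preset.gain * env * x
    x += _bandlimited_noise(n, fs, preset.noise_rms_uv, rng)
    return x, onset_times


def generate_event(preset: ClassPreset, stim_rate_hz: float = 25.0,
                   duration_s: float = 50.0, fs: float = 2000.0,
                   seed: int | np.random.Generator = 0,
                   event_id: str = "synth-0",
                   participant_id: str = "SYNTH") -> SyntheticEvent:
    """Generate one labeled single-muscle standing event.

    Deterministic given ``seed``.  Defaults follow the study conditions the
    package targets: 2000 Hz sampling, 25 Hz stimulation, 50 s events.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x, onsets = synthesize_trace(preset, stim_rate_hz, duration_s, fs, rng)
    rec = EmgRecording(samples=x[:, None], fs=fs, channel_labels=["L SOL"],
                       participant_id=participant_id)
    label_factory = PRESET_TO_LABEL.get(preset.name, AssistanceLabel.assisted)
    event = StandingEvent(event_id=event_id, start_s=0.0, end_s=duration_s,
                          label=label_factory(),
                          stim_frequency_hz=stim_rate_hz,
                          recording_ref=event_id)
    truth = {"preset": preset, "stim_rate_hz": stim_rate_hz,
             "onset_times": onsets, "fs": fs, "duration_s": duration_s}
    return SyntheticEvent(recording=rec, event=event,
                          pulse_train=PulseTrain(onsets, stim_rate_hz),
                          truth=truth)


@dataclass(frozen=True)
class HeterogeneityModel:
    """Between-event and between-muscle variability of the generator.

    Real standing sessions differ in overall activation strength from event
    to event, and muscles differ in evoked-response shape and recording
    gain (electrode placement, tissue filtering).  Each relative SD below
    is the sigma-parameter of a lognormal multiplier applied to the
    corresponding preset parameter: ``cf_rel_sd`` to the kernel central
    frequency (per muscle trace), ``amp_cv_rel_sd`` to the per-pulse
    amplitude CV, ``gain_event_rel_sd`` to a gain factor shared by all
    muscles of an event, ``gain_muscle_rel_sd`` to an additional per-trace
    gain, and ``noise_rel_sd`` to the noise RMS.  Zeros give the
    homogeneous generator.
    """

    cf_rel_sd: float = 0.2
    amp_cv_rel_sd: float = 0.5
    gain_event_rel_sd: float = 0.4
    gain_muscle_rel_sd: float = 0.3
    noise_rel_sd: float = 0.3

    def perturb(self, preset: ClassPreset, event_gain: float,
                rng: np.random.Generator) -> ClassPreset:
        def ln(sd: float) -> float:
            return float(rng.lognormal(0.0, sd)) if sd > 0 else 1.0

        cf = float(np.clip(preset.kernel.central_frequency_hz
                           * ln(self.cf_rel_sd), 10.0, 200.0))
        kernel = replace(preset.kernel, central_frequency_hz=cf)
        return replace(
            preset, kernel=kernel,
            amplitude_cv=preset.amplitude_cv * ln(self.amp_cv_rel_sd),
            gain=preset.gain * event_gain * ln(self.gain_muscle_rel_sd),
            noise_rms_uv=preset.noise_rms_uv * ln(self.noise_rel_sd))


@dataclass
class SyntheticDataset:
    """Collection of generated multi-muscle events with ground truth."""

    events: list[SyntheticEvent]

    def __len__(self) -> int:
        return len(self.events)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for se in self.events:
            name = se.truth["class_name"]
            out[name] = out.get(name, 0) + 1
        return out

    def save(self, out_dir) -> None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for se in self.events:
            save_recording(out_dir / f"{se.event.event_id}.h5", se.recording)
        save_events(out_dir / "events.csv", [se.event for se in self.events])


def generate_dataset(n_events_per_class: int,
                     muscle_set: Sequence[str],
                     presets: Mapping[str, Mapping[str, ClassPreset] | ClassPreset],
                     stim_rate_hz: float = 25.0,
                     duration_s: float = 50.0,
                     fs: float = 2000.0,
                     seed: int = 0,
                     heterogeneity: HeterogeneityModel | None = None,
                     participant_id: str = "SYNTH") -> SyntheticDataset:
    """Generate a balanced labeled dataset of multi-muscle standing events.

    ``presets`` maps class name to either a single :class:`ClassPreset`
    (applied to every muscle) or a muscle -> preset mapping.
    ``heterogeneity`` (default :class:`HeterogeneityModel`) perturbs the
    preset parameters per event and per muscle trace, emulating the
    between-event and between-muscle variability of real sessions; pass a
    zeroed model for homogeneous draws.
    """
    if heterogeneity is None:
        heterogeneity = HeterogeneityModel()
    if n_events_per_class < 1:
        raise ValueError("n_events_per_class must be >= 1")
    if len(presets) < 2:
        raise ValueError("need at least two classes")
    for cls, p in presets.items():
        if isinstance(p, Mapping):
            missing = set(muscle_set) - set(p)
            if missing:
                raise ValueError(f"class {cls}: no preset for muscles {missing}")

    ss = np.random.SeedSequence(seed)
    events: list[SyntheticEvent] = []
    class_names = list(presets)
    child_seeds = ss.spawn(n_events_per_class * len(class_names))
    k = 0
    for cls in class_names:
        for i in range(n_events_per_class):
            rng = np.random.default_rng(child_seeds[k]); k += 1
            if heterogeneity.gain_event_rel_sd > 0:
                gain_mult = float(rng.lognormal(
                    0.0, heterogeneity.gain_event_rel_sd))
            else:
                gain_mult = 1.0
            cols, truths = [], {}
            onsets = None
            for m in muscle_set:
                p = presets[cls]
                preset = p[m] if isinstance(p, Mapping) else p
                preset = heterogeneity.perturb(preset, gain_mult, rng)
                x, onsets = synthesize_trace(preset, stim_rate_hz, duration_s,
                                             fs, rng)
                cols.append(x)
                truths[m] = preset
            rec = EmgRecording(samples=np.column_stack(cols), fs=fs,
                               channel_labels=list(muscle_set),
                               participant_id=participant_id)
            label = PRESET_TO_LABEL.get(cls, AssistanceLabel.assisted)()
            eid = f"{cls}-{i:04d}"
            event = StandingEvent(event_id=eid, start_s=0.0, end_s=duration_s,
                                  label=label, stim_frequency_hz=stim_rate_hz,
                                  recording_ref=eid)
            events.append(SyntheticEvent(
                recording=rec, event=event,
                pulse_train=PulseTrain(onsets, stim_rate_hz),
                truth={"class_name": cls, "presets": truths,
                       "gain_mult": gain_mult, "onset_times": onsets,
                       "stim_rate_hz": stim_rate_hz}))
    return SyntheticDataset(events=events)
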