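"""Paradigm-faithful synthetic EEG with known ground truth.

Emulates the cue-based command-following paradigm: runs of 15 trials of
12 s (beep at t = 0, verbal cue at t = 2 s, reference interval at 1-2 s),
separated by random 4-6 s pauses.  Each session carries

* a 1/f ("pink") Gaussian background, generated in the frequency domain
  with random phases and |H(f)| ∝ f^(−exponent/2) for exact spectral
  control;
* band-limited oscillations (band-passed white noise, not sinusoids, so
  trial-to-trial band-power variance resembles real EEG rhythms) whose
  amplitude is scaled by a per-trial activity factor during the modulation
  window — factor < 1 implants ERD, factor > 1 implants ERS, with a 0.25-s
  raised-cosine ramp against spectral splatter;
* optional additive high-amplitude transients standing in for muscle and
  movement artifacts.

For a pure amplitude-scaled oscillation the implanted ERD/ERS percentage
is (factor² − 1)·100, which the :class:`GroundTruth` records so downstream
estimators can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import EventList, Recording
from .montage import DEFAULT_LABELS, compact_labels

RAMP_S = 0.25  # raised-cosine amplitude ramp


@dataclass(frozen=True)
class OscillationSpec:
    """A rhythmic component on one channel.

    ``activity_factor`` scales the oscillation amplitude inside the
    modulation window of every trial: 0.5 implants −75% ERD, √2 implants
    +100% ERS, 1.0 leaves the rhythm unmodulated.
    """

    channel: str
    center_freq: float
    bandwidth: float = 2.0
    baseline_amplitude: float = 10.0  # µV RMS
    activity_factor: float = 0.5
    modulation_onset: float = 2.0  # s within trial
    modulation_duration: float = 10.0  # s

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2, self.center_freq + self.bandwidth / 2)

    @property
    def erds_percent(self) -> float:
        return (self.activity_factor**2 - 1.0) * 100.0


@dataclass(frozen=True)
class ArtifactSpec:
    """A transient to inject: position given per trial, onset within trial."""

    trial_index: int
    channel: str
    onset: float  # s within trial
    duration: float = 0.2  # s
    amplitude_factor: float = 10.0  # × channel RMS


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 32
    channel_labels: tuple[str, ...] | None = None
    fs: float = 512.0
    trial_length: float = 12.0
    cue_onset: float = 2.0
    reference_window: tuple[float, float] = (1.0, 2.0)
    n_trials_per_run: int = 15
    n_runs: int = 3
    pause_range: tuple[float, float] = (4.0, 6.0)
    task_label: str = "sport"
    oscillations: tuple[OscillationSpec, ...] = ()
    noise_exponent: float = 1.0
    noise_scale: float = 10.0  # µV total RMS of the 1/f background
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    @property
    def labels(self) -> tuple[str, ...]:
        if self.channel_labels is not None:
            return tuple(self.channel_labels)
        if self.n_channels == len(DEFAULT_LABELS):
            return DEFAULT_LABELS
        return tuple(compact_labels(self.n_channels))

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_run * self.n_runs

    def validate(self) -> None:
        if not 0 <= self.reference_window[0] < self.reference_window[1] <= self.cue_onset:
            raise ValueError("reference window must lie before the cue and inside the trial")
        if self.cue_onset >= self.trial_length:
            raise ValueError("cue onset must fall inside the trial")
        if len(self.labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        if self.pause_range[0] > self.pause_range[1] or self.pause_range[0] < 0:
            raise ValueError("invalid pause range")
        for spec in self.oscillations:
            if spec.activity_factor <= 0:
                raise ValueError("activity_factor must be positive")
            if spec.channel not in self.labels:
                raise ValueError(f"oscillation channel {spec.channel!r} not in montage")
            if spec.band[0] <= 0 or spec.band[1] >= self.fs / 2:
                raise ValueError("oscillation band outside (0, Nyquist)")
        for a, sa in enumerate(self.oscillations):
            for sb in self.oscillations[a + 1 :]:
                if sa.channel == sb.channel and not (
                    sa.band[1] <= sb.band[0] or sb.band[1] <= sa.band[0]
                ):
                    raise ValueError(
                        f"overlapping oscillation bands on channel {sa.channel!r}"
                    )
        for art in self.artifacts:
            if not 0 <= art.trial_index < self.n_trials:
                raise ValueError(f"artifact trial index {art.trial_index} out of range")
            if art.onset < 0 or art.onset + art.duration > self.trial_length:
                raise ValueError("artifact span outside its trial")
            if art.channel not in self.labels:
                raise ValueError(f"artifact channel {art.channel!r} not in montage")


@dataclass
class ArtifactAnnotation:
    trial_index: int
    channel: str
    start_sample: int  # absolute sample in the continuous recording
    stop_sample: int


@dataclass
class GroundTruth:
    """What was implanted where — the oracle for downstream estimators."""

    trial_labels: list[str]
    erds_percent: dict[tuple[str, float], float]  # (channel, center_freq) -> %
    modulation_window: tuple[float, float]
    artifacts: list[ArtifactAnnotation] = field(default_factory=list)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with PSD ∝ 1/f^exponent, scaled to a target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.std(x)
    return x


def _band_limited_rhythm(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    """Unit-structure rhythm: band-passed white noise normalized to ``rms``."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    x *= rms / np.std(x)
    return x


def _modulation_envelope(
    n_total: int,
    fs: float,
    trial_onsets: np.ndarray,
    spec: OscillationSpec,
    trial_length: float,
    ramp_s: float = RAMP_S,
) -> np.ndarray:
    """Amplitude envelope: baseline 1, ``activity_factor`` inside each
    trial's modulation window, raised-cosine transitions of ``ramp_s``."""
    env = np.ones(n_total)
    dur = min(spec.modulation_duration, trial_length - spec.modulation_onset)
    n_mod = int(round(dur * fs))
    n_ramp = min(int(round(ramp_s * fs)), n_mod // 2)
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_ramp) / max(n_ramp, 1))  # 0 -> 1
    shape = np.ones(n_mod)
    shape[:n_ramp] = ramp
    if spec.modulation_onset + dur < trial_length - 1e-9:
        shape[n_mod - n_ramp :] = ramp[::-1]
    depth = spec.activity_factor - 1.0
    for onset in trial_onsets:
        lo = onset + int(round(spec.modulation_onset * fs))
        env[lo : lo + n_mod] += depth * shape
    return env


def generate_session(config: SimulationConfig) -> tuple[Recording, EventList, GroundTruth]:
    """Synthesize one session: continuous recording + events + ground truth.

    Bit-identical output for identical ``config`` (including ``seed``).
    """
    config.validate()
    fs = config.fs
    rng = np.random.default_rng([int(config.seed), 0])

    n_trial = int(round(config.trial_length * fs))
    pauses = rng.uniform(*config.pause_range, size=config.n_trials)
    n_pauses = np.round(pauses * fs).astype(int)
    onsets = np.zeros(config.n_trials, dtype=np.int64)
    pos = 0
    for i in range(config.n_trials):
        onsets[i] = pos
        pos += n_trial + n_pauses[i]
    n_total = pos

    data = np.empty((config.n_channels, n_total))
    for c in range(config.n_channels):
        data[c] = _pink_noise(rng, n_total, config.noise_exponent, config.noise_scale)

    for spec in config.oscillations:
        rhythm = _band_limited_rhythm(rng, n_total, fs, spec.band, spec.baseline_amplitude)
        env = _modulation_envelope(n_total, fs, onsets, spec, config.trial_length)
        data[config.labels.index(spec.channel)] += rhythm * env

    recording = Recording(
        data=data,
        fs=fs,
        channel_labels=list(config.labels),
        highpass=0.5,
        lowpass=100.0,
        notch=50.0,
    )

    abs_specs = [
        (art, int(onsets[art.trial_index] + round(art.onset * fs)))
        for art in config.artifacts
    ]
    recording, annotations = inject_artifacts(
        recording,
        [(start, art.channel, art.duration, art.amplitude_factor) for art, start in abs_specs],
        trial_indices=[art.trial_index for art in config.artifacts],
    )

    events = EventList(
        onsets=onsets,
        labels=[config.task_label] * config.n_trials,
        runs=np.repeat(np.arange(config.n_runs), config.n_trials_per_run),
    )
    truth = GroundTruth(
        trial_labels=list(events.labels),
        erds_percent={
            (s.channel, s.center_freq): s.erds_percent for s in config.oscillations
        },
        modulation_window=(
            config.oscillations[0].modulation_onset if config.oscillations else config.cue_onset,
            (config.oscillations[0].modulation_onset + config.oscillations[0].modulation_duration)
            if config.oscillations
            else config.trial_length,
        ),
        artifacts=annotations,
    )
    return recording, events, truth


def generate_resting(config: SimulationConfig, duration: float = 90.0) -> Recording:
    """Artifact-free, modulation-free segment for detector calibration.

    Contains the same 1/f background and the configured rhythms at their
    baseline amplitude (idle rhythms are present at rest), so an AR model
    fitted here whitens exactly the stationary process the trials contain.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 10.0:
        raise ValueError("resting segment must be at least 10 s")
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    n = int(round(duration * config.fs))
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        data[c] = _pink_noise(rng, n, config.noise_exponent, config.noise_scale)
    for spec in config.oscillations:
        data[config.labels.index(spec.channel)] += _band_limited_rhythm(
            rng, n, config.fs, spec.band, spec.baseline_amplitude
        )
    return Recording(
        data=data,
        fs=config.fs,
        channel_labels=list(config.labels),
        highpass=0.5,
        lowpass=100.0,
        notch=50.0,
    )


def inject_artifacts(
    recording: Recording,
    specs: list[tuple[int, str, float, float]],
    trial_indices: list[int] | None = None,
) -> tuple[Recording, list[ArtifactAnnotation]]:
    """Add transient artifacts; returns a new recording plus annotations.

    Each spec is ``(start_sample, channel, duration_s, amplitude_factor)``;
    the transient is a Hann-windowed 45-Hz tone burst (a muscle-like
    high-frequency transient) whose peak is ``amplitude_factor × RMS`` of
    the pre-injection channel.  Deterministic: no randomness involved.
    """
    burst_freq = 45.0  # Hz, inside the EMG range and above the EEG rhythms
    data = recording.data.copy()
    annotations: list[ArtifactAnnotation] = []
    if trial_indices is None:
        trial_indices = [-1] * len(specs)
    for (start, channel, duration, factor), trial in zip(specs, trial_indices):
        ci = recording.channel_index(channel)
        n = int(round(duration * recording.fs))
        stop = start + n
        if start < 0 or stop > recording.n_samples:
            raise ValueError(f"artifact span [{start}, {stop}) outside recording")
        rms = np.sqrt(np.mean(recording.data[ci] ** 2))
        t = (np.arange(n) - (n - 1) / 2) / recording.fs
        pulse = factor * rms * np.hanning(n) * np.cos(2 * np.pi * burst_freq * t)
        data[ci, start:stop] += pulse
        annotations.append(
            ArtifactAnnotation(trial_index=trial, channel=channel, start_sample=start, stop_sample=stop)
        )
    out = replace(recording, data=data)
    return out, annotations
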