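"""Data model and standard-format I/O: recordings, events, epochs.

A :class:`Recording` is a continuous multichannel EEG signal in microvolts;
an :class:`EventList` holds cue onsets (trial starts) with task labels and
run membership; :func:`epoch` cuts the continuous signal into the fixed
12-s trial windows of the cue-based paradigm, producing an
:class:`EpochSet`.

EDF files are read through mne; writing uses a minimal plain-EDF encoder
(1-second data records, 16-bit samples, configurable symmetric physical
range).  Events travel in a sidecar CSV rather than EDF+ annotations, which
keeps round-trips deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDF_PHYSICAL_RANGE_UV = 200.0  # default symmetric physical range, µV


@dataclass
class Recording:
    """Continuous multichannel signal (channels × samples, µV)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    highpass: float | None = None
    lowpass: float | None = None
    notch: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EventList:
    """Cue events: onset sample, task label, run index."""

    onsets: np.ndarray
    labels: list[str]
    runs: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.runs = np.asarray(self.runs, dtype=np.int64)
        if not (len(self.onsets) == len(self.labels) == len(self.runs)):
            raise ValueError("onsets, labels and runs must have equal length")
        if len(self.onsets) > 1:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("event onsets must be strictly increasing")
            if np.any(np.diff(self.runs) < 0):
                raise ValueError("run indices must be non-decreasing")

    def __len__(self) -> int:
        return len(self.onsets)

    def to_csv(self, path: str | Path, fs: float) -> None:
        pd.DataFrame(
            {
                "onset_sample": self.onsets,
                "onset_s": self.onsets / fs,
                "label": self.labels,
                "run": self.runs,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventList":
        df = pd.read_csv(path)
        return cls(
            onsets=df["onset_sample"].to_numpy(),
            labels=[str(x) for x in df["label"]],
            runs=df["run"].to_numpy(),
        )


@dataclass
class EpochSet:
    """Trials cut to a fixed window around trial start (beep at t = 0).

    The time axis is relative to trial start; the auditory cue falls at
    ``cue_onset`` (2 s by default) and the reference interval at 1-2 s,
    one second before the cue.
    """

    data: np.ndarray  # trials × channels × samples
    fs: float
    channel_labels: list[str]
    labels: list[str]
    runs: np.ndarray
    cue_onset: float = 2.0
    reference_window: tuple[float, float] = (1.0, 2.0)
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        self.runs = np.asarray(self.runs, dtype=np.int64)
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if not self.reference_window[0] < self.reference_window[1] <= self.cue_onset:
            raise ValueError("reference window must precede the cue onset")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def trial_length(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def unrejected(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            data=self.data[keep],
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            labels=[l for l, k in zip(self.labels, keep) if k],
            runs=self.runs[keep],
            cue_onset=self.cue_onset,
            reference_window=self.reference_window,
        )


def epoch(
    recording: Recording,
    events: EventList,
    window: tuple[float, float] = (0.0, 12.0),
    cue_onset: float = 2.0,
    reference_window: tuple[float, float] = (1.0, 2.0),
) -> EpochSet:
    """Cut one trial per event; a pure slice, no filtering.

    ``window`` is half-open in samples: ``[onset + start·fs, onset + stop·fs)``,
    so a 12-s window at 512 Hz yields exactly 6144 samples.
    """
    start = int(round(window[0] * recording.fs))
    stop = int(round(window[1] * recording.fs))
    n_samp = stop - start
    if n_samp <= 0:
        raise ValueError("window must have positive length")
    trials = np.empty((len(events), recording.n_channels, n_samp))
    for i, onset in enumerate(events.onsets):
        lo, hi = onset + start, onset + stop
        if lo < 0 or hi > recording.n_samples:
            raise ValueError(
                f"event {i} (onset sample {onset}, label {events.labels[i]!r}): "
                f"window [{lo}, {hi}) outside recording of {recording.n_samples} samples"
            )
        trials[i] = recording.data[:, lo:hi]
    return EpochSet(
        data=trials,
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        labels=list(events.labels),
        runs=events.runs.copy(),
        cue_onset=cue_onset,
        reference_window=reference_window,
    )


# ---------------------------------------------------------------------------
# EDF I/O

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_raw(
    recording: Recording,
    path: str | Path,
    physical_range: float = EDF_PHYSICAL_RANGE_UV,
) -> None:
    """Write a plain EDF file (16-bit, 1-s records, ±``physical_range`` µV).

    The sampling rate must be an integer (one data record per second).
    Samples outside the physical range are clipped; the final partial
    record, if any, is zero-padded.
    """
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    ns = recording.n_channels
    n_rec = -(-recording.n_samples // fs)  # ceil

    dig_min, dig_max = -32768, 32767
    gain = 2.0 * physical_range / (dig_max - dig_min)
    padded = np.zeros((ns, n_rec * fs))
    padded[:, : recording.n_samples] = np.clip(
        recording.data, -physical_range, physical_range
    )
    digital = np.round((padded + physical_range) / gain + dig_min).astype("<i2")
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    prefilter = []
    if recording.highpass is not None:
        prefilter.append(f"HP:{recording.highpass}Hz")
    if recording.lowpass is not None:
        prefilter.append(f"LP:{recording.lowpass}Hz")
    if recording.notch is not None:
        prefilter.append(f"N:{recording.notch}Hz")
    prefilter_s = " ".join(prefilter)

    header = b"".join(
        [
            _edf_field(0, 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in recording.channel_labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{-physical_range:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{physical_range:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
            b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
            b"".join(_edf_field(prefilter_s, 80) for _ in range(ns)),
            b"".join(_edf_field(fs, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    records = digital.reshape(ns, n_rec, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())


def _edf_header_labels(path: str | Path) -> list[str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError:
            raise ValueError(f"{path}: malformed EDF header (signal count)") from None
        raw = fh.read(16 * ns)
    return [raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]


def read_raw(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = _edf_header_labels(path)
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel labels {labels}")

    import mne  # deferred: heavy import, only needed for file reading

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        highpass=float(raw.info["highpass"]) if raw.info["highpass"] else None,
        lowpass=float(raw.info["lowpass"]) if raw.info["lowpass"] else None,
    )
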