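"""Spatial Laplacian derivation and AR inverse-filter artifact rejection.

The online branch of the pipeline cannot rely on component inspection, so
transient non-stationarities (muscle/movement artifacts) are caught with a
whitening ("inverse") filter: an autoregressive model fitted per Laplacian
derivation on a resting-state segment.  On clean data the prediction error
of that filter is small white noise; a transient drives it far outside its
resting distribution.  The detection threshold is five times the RMS of
the resting-state prediction error, and any trial whose error exceeds the
threshold on a monitored channel is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from statsmodels.regression.linear_model import burg

from .io import EpochSet, Recording
from .montage import orthogonal_neighbors

THRESHOLD_FACTOR = 5.0  # × resting residual RMS

_MIN_RESTING_S = 10.0


@dataclass
class LaplacianMontage:
    """Per derived channel: center label → neighbor labels (≤ 4)."""

    neighbors: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for center, nbs in self.neighbors.items():
            if center in nbs:
                raise ValueError(f"{center!r} listed as its own neighbor")
            if len(nbs) == 0:
                raise ValueError(f"{center!r} has no neighbors")

    @classmethod
    def hjorth(cls, labels: list[str] | tuple[str, ...], min_neighbors: int = 2) -> "LaplacianMontage":
        """Orthogonal nearest-neighbor montage over the given electrodes.

        Edge channels keep whatever orthogonal neighbors exist; centers
        with fewer than ``min_neighbors`` are excluded from derivation.
        """
        nb = {}
        for lab in labels:
            found = orthogonal_neighbors(lab, available=list(labels))
            if len(found) >= min_neighbors:
                nb[lab] = tuple(found)
        return cls(neighbors=nb)

    @property
    def centers(self) -> list[str]:
        return list(self.neighbors)

    def validate_against(self, labels: list[str]) -> None:
        present = set(labels)
        for center, nbs in self.neighbors.items():
            if center not in present:
                raise KeyError(f"montage center {center!r} missing from data")
            for n in nbs:
                if n not in present:
                    raise KeyError(f"neighbor {n!r} of {center!r} missing from data")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({c: list(n) for c, n in self.neighbors.items()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LaplacianMontage":
        return cls({c: tuple(n) for c, n in json.loads(Path(path).read_text()).items()})


def laplacian_derive(x: Recording | EpochSet, montage: LaplacianMontage):
    """Subtract from each montage center the mean of its neighbors.

    Returns an object of the same type and shape.  Channels that are not
    montage centers are passed through unchanged (non-Laplacian; see
    :func:`laplacian_flags`).  The operation is linear.
    """
    montage.validate_against(x.channel_labels)
    data = x.data.copy()
    idx = {lab: i for i, lab in enumerate(x.channel_labels)}
    source = x.data
    for center, nbs in montage.neighbors.items():
        nb_idx = [idx[n] for n in nbs]
        data[..., idx[center], :] = source[..., idx[center], :] - source[..., nb_idx, :].mean(
            axis=-2
        )
    from dataclasses import replace

    return replace(x, data=data)


def laplacian_flags(labels: list[str], montage: LaplacianMontage) -> np.ndarray:
    """True where the channel is a derived (Laplacian) channel."""
    return np.array([lab in montage.neighbors for lab in labels])


@dataclass
class ARModel:
    """Whitening filter per monitored channel, with detection thresholds.

    ``threshold[c] = 5 × residual_rms[c]`` always; the residual RMS is the
    prediction error of the AR filter on the resting segment it was fitted
    on.
    """

    order: int
    fs: float
    coefficients: dict[str, np.ndarray]
    residual_rms: dict[str, float]
    channel_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("AR order must be ≥ 1")

    @property
    def thresholds(self) -> dict[str, float]:
        return {c: THRESHOLD_FACTOR * r for c, r in self.residual_rms.items()}

    def prediction_error(self, x: np.ndarray, channel: str) -> np.ndarray:
        """e[t] = x[t] − Σ a_k x[t−k]; first ``order`` samples are transient."""
        a = self.coefficients[channel]
        xc = x - self.channel_means.get(channel, 0.0)
        return sps.lfilter(np.concatenate(([1.0], -a)), [1.0], xc)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "order": self.order,
                    "fs": self.fs,
                    "coefficients": {c: list(a) for c, a in self.coefficients.items()},
                    "residual_rms": self.residual_rms,
                    "channel_means": self.channel_means,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ARModel":
        d = json.loads(Path(path).read_text())
        return cls(
            order=d["order"],
            fs=d["fs"],
            coefficients={c: np.asarray(a) for c, a in d["coefficients"].items()},
            residual_rms=d["residual_rms"],
            channel_means=d.get("channel_means", {}),
        )


def fit_inverse_filter(
    resting: Recording,
    montage: LaplacianMontage,
    order: int = 10,
    channels: list[str] | None = None,
) -> ARModel:
    """Fit per-channel AR models (Burg) on Laplacian-derived resting EEG.

    ``channels`` defaults to all derivable montage centers.  The detection
    threshold of each channel is fixed at 5 × RMS of the whitening-filter
    residual on this resting segment.
    """
    if order < 1:
        raise ValueError("AR order must be ≥ 1")
    if resting.duration < _MIN_RESTING_S:
        raise ValueError("resting segment must be at least 10 s")
    if resting.n_samples < 10 * order:
        raise ValueError("resting segment shorter than 10 × order samples")
    if not np.all(np.isfinite(resting.data)):
        raise ValueError("resting segment contains non-finite samples")
    derived = laplacian_derive(resting, montage)
    monitored = montage.centers if channels is None else channels
    coefficients, residual_rms, means = {}, {}, {}
    for ch in monitored:
        x = derived.data[derived.channel_index(ch)]
        mu = float(np.mean(x))
        ar, _sigma2 = burg(x, order=order, demean=True)
        e = sps.lfilter(np.concatenate(([1.0], -ar)), [1.0], x - mu)[order:]
        coefficients[ch] = np.asarray(ar)
        residual_rms[ch] = float(np.sqrt(np.mean(e**2)))
        means[ch] = mu
    return ARModel(
        order=order,
        fs=resting.fs,
        coefficients=coefficients,
        residual_rms=residual_rms,
        channel_means=means,
    )


@dataclass
class RejectionEvent:
    trial_index: int
    channel: str
    first_sample: int  # within-trial sample of first exceedance


def detect_artifact_trials(
    epochs: EpochSet,
    model: ARModel,
    montage: LaplacianMontage,
    min_run_length: int = 1,
) -> tuple[np.ndarray, list[RejectionEvent]]:
    """Flag trials whose whitening residual exceeds the channel threshold.

    A single-sample exceedance flags the trial by default (strict
    reading); ``min_run_length`` > 1 requires that many consecutive
    exceeding samples.  Decisions use only the trial's own samples and the
    fixed resting-state thresholds.  Returns (flags, rejection log); the
    flags are also stored on ``epochs.rejected``.
    """
    if epochs.fs != model.fs:
        raise ValueError(f"sampling-rate mismatch: epochs {epochs.fs} Hz, model {model.fs} Hz")
    flags = np.zeros(epochs.n_trials, dtype=bool)
    log: list[RejectionEvent] = []
    if epochs.n_trials == 0:
        return flags, log
    derived = laplacian_derive(epochs, montage)
    thresholds = model.thresholds
    for ch in model.coefficients:
        ci = derived.channel_index(ch)
        thr = thresholds[ch]
        for t in range(epochs.n_trials):
            e = model.prediction_error(derived.data[t, ci], ch)
            exceed = np.abs(e[model.order :]) > thr
            if min_run_length > 1:
                kernel = np.ones(min_run_length)
                exceed = np.convolve(exceed.astype(float), kernel, mode="valid") >= min_run_length
            if exceed.any():
                first = int(np.argmax(exceed)) + model.order
                if not flags[t]:
                    flags[t] = True
                    log.append(RejectionEvent(trial_index=t, channel=ch, first_sample=first))
    epochs.rejected = flags.copy()
    return flags, log
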