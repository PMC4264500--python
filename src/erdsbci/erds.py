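"""ERD/ERS time-frequency maps with t-percentile bootstrap significance.

Event-related desynchronization (ERD) / synchronization (ERS) is the
percent decrease / increase of band power relative to a pre-cue reference
interval:

    ERDS%(c, f, t) = (Ā(c, f, t) − R̄(c, f)) / R̄(c, f) × 100

where Ā is the trial-averaged band power at a time-frequency pixel and R̄
the trial-averaged power over the reference window (second 1-2 of the
trial).  Band power is computed by band-pass filtering, squaring and
smoothing; the default grid covers 6-40 Hz starting frequencies with 35
overlapping 2-Hz bands at 1-Hz steps.

Per-pixel significance uses a studentized (t-percentile) bootstrap over
trials at level α: trials are resampled with replacement, the ratio
statistic is studentized with a delta-method standard error per resample,
and a pixel is marked significant iff the resulting (1 − α) interval
excludes zero.  No correction across pixels is applied (pixel-wise
display convention); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import EpochSet

DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 1000
DEFAULT_SMOOTH_S = 0.25
DEFAULT_EDGE_S = 0.5  # filter settling margin masked at trial edges


def band_grid(
    f_start: float = 6.0, n_bands: int = 35, width: float = 2.0, step: float = 1.0
) -> list[tuple[float, float]]:
    """Overlapping analysis bands: band i = [f_start + i·step, +width]."""
    return [(f_start + i * step, f_start + i * step + width) for i in range(n_bands)]


def band_power_trials(
    epochs: EpochSet,
    band: tuple[float, float],
    smooth_s: float = DEFAULT_SMOOTH_S,
    zero_phase: bool = True,
) -> np.ndarray:
    """Per-trial band-power time courses: filter → square → moving average.

    Zero-phase (forward-backward) filtering by default, for offline maps;
    ``zero_phase=False`` gives the causal variant used online.  Output is
    trials × channels × samples, non-negative everywhere.
    """
    if not 0 < band[0] < band[1] < epochs.fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={epochs.fs / 2})")
    sos = sps.butter(4, band, btype="bandpass", fs=epochs.fs, output="sos")
    if zero_phase:
        y = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        y = sps.sosfilt(sos, epochs.data, axis=-1)
    p = y**2
    n_smooth = max(int(round(smooth_s * epochs.fs)), 1)
    return uniform_filter1d(p, size=n_smooth, axis=-1, mode="nearest")


@dataclass
class ERDSMap:
    """Per-channel time-frequency grid of percent power change + mask."""

    values: np.ndarray  # channels × bands × times, percent
    mask: np.ndarray  # True where significantly ≠ 0 (and not edge-masked)
    valid: np.ndarray  # False inside the edge (filter-settling) margin
    times: np.ndarray  # s, relative to trial start
    bands: list[tuple[float, float]]
    channel_labels: list[str]
    alpha: float
    n_boot: int
    reference_window: tuple[float, float]

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            mask=self.mask,
            valid=self.valid,
            times=self.times,
            bands=np.asarray(self.bands),
            channel_labels=np.asarray(self.channel_labels),
            alpha=self.alpha,
            n_boot=self.n_boot,
            reference_window=np.asarray(self.reference_window),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ERDSMap":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                mask=z["mask"],
                valid=z["valid"],
                times=z["times"],
                bands=[tuple(b) for b in z["bands"]],
                channel_labels=[str(s) for s in z["channel_labels"]],
                alpha=float(z["alpha"]),
                n_boot=int(z["n_boot"]),
                reference_window=tuple(z["reference_window"]),
            )

    def plot(self, label: str, ax=None, vlim: float = 150.0):
        """Render one channel's map (red = ERD, blue = ERS convention)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.channel(label)
        centers = [(lo + hi) / 2 for lo, hi in self.bands]
        im = ax.pcolormesh(
            self.times, centers, v, cmap="RdBu", vmin=-vlim, vmax=vlim, shading="nearest"
        )
        m = self.mask[self.channel_labels.index(label)]
        tt, ff = np.meshgrid(self.times, centers)
        ax.plot(tt[m], ff[m], ".k", ms=2)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(label)
        return im


def bootstrap_significance(
    activity: np.ndarray,
    reference: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    chunk: int = 50_000,
) -> np.ndarray:
    """Studentized bootstrap mask for the ERDS ratio statistic.

    Parameters
    ----------
    activity
        Per-trial pixel powers, shape (n_trials, ...pixels...).
    reference
        Per-trial reference-window mean power, broadcastable against
        ``activity`` (e.g. shape (n_trials, ...pixels_without_time..., 1)).
    alpha
        Two-sided level; a pixel is significant iff the (1 − α)
        t-percentile interval for mean ERDS excludes zero.
    n_boot
        Number of resamples (≥ 200).
    seed
        RNG seed; identical seed → identical mask.

    Returns a boolean array of pixel shape.  Pixels with zero bootstrap
    variance fall back to exact comparison of the point estimate with 0.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be ≥ 200")
    n = activity.shape[0]
    if n < 5:
        raise ValueError("need at least 5 trials for the bootstrap")
    pix_shape = activity.shape[1:]
    X = activity.reshape(n, -1)
    R = np.broadcast_to(reference, activity.shape).reshape(n, -1)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_boot, n))
    draws = rng.integers(0, n, size=(n_boot, n))
    for b in range(n_boot):
        counts[b] = np.bincount(draws[b], minlength=n)
    W = counts / n  # (B, n): resample weights

    mask = np.empty(X.shape[1], dtype=bool)
    for lo in range(0, X.shape[1], chunk):
        sl = slice(lo, min(lo + chunk, X.shape[1]))
        mask[sl] = _bootstrap_chunk(X[:, sl], R[:, sl], W, alpha)
    return mask.reshape(pix_shape)


def _ratio_se(xm, rm, vx, vr, cxr, n):
    """Delta-method SE of x̄/r̄ − 1 from sample moments."""
    var = (vx / rm**2 - 2.0 * xm * cxr / rm**3 + xm**2 * vr / rm**4) / n
    return np.sqrt(np.maximum(var, 0.0))


def _bootstrap_chunk(X, R, W, alpha):
    n = X.shape[0]
    bias = n / max(n - 1, 1)

    xm, rm = X.mean(0), R.mean(0)
    vx = X.var(0) * bias
    vr = R.var(0) * bias
    cxr = ((X - xm) * (R - rm)).mean(0) * bias
    theta = xm / rm - 1.0
    se = _ratio_se(xm, rm, vx, vr, cxr, n)

    # resample moments via the weight matrix (B, n) @ (n, P)
    xm_b = W @ X
    rm_b = W @ R
    vx_b = (W @ X**2 - xm_b**2) * bias
    vr_b = (W @ R**2 - rm_b**2) * bias
    cxr_b = (W @ (X * R) - xm_b * rm_b) * bias
    theta_b = xm_b / rm_b - 1.0
    se_b = _ratio_se(xm_b, rm_b, vx_b, vr_b, cxr_b, n)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (theta_b - theta) / se_b
    t[~np.isfinite(t)] = 0.0
    q_lo, q_hi = np.percentile(t, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    ci_lo = theta - q_hi * se
    ci_hi = theta - q_lo * se
    sig = (ci_lo > 0) | (ci_hi < 0)
    degenerate = se == 0
    sig[degenerate] = theta[degenerate] != 0
    return sig


def compute_erds_map(
    epochs: EpochSet,
    grid: list[tuple[float, float]] | None = None,
    reference_window: tuple[float, float] | None = None,
    smooth_s: float = DEFAULT_SMOOTH_S,
    step_s: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    significance: bool = True,
    edge_s: float = DEFAULT_EDGE_S,
) -> ERDSMap:
    """Full-trial ERD/ERS map with bootstrap significance mask.

    Requires ≥ 5 unrejected trials.  ``step_s`` sets the time resolution
    of the map (default: the smoothing length).  Pixels within ``edge_s``
    of the trial edges are excluded from the mask (filter settling).
    """
    epochs = epochs.unrejected()
    if epochs.n_trials < 5:
        raise ValueError("need at least 5 unrejected trials")
    grid = grid if grid is not None else band_grid()
    reference_window = reference_window or epochs.reference_window
    fs = epochs.fs
    step = max(int(round((step_s if step_s is not None else smooth_s) * fs)), 1)
    t_idx = np.arange(step // 2, epochs.n_samples, step)
    times = t_idx / fs
    r_lo, r_hi = (int(round(t * fs)) for t in reference_window)

    n_tr, n_ch = epochs.n_trials, epochs.data.shape[1]
    act = np.empty((n_tr, n_ch, len(grid), len(t_idx)))
    ref = np.empty((n_tr, n_ch, len(grid)))
    for bi, band in enumerate(grid):
        p = band_power_trials(epochs, band, smooth_s=smooth_s)
        act[:, :, bi, :] = p[:, :, t_idx]
        ref[:, :, bi] = p[:, :, r_lo:r_hi].mean(axis=-1)

    r_bar = ref.mean(axis=0)
    if np.any(r_bar == 0):
        raise ValueError("reference power is zero for some pixel (degenerate input)")
    values = (act.mean(axis=0) / r_bar[..., None] - 1.0) * 100.0

    valid = (times >= edge_s) & (times <= epochs.trial_length - edge_s)
    valid = np.broadcast_to(valid, values.shape).copy()

    if significance:
        mask = bootstrap_significance(
            act, ref[..., None], alpha=alpha, n_boot=n_boot, seed=seed
        )
        mask &= valid
    else:
        mask = np.zeros_like(values, dtype=bool)

    return ERDSMap(
        values=values,
        mask=mask,
        valid=valid,
        times=times,
        bands=list(grid),
        channel_labels=list(epochs.channel_labels),
        alpha=alpha,
        n_boot=n_boot,
        reference_window=tuple(reference_window),
    )
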