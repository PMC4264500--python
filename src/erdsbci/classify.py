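"""Log band-power features, LDA, and nested block-wise cross-validation.

The detection question is binary: does the EEG during a post-cue time
period differ from the pre-cue reference period?  Features are logarithmic
band-power values — causal band-pass filter, squaring, 1-s moving average
computed sample by sample, log — in five canonical bands (θ 4-7, α 7-13,
β_L 13-19, β_M 19-25, β_H 25-30 Hz).  Each 12-s trial is tiled into twelve
consecutive non-overlapping 1-s periods and a single value is read at the
middle of each period; the 1-2 s period (one second before the cue) is the
reference class, every post-cue period a candidate activity class.

One (Laplacian channel, band, time period) triple is selected by inner
cross-validated accuracy; the outer loop estimates the selected pipeline's
accuracy without bias.  Offline sessions use leave-one-block-out outer
folds (blocks = runs of 15 trials) with a 10-times-repeated 10-fold inner
CV; initial online runs use leave-one-trial-out.  Confusion matrices from
outer folds are summed (micro-averaged) before computing accuracy, and the
session p-value is a one-sided exact binomial test against chance 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import binomtest

from .io import EpochSet

#: canonical frequency bands (Hz); iteration order defines band indices
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta_low": (13.0, 19.0),
    "beta_mid": (19.0, 25.0),
    "beta_high": (25.0, 30.0),
}

_LOG_FLOOR = 1e-30


@dataclass
class FeatureSet:
    """Log band-power values per (trial, channel, band, 1-s segment)."""

    values: np.ndarray  # trials × channels × bands × segments
    channel_labels: list[str]
    band_names: list[str]
    segment_mids: np.ndarray  # s, midpoints of the 1-s periods
    reference_segment: int  # index of the 1-2 s period
    labels: list[str]
    blocks: np.ndarray  # run/block index per trial
    cue_onset: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.blocks = np.asarray(self.blocks, dtype=np.int64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def activity_segments(self) -> np.ndarray:
        """Indices of post-cue segments (candidate activity periods)."""
        return np.flatnonzero(self.segment_mids > self.cue_onset)

    def to_csv(self, path: str | Path) -> None:
        n_t, n_c, n_b, n_s = self.values.shape
        t, c, b, s = np.meshgrid(
            np.arange(n_t), np.arange(n_c), np.arange(n_b), np.arange(n_s), indexing="ij"
        )
        pd.DataFrame(
            {
                "trial": t.ravel(),
                "block": self.blocks[t.ravel()],
                "channel": np.asarray(self.channel_labels)[c.ravel()],
                "band": np.asarray(self.band_names)[b.ravel()],
                "segment": s.ravel(),
                "value": self.values.ravel(),
            }
        ).to_csv(path, index=False)


def causal_moving_average(p: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average along the last axis.

    Sample t averages ``p[max(0, t − window + 1) .. t]``: strictly causal,
    with a growing window during the first second.
    """
    csum = np.cumsum(p, axis=-1)
    out = np.empty_like(csum)
    w = min(window, p.shape[-1])
    out[..., :w] = csum[..., :w] / np.arange(1, w + 1)
    out[..., w:] = (csum[..., w:] - csum[..., :-w]) / w
    return out


def log_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], avg_s: float = 1.0
) -> np.ndarray:
    """Causal log band power: band-pass → square → 1-s trailing MA → log."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    p = sps.sosfilt(sos, x, axis=-1) ** 2
    ma = causal_moving_average(p, max(int(round(avg_s * fs)), 1))
    return np.log(np.maximum(ma, _LOG_FLOOR))


def extract_features(
    epochs: EpochSet, bands: dict[str, tuple[float, float]] | None = None
) -> FeatureSet:
    """One log band-power value per (channel, band, 1-s period) per trial.

    Values are read at the midpoint sample of each period, so the causal
    1-s average at the midpoint uses only samples up to that point.
    """
    epochs = epochs.unrejected()
    bands = bands if bands is not None else CANONICAL_BANDS
    fs = epochs.fs
    n_seg = int(epochs.trial_length)
    if abs(epochs.trial_length - n_seg) > 1e-9:
        raise ValueError("trial length must be an integer number of seconds")
    mids = (np.arange(n_seg) + 0.5)
    mid_idx = np.round(mids * fs).astype(int)
    ref_candidates = np.flatnonzero(
        (mids > epochs.reference_window[0]) & (mids < epochs.reference_window[1])
    )
    if len(ref_candidates) != 1:
        raise ValueError("exactly one segment must fall in the reference window")
    values = np.empty((epochs.n_trials, epochs.data.shape[1], len(bands), n_seg))
    for bi, band in enumerate(bands.values()):
        values[:, :, bi, :] = log_band_power(epochs.data, fs, band)[..., mid_idx]
    return FeatureSet(
        values=values,
        channel_labels=list(epochs.channel_labels),
        band_names=list(bands),
        segment_mids=mids,
        reference_segment=int(ref_candidates[0]),
        labels=list(epochs.labels),
        blocks=epochs.runs.copy(),
        cue_onset=epochs.cue_onset,
    )


def laplacian_features(
    epochs: EpochSet,
    montage,
    bands: dict[str, tuple[float, float]] | None = None,
) -> FeatureSet:
    """Features on Laplacian derivations, restricted to derivable centers.

    Convenience wrapper: spatial derivation, feature extraction, then the
    channel axis is cut down to the montage centers (the non-Laplacian
    pass-through channels are dropped from classification).
    """
    from .preprocessing import laplacian_derive

    derived = laplacian_derive(epochs, montage)
    f = extract_features(derived, bands=bands)
    keep = [f.channel_labels.index(c) for c in montage.centers]
    return FeatureSet(
        values=f.values[:, keep],
        channel_labels=list(montage.centers),
        band_names=f.band_names,
        segment_mids=f.segment_mids,
        reference_segment=f.reference_segment,
        labels=f.labels,
        blocks=f.blocks,
        cue_onset=f.cue_onset,
    )


# ---------------------------------------------------------------------------
# LDA

@dataclass
class LDAModel:
    """Linear discriminant: d(x) = w·x + b, predict class 1 iff d(x) > 0."""

    w: np.ndarray
    b: float
    class_labels: tuple[str, str] = ("reference", "activity")

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) > 0).astype(int)


def train_lda(X_ref: np.ndarray, X_act: np.ndarray, shrinkage: float | None = None) -> LDAModel:
    """Fisher LDA with pooled covariance and optional shrinkage.

    w ∝ Σ_pooled⁻¹ (μ_act − μ_ref); the bias places the boundary at the
    midpoint between the class means.  If ``shrinkage`` is None, the
    pooled covariance is shrunk toward a scaled identity only when it is
    ill-conditioned or the sample is small (n < 2·dims).
    """
    X0 = np.atleast_2d(np.asarray(X_ref, dtype=float))
    X1 = np.atleast_2d(np.asarray(X_act, dtype=float))
    if X0.ndim == 2 and X0.shape[1] != X1.shape[1]:
        raise ValueError("class feature dimensions differ")
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need at least 2 samples per class")
    if not (np.all(np.isfinite(X0)) and np.all(np.isfinite(X1))):
        raise ValueError("features must be finite")
    mu0, mu1 = X0.mean(0), X1.mean(0)
    d = X0.shape[1]
    n = len(X0) + len(X1)
    S = (np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1)
         + np.cov(X1, rowvar=False, ddof=1) * (len(X1) - 1)) / (n - 2)
    S = np.atleast_2d(S)
    nu = np.trace(S) / d
    if nu == 0:
        raise ValueError("all features constant")
    gamma = shrinkage
    if gamma is None:
        cond = np.linalg.cond(S)
        gamma = 0.1 if (n < 2 * d or not np.isfinite(cond) or cond > 1e10) else 0.0
    S_reg = (1 - gamma) * S + gamma * nu * np.eye(d)
    w = np.linalg.solve(S_reg, mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    return LDAModel(w=w, b=float(b))


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class SessionResult:
    """Outcome of one cross-validated session analysis."""

    channel: str
    band: str
    segment: int
    segment_time: float  # midpoint, s
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]; class 0 = reference
    accuracy: float  # percent
    p_value: float
    scheme: str
    per_fold_selected: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def significance_level(self) -> str:
        """Reporting tag: '0.01', '0.05' or 'n.s.'."""
        if self.p_value <= 0.01:
            return "0.01"
        if self.p_value <= 0.05:
            return "0.05"
        return "n.s."

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "channel": self.channel,
                    "band": self.band,
                    "segment": self.segment,
                    "segment_time": self.segment_time,
                    "confusion": self.confusion.tolist(),
                    "accuracy": self.accuracy,
                    "p_value": self.p_value,
                    "significance_level": self.significance_level,
                    "scheme": self.scheme,
                },
                indent=1,
            )
        )


def _combo_matrices(features: FeatureSet, flip_mask: np.ndarray | None):
    """Flatten (channel, band, activity-segment) into K columns.

    Returns V (n, K) activity values, R (n, K) reference values, and the
    (channel, band, segment) index triple per column.  ``flip_mask`` swaps
    the class roles of selected trials (label permutation for null
    checks).
    """
    segs = features.activity_segments
    n, n_c, n_b, _ = features.values.shape
    V = features.values[:, :, :, segs].reshape(n, -1)  # (n, C*B*S)
    R = np.repeat(
        features.values[:, :, :, features.reference_segment].reshape(n, -1), len(segs), axis=1
    )
    ci, bi, si = np.meshgrid(
        np.arange(n_c), np.arange(n_b), segs, indexing="ij"
    )
    combos = np.stack([ci.ravel(), bi.ravel(), si.ravel()], axis=1)
    if flip_mask is not None:
        flip_mask = np.asarray(flip_mask, dtype=bool)
        V = V.copy()
        R_orig = R
        R = R.copy()
        V[flip_mask] = R_orig[flip_mask]
        R[flip_mask] = features.values[:, :, :, segs].reshape(n, -1)[flip_mask]
    return V, R, combos


def _inner_accuracy(
    V: np.ndarray, R: np.ndarray, train_idx: np.ndarray, reps: int, folds: int, ss: np.random.SeedSequence
) -> np.ndarray:
    """Repeated k-fold inner CV accuracy per combo (vectorized 1-D LDA).

    In one dimension the LDA boundary is the midpoint of the class means
    and the orientation the sign of their difference, so each fold reduces
    to mean computations — evaluated for all combos at once.
    """
    rng = np.random.default_rng(ss)
    n_tr = len(train_idx)
    correct = np.zeros(V.shape[1])
    total = 0
    for _rep in range(reps):
        perm = train_idx[rng.permutation(n_tr)]
        fold_parts = np.array_split(perm, folds)
        sum_v = V[perm].sum(0)
        sum_r = R[perm].sum(0)
        for part in fold_parts:
            if len(part) == 0:
                continue
            tr_n = n_tr - len(part)
            mu1 = (sum_v - V[part].sum(0)) / tr_n
            mu0 = (sum_r - R[part].sum(0)) / tr_n
            mid = 0.5 * (mu0 + mu1)
            sgn = np.sign(mu1 - mu0)
            d_act = sgn * (V[part] - mid)
            d_ref = sgn * (R[part] - mid)
            correct += (d_act > 0).sum(0) + (d_ref <= 0).sum(0)
            total += 2 * len(part)
    return correct / total


def _select(inner_acc: np.ndarray, combos: np.ndarray) -> int:
    """Best inner accuracy; ties → earlier segment, lower band, channel order."""
    order = np.lexsort((combos[:, 0], combos[:, 1], combos[:, 2], -inner_acc))
    return int(order[0])


def _evaluate(V, R, combo_col, train_idx, test_idx) -> np.ndarray:
    """Train 1-D LDA on the training trials of one combo, return the 2×2
    confusion on the test trials ([[TN, FP], [FN, TP]])."""
    model = train_lda(R[train_idx, combo_col, None], V[train_idx, combo_col, None])
    pred_act = model.predict(V[test_idx, combo_col, None])
    pred_ref = model.predict(R[test_idx, combo_col, None])
    tp = int(pred_act.sum())
    fn = len(test_idx) - tp
    fp = int(pred_ref.sum())
    tn = len(test_idx) - fp
    return np.array([[tn, fp], [fn, tp]])


def _combo_name(features: FeatureSet, combo) -> tuple[str, str, int]:
    c, b, s = (int(v) for v in combo)
    return features.channel_labels[c], features.band_names[b], s


def _nested_cv(
    features: FeatureSet,
    outer_folds: list[np.ndarray],
    scheme: str,
    inner_reps: int,
    inner_folds: int,
    seed: int,
    flip_mask: np.ndarray | None,
) -> SessionResult:
    V, R, combos = _combo_matrices(features, flip_mask)
    n = features.n_trials
    all_idx = np.arange(n)
    confusion = np.zeros((2, 2), dtype=int)
    per_fold: list[tuple[str, str, int]] = []
    ss_root = np.random.SeedSequence([int(seed), 17])
    children = ss_root.spawn(len(outer_folds) + 1)
    for k, test_idx in enumerate(outer_folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(train_idx) < inner_folds:
            raise ValueError("fewer training samples than inner folds")
        acc = _inner_accuracy(V, R, train_idx, inner_reps, inner_folds, children[k])
        best = _select(acc, combos)
        per_fold.append(_combo_name(features, combos[best]))
        confusion += _evaluate(V, R, best, train_idx, test_idx)
    # headline triple: inner selection re-run on all trials (final model)
    acc_all = _inner_accuracy(V, R, all_idx, inner_reps, inner_folds, children[-1])
    best_all = combos[_select(acc_all, combos)]
    channel, band, seg = _combo_name(features, best_all)
    total = confusion.sum()
    accuracy = 100.0 * (confusion[0, 0] + confusion[1, 1]) / total
    p = accuracy_significance(confusion)
    return SessionResult(
        channel=channel,
        band=band,
        segment=seg,
        segment_time=float(features.segment_mids[seg]),
        confusion=confusion,
        accuracy=accuracy,
        p_value=p,
        scheme=scheme,
        per_fold_selected=per_fold,
    )


def nested_blockwise_cv(
    features: FeatureSet,
    inner_reps: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    flip_mask: np.ndarray | None = None,
) -> SessionResult:
    """Leave-one-block-out outer CV with 10×10-fold inner selection.

    Blocks are the runs of 15 trials.  Inner selection sees only training
    blocks; the selected (channel, band, segment) is evaluated on the
    held-out block and outer confusion matrices are micro-averaged.
    ``flip_mask`` (per-trial booleans) permutes class roles for null
    calibration.
    """
    blocks = np.unique(features.blocks)
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks for block-wise CV")
    outer = [np.flatnonzero(features.blocks == b) for b in blocks]
    for b, idx in zip(blocks, outer):
        if len(idx) == 0:
            raise ValueError(f"block {b} is empty")
    return _nested_cv(
        features, outer, "nested_blockwise", inner_reps, inner_folds, seed, flip_mask
    )


def loto_cv(
    features: FeatureSet,
    inner_reps: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    flip_mask: np.ndarray | None = None,
) -> SessionResult:
    """Leave-one-trial-out outer CV (used for initial single runs)."""
    if features.n_trials < 10:
        raise ValueError("need at least 10 trials for leave-one-trial-out CV")
    outer = [np.array([i]) for i in range(features.n_trials)]
    return _nested_cv(features, outer, "loto", inner_reps, inner_folds, seed, flip_mask)


def accuracy_significance(confusion: np.ndarray, chance: float = 0.5) -> float:
    """One-sided exact binomial p for the correct count vs. chance."""
    confusion = np.asarray(confusion)
    total = int(confusion.sum())
    if total <= 0:
        raise ValueError("empty confusion matrix")
    correct = int(confusion[0, 0] + confusion[1, 1])
    return float(binomtest(correct, total, chance, alternative="greater").pvalue)
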