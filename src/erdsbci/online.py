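"""Simulated online feedback loop with run-by-run classifier recalculation.

Mirrors the feedback stage of the paradigm: the classifier runs causally,
sample by sample, on one selected (Laplacian channel, band); a trial earns
the positive message only when the prediction is correct for more than
50% of the imagery period (strict inequality) and no artifact was
detected — artifact-flagged trials always receive "Pause".  Feedback is
therefore biased (only successes are announced), so each
:class:`TrialOutcome` records the true correct-prediction fraction
alongside the delivered message to keep the bias quantifiable.

After each run the classifier is recalculated from the up-to-three most
recent runs; accuracy is estimated with leave-one-trial-out CV when only
one run exists and nested block-wise CV otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .classify import (
    CANONICAL_BANDS,
    FeatureSet,
    LDAModel,
    SessionResult,
    log_band_power,
    loto_cv,
    nested_blockwise_cv,
    train_lda,
)
from .io import EventList, Recording, epoch
from .preprocessing import ARModel, LaplacianMontage, detect_artifact_trials, laplacian_derive

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeedbackRule:
    """Positive feedback iff correct fraction > threshold and no artifact."""

    fraction_threshold: float = 0.5
    correct_message: str = "correct"
    pause_message: str = "pause"

    def decide(self, correct_fraction: float, artifact: bool) -> str:
        if artifact:
            return self.pause_message
        return (
            self.correct_message
            if correct_fraction > self.fraction_threshold
            else self.pause_message
        )


@dataclass
class TrialOutcome:
    trial_index: int
    correct_fraction: float
    artifact: bool
    message: str


def simulate_online_run(
    recording: Recording,
    events: EventList,
    model: LDAModel,
    selected: tuple[str, str],
    armodel: ARModel,
    montage: LaplacianMontage,
    rule: FeedbackRule | None = None,
    trial_window: tuple[float, float] = (0.0, 12.0),
    imagery_window: tuple[float, float] = (2.0, 12.0),
) -> list[TrialOutcome]:
    """Replay a recorded run through the causal online pipeline.

    Per trial: Laplacian derivation, causal band-pass + squaring + 1-s
    trailing average + log on the selected channel/band, per-sample LDA
    prediction over the imagery period, and concurrent AR artifact
    detection.  The decision for trial t uses no samples beyond trial t.
    """
    rule = rule or FeedbackRule()
    channel, band_name = selected
    if band_name not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band_name!r}")
    if recording.fs != armodel.fs:
        raise ValueError("sampling-rate mismatch between recording and AR model")
    if channel not in montage.neighbors:
        raise ValueError(f"selected channel {channel!r} is not a Laplacian derivation")
    band = CANONICAL_BANDS[band_name]
    epochs = epoch(recording, events, window=trial_window)
    derived = laplacian_derive(epochs, montage)
    flags, _log = detect_artifact_trials(epochs, armodel, montage)
    ci = derived.channel_index(channel)
    lo = int(round(imagery_window[0] * recording.fs))
    hi = int(round(imagery_window[1] * recording.fs))
    outcomes = []
    for t in range(epochs.n_trials):
        feat = log_band_power(derived.data[t, ci], recording.fs, band)
        pred = (feat * model.w[0] + model.b > 0).astype(int)
        frac = float(np.mean(pred[lo:hi] == 1))  # true class during imagery: activity
        message = rule.decide(frac, bool(flags[t]))
        outcomes.append(
            TrialOutcome(
                trial_index=t, correct_fraction=frac, artifact=bool(flags[t]), message=message
            )
        )
        logger.info(
            "trial %d: correct fraction %.2f, artifact %s -> %s",
            t, frac, bool(flags[t]), message,
        )
    return outcomes


def write_transcript(outcomes: list[TrialOutcome], path: str | Path) -> None:
    """One JSON object per line (session transcript)."""
    with open(path, "w") as fh:
        for o in outcomes:
            fh.write(json.dumps(asdict(o)) + "\n")


def recalibrate(
    feature_history: list[FeatureSet],
    max_runs: int = 3,
    seed: int = 0,
) -> tuple[LDAModel, tuple[str, str, int], SessionResult]:
    """Recalculate the classifier from the most recent runs.

    Concatenates up to ``max_runs`` most recent runs (one
    :class:`FeatureSet` each), re-runs triple selection and training, and
    returns the refreshed model plus a cross-validated accuracy estimate:
    leave-one-trial-out when a single run exists, nested block-wise
    otherwise.  Deterministic for identical history and seed.
    """
    if len(feature_history) == 0:
        raise ValueError("no previous runs to recalibrate from")
    recent = feature_history[-max_runs:]
    merged = _concat_features(recent)
    if len(recent) == 1:
        result = loto_cv(merged, seed=seed)
    else:
        result = nested_blockwise_cv(merged, seed=seed)
    ci = merged.channel_labels.index(result.channel)
    bi = merged.band_names.index(result.band)
    x_ref = merged.values[:, ci, bi, merged.reference_segment, None]
    x_act = merged.values[:, ci, bi, result.segment, None]
    model = train_lda(x_ref, x_act)
    return model, (result.channel, result.band, result.segment), result


def _concat_features(runs: list[FeatureSet]) -> FeatureSet:
    first = runs[0]
    for r in runs[1:]:
        if r.channel_labels != first.channel_labels or r.band_names != first.band_names:
            raise ValueError("feature sets from different montages/bands")
    return FeatureSet(
        values=np.concatenate([r.values for r in runs], axis=0),
        channel_labels=list(first.channel_labels),
        band_names=list(first.band_names),
        segment_mids=first.segment_mids.copy(),
        reference_segment=first.reference_segment,
        labels=[l for r in runs for l in r.labels],
        blocks=np.concatenate(
            [np.full(r.n_trials, i, dtype=np.int64) for i, r in enumerate(runs)]
        ),
        cue_onset=first.cue_onset,
    )


def session_controller(
    latest_result: SessionResult | None,
    p_threshold: float = 0.05,
    manual_override: str | None = None,
) -> tuple[str, str]:
    """Decide whether to continue the feedback session.

    Deterministic policy: continue iff the latest cross-validated p-value
    is at or below the threshold.  ``manual_override`` ("continue" or
    "stop") models the clinical judgement hook.  Returns (action, reason).
    """
    if manual_override is not None:
        if manual_override not in ("continue", "stop"):
            raise ValueError("override must be 'continue' or 'stop'")
        reason = f"manual override: {manual_override}"
        logger.info(reason)
        return manual_override, reason
    if latest_result is None:
        raise ValueError("no session result available")
    if latest_result.p_value <= p_threshold:
        reason = (
            f"p = {latest_result.p_value:.3g} <= {p_threshold}: accuracy "
            f"{latest_result.accuracy:.1f}% above chance, continue feedback"
        )
        action = "continue"
    else:
        reason = f"p = {latest_result.p_value:.3g} > {p_threshold}: stop"
        action = "stop"
    logger.info(reason)
    return action, reason
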