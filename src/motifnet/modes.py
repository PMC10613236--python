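"""Coding-direction (stimulus/choice mode) computation and projections.

The choice axis is the unit-norm vector of per-neuron activity
differences between right- and left-choice trials averaged over the
pre-action epoch; the stimulus axis is defined analogously over the
stimulus epoch and stimulus sides.  Projections of single-trial
population activity onto an axis give one-dimensional selectivity
trajectories, baseline-subtracted per condition using the trial-averaged
ITI projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import EpochSpec, EPOCHS, EpochOutOfRangeError, Session, epoch_frames, get_epoch

logger = logging.getLogger(__name__)

MIN_NEURONS = 20
MIN_TRIALS_PER_SIDE = 5


class ExclusionError(ValueError):
    """Region/session fails the minimum neuron or trial counts."""


class DegenerateAxisError(ValueError):
    """The defining activity difference has zero norm."""


@dataclass
class ModeAxis:
    weights: np.ndarray
    mode: str  # "stimulus" | "choice"
    region: str
    defining_epoch: EpochSpec
    neuron_ids: np.ndarray
    orthogonalized: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class TrialProjection:
    """Per-trial projection time series aligned to a common trial window."""

    series: np.ndarray  # (n_trials, n_frames_in_window)
    trial_index: np.ndarray
    stimulus_side: np.ndarray
    choice_side: np.ndarray
    window: range  # frames relative to stimulus onset
    frame_rate: float
    mode: str

    def epoch_mean(self, epoch: "EpochSpec | str", go_cue_offset: int) -> np.ndarray:
        """Mean projection within *epoch* per trial.

        ``go_cue_offset`` is the go-cue frame relative to stimulus onset
        (constant across trials under the fixed task timing).
        """
        epoch = get_epoch(epoch)
        ref = 0 if epoch.reference_event == "stimulus_onset" else go_cue_offset
        start = ref + int(epoch.start_offset_s * self.frame_rate) - self.window.start
        stop = ref + int(epoch.end_offset_s * self.frame_rate) - self.window.start
        if start < 0 or stop > self.series.shape[1]:
            raise EpochOutOfRangeError("epoch outside the projection window")
        return self.series[:, start:stop].mean(axis=1)


def _group_trials(session: Session, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of (left, right) trials.  Choice groups by lick side
    regardless of stimulus (error trials included); stimulus groups by
    stimulus side regardless of choice."""
    col = "choice_side" if mode == "choice" else "stimulus_side"
    sides = session.trials[col].to_numpy()
    return sides == "L", sides == "R"


def compute_mode_axis(
    session: Session,
    region: str,
    mode: str,
    epoch: "EpochSpec | str | None" = None,
    min_neurons: int = MIN_NEURONS,
    min_trials: int = MIN_TRIALS_PER_SIDE,
) -> ModeAxis:
    """Unit-norm difference axis (right minus left) for one region.

    Positive weights mark right-preferring neurons.
    """
    if mode not in ("stimulus", "choice"):
        raise ValueError("mode must be 'stimulus' or 'choice'")
    if epoch is None:
        epoch = EPOCHS["pre_action"] if mode == "choice" else EPOCHS["stimulus"]
    epoch = get_epoch(epoch)
    idx = session.region_indices(region)
    if idx.size < min_neurons:
        raise ExclusionError(
            f"region {region} has {idx.size} < {min_neurons} neurons"
        )
    sub = session.subset_neurons(idx)
    means, kept = sub.trial_epoch_means(epoch)
    left, right = _group_trials(session, mode)
    left, right = left[kept], right[kept]
    if left.sum() < min_trials or right.sum() < min_trials:
        raise ExclusionError(
            f"fewer than {min_trials} usable trials per side "
            f"(L={left.sum()}, R={right.sum()})"
        )
    delta = means[right].mean(axis=0) - means[left].mean(axis=0)
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise DegenerateAxisError("right/left mean activities are identical")
    return ModeAxis(
        weights=delta / norm,
        mode=mode,
        region=region,
        defining_epoch=epoch,
        neuron_ids=session.neuron_ids[idx],
    )


def orthogonalize_axes(choice: ModeAxis, stimulus: ModeAxis) -> tuple[ModeAxis, ModeAxis]:
    """Gram-Schmidt in the order (choice, stimulus): the choice axis is
    kept, the stimulus axis loses its projection onto it."""
    if choice.weights.shape != stimulus.weights.shape:
        raise ValueError("axes are defined on different neuron sets")
    if not np.array_equal(choice.neuron_ids, stimulus.neuron_ids):
        raise ValueError("axes are defined on different neuron sets")
    residual = stimulus.weights - (stimulus.weights @ choice.weights) * choice.weights
    norm = np.linalg.norm(residual)
    if norm < 1e-12:
        raise DegenerateAxisError("stimulus axis is parallel to the choice axis")
    stim_out = ModeAxis(
        weights=residual / norm,
        mode=stimulus.mode,
        region=stimulus.region,
        defining_epoch=stimulus.defining_epoch,
        neuron_ids=stimulus.neuron_ids,
        orthogonalized=True,
    )
    choice_out = ModeAxis(
        weights=choice.weights.copy(),
        mode=choice.mode,
        region=choice.region,
        defining_epoch=choice.defining_epoch,
        neuron_ids=choice.neuron_ids,
        orthogonalized=True,
    )
    return choice_out, stim_out


def default_trial_window(session: Session) -> range:
    """Frames relative to stimulus onset covering ITI through response."""
    go_offset = int(
        (session.trials["go_cue_frame"] - session.trials["stimulus_onset_frame"]).iloc[0]
    )
    post = go_offset + int(1.5 * session.frame_rate)
    return range(-int(2 * session.frame_rate), post)


def project_trials(
    session: Session,
    region: str,
    axis: ModeAxis,
    window: range | None = None,
    baseline_epoch: "EpochSpec | str" = "iti_baseline",
    subtract_baseline: bool = True,
) -> TrialProjection:
    """Project each trial's population activity onto *axis*.

    The per-condition trial-averaged projection over the ITI baseline
    epoch is subtracted when ``subtract_baseline``.
    """
    idx = session.region_indices(region)
    if idx.size != axis.weights.size:
        raise ValueError(
            f"axis has {axis.weights.size} weights but region {region} "
            f"has {idx.size} neurons"
        )
    if window is None:
        window = default_trial_window(session)
    act = session.activity[idx]
    series, kept = [], []
    for ti, trial in session.trials.iterrows():
        s0 = int(trial.stimulus_onset_frame)
        start, stop = s0 + window.start, s0 + window.stop
        if start < 0 or stop > session.n_frames:
            logger.warning("trial %s outside recording for projection window", ti)
            continue
        series.append(act[:, start:stop].T @ axis.weights)
        kept.append(ti)
    series = np.asarray(series)
    kept = np.asarray(kept, dtype=int)
    trials = session.trials.loc[kept]
    proj = TrialProjection(
        series=series,
        trial_index=kept,
        stimulus_side=trials["stimulus_side"].to_numpy(),
        choice_side=trials["choice_side"].to_numpy(),
        window=window,
        frame_rate=session.frame_rate,
        mode=axis.mode,
    )
    if subtract_baseline and len(series):
        go_offset = int(
            (trials["go_cue_frame"] - trials["stimulus_onset_frame"]).iloc[0]
        )
        sides = proj.choice_side if axis.mode == "choice" else proj.stimulus_side
        base = proj.epoch_mean(baseline_epoch, go_offset)
        for side in np.unique(sides):
            mask = sides == side
            proj.series[mask] -= base[mask].mean()
    return proj


def _condition_sides(proj: TrialProjection) -> np.ndarray:
    return proj.choice_side if proj.mode == "choice" else proj.stimulus_side


def choice_selectivity(
    proj: TrialProjection, go_cue_offset: int, epoch: "EpochSpec | str" = "pre_action"
) -> float:
    """Mean(right-condition epoch means) minus mean(left-condition)."""
    sides = _condition_sides(proj)
    means = proj.epoch_mean(epoch, go_cue_offset)
    left, right = means[sides == "L"], means[sides == "R"]
    if left.size == 0 or right.size == 0:
        raise ValueError("both conditions must be present")
    return float(right.mean() - left.mean())


def interregion_coordination(
    proj_a: TrialProjection,
    proj_b: TrialProjection,
    go_cue_offset: int,
    epoch: "EpochSpec | str",
    scope: str = "both_types",
) -> dict:
    """Trial-by-trial Pearson r of epoch-averaged projections between two
    regions of the same session."""
    common, ia, ib = np.intersect1d(
        proj_a.trial_index, proj_b.trial_index, return_indices=True
    )
    a = proj_a.epoch_mean(epoch, go_cue_offset)[ia]
    b = proj_b.epoch_mean(epoch, go_cue_offset)[ib]
    sides = _condition_sides(proj_a)[ia]
    out: dict = {}
    if scope == "both_types":
        out["pooled"] = _safe_corr(a, b)
    elif scope == "same_type":
        for side in ("L", "R"):
            mask = sides == side
            out[side] = _safe_corr(a[mask], b[mask])
    else:
        raise ValueError("scope must be 'same_type' or 'both_types'")
    return out


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3:
        logger.warning("fewer than 3 trials in scope; correlation undefined")
        return float("nan")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def balanced_coordination(
    proj_a: TrialProjection,
    proj_b: TrialProjection,
    go_cue_offset: int,
    epoch: "EpochSpec | str",
    scope: str = "both_types",
    n_per_type: int = 40,
    iters: int = 100,
    seed: int = 0,
) -> float:
    """Trial-type-balanced coordination: resample ``n_per_type`` trials
    per side with replacement, correlate, repeat, average."""
    rng = np.random.default_rng(seed)
    common, ia, ib = np.intersect1d(
        proj_a.trial_index, proj_b.trial_index, return_indices=True
    )
    a = proj_a.epoch_mean(epoch, go_cue_offset)[ia]
    b = proj_b.epoch_mean(epoch, go_cue_offset)[ib]
    sides = _condition_sides(proj_a)[ia]
    idx_l = np.flatnonzero(sides == "L")
    idx_r = np.flatnonzero(sides == "R")
    if idx_l.size == 0 or idx_r.size == 0:
        raise ValueError("both trial types must be present")
    vals = []
    for _ in range(iters):
        pick = np.concatenate(
            [rng.choice(idx_l, n_per_type, replace=True),
             rng.choice(idx_r, n_per_type, replace=True)]
        )
        if scope == "same_type":
            rl = _safe_corr(a[pick[:n_per_type]], b[pick[:n_per_type]])
            rr = _safe_corr(a[pick[n_per_type:]], b[pick[n_per_type:]])
            vals.append(np.nanmean([rl, rr]))
        else:
            vals.append(_safe_corr(a[pick], b[pick]))
    return float(np.nanmean(vals))
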