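"""Trial-structured multi-region session container, epoch arithmetic and I/O.

A :class:`Session` bundles a nonnegative deconvolved-activity matrix
(neurons x frames) with per-neuron region labels, stable neuron ids, a
trial-event table and a frame rate.  Epochs are expressed in seconds
relative to a trial event and converted to half-open, 0-based frame
ranges; seconds are converted to frames by truncation toward zero so
that a 1-s epoch at 9.35 Hz spans 9 frames on either side of the event.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cortical areas of the standard 8-region imaging window.
DEFAULT_REGIONS = ("ALM", "M1a", "M1p", "S1fl", "vS1", "M2", "RSC", "PPC")

STAGES = ("naive", "intermediate", "expert")

TRIAL_COLUMNS = [
    "stimulus_side",
    "choice_side",
    "correct",
    "rewarded",
    "stimulus_onset_frame",
    "go_cue_frame",
    "response_frame",
    "distractor",
]


class SchemaError(ValueError):
    """A required field is missing or malformed in a stored session."""


class EmptySessionError(ValueError):
    """All neurons were removed by a filter."""


class EpochOutOfRangeError(ValueError):
    """An epoch extends outside the recorded frames for a trial."""


@dataclass(frozen=True)
class EpochSpec:
    """A half-open window ``[start, end)`` in seconds relative to an event."""

    name: str
    reference_event: str  # "stimulus_onset" | "go_cue"
    start_offset_s: float
    end_offset_s: float

    def __post_init__(self) -> None:
        if self.reference_event not in ("stimulus_onset", "go_cue"):
            raise ValueError(f"unknown reference event {self.reference_event!r}")
        if not self.start_offset_s < self.end_offset_s:
            raise ValueError("epoch start must precede end")


#: Named epochs used throughout the pipeline (offsets in seconds).
EPOCHS = {
    "stimulus": EpochSpec("stimulus", "stimulus_onset", 0.0, 1.0),
    "delay": EpochSpec("delay", "stimulus_onset", 1.0, 3.0),
    "pre_action": EpochSpec("pre_action", "go_cue", -1.0, 0.0),
    "iti_baseline": EpochSpec("iti_baseline", "stimulus_onset", -1.0, 0.0),
    "spontaneous_iti": EpochSpec("spontaneous_iti", "stimulus_onset", -2.0, 0.0),
}


def get_epoch(epoch: "EpochSpec | str") -> EpochSpec:
    if isinstance(epoch, EpochSpec):
        return epoch
    try:
        return EPOCHS[epoch]
    except KeyError:
        raise KeyError(f"unknown epoch {epoch!r}; known: {sorted(EPOCHS)}") from None


def _offset_to_frames(offset_s: float, frame_rate: float) -> int:
    # truncation toward zero: -1 s at 9.35 Hz is 9 frames back, not 10
    return int(offset_s * frame_rate)


def epoch_frames(epoch: "EpochSpec | str", trial: pd.Series, frame_rate: float,
                 n_frames: int | None = None) -> range:
    """Frame range of *epoch* for one trial (a row of the trial table).

    Returns a half-open ``range``.  Raises :class:`EpochOutOfRangeError`
    when the window would leave the recording (the caller is expected to
    skip such trials).
    """
    epoch = get_epoch(epoch)
    event_col = {"stimulus_onset": "stimulus_onset_frame", "go_cue": "go_cue_frame"}[
        epoch.reference_event
    ]
    event_frame = trial[event_col]
    if event_frame is None or (isinstance(event_frame, float) and np.isnan(event_frame)):
        raise EpochOutOfRangeError(f"trial has no {epoch.reference_event} event")
    event_frame = int(event_frame)
    start = event_frame + _offset_to_frames(epoch.start_offset_s, frame_rate)
    end = event_frame + _offset_to_frames(epoch.end_offset_s, frame_rate)
    if start < 0 or (n_frames is not None and end > n_frames):
        raise EpochOutOfRangeError(
            f"epoch {epoch.name!r} spans frames [{start}, {end}) outside the recording"
        )
    return range(start, end)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    t = trials.copy()
    for col in ("correct", "rewarded", "distractor"):
        t[col] = t[col].astype(bool)
    for col in ("stimulus_onset_frame", "go_cue_frame", "response_frame"):
        t[col] = t[col].astype(np.int64)
    bad = t["stimulus_onset_frame"] >= t["go_cue_frame"]
    if bad.any():
        raise SchemaError("stimulus_onset_frame must precede go_cue_frame")
    responded = t["choice_side"].isin(["L", "R"])
    if (t.loc[responded, "go_cue_frame"] > t.loc[responded, "response_frame"]).any():
        raise SchemaError("go_cue_frame must not exceed response_frame")
    want = responded & (t["choice_side"] == t["stimulus_side"])
    if not (t["correct"] == want).all():
        raise SchemaError("correct flag inconsistent with stimulus/choice sides")
    return t


@dataclass
class Session:
    """One imaging session: activity, labels and the trial-event table."""

    activity: np.ndarray  # (n_neurons, n_frames), nonnegative
    frame_rate: float
    neuron_ids: np.ndarray
    regions: np.ndarray  # per-neuron strings
    trials: pd.DataFrame
    stage: str = "expert"
    _skip_validation: dataclasses.InitVar[bool] = False

    def __post_init__(self, _skip_validation: bool = False) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.regions = np.asarray(self.regions, dtype=object)
        if _skip_validation:
            return
        if self.activity.ndim != 2:
            raise SchemaError("activity must be 2-D (neurons x frames)")
        if np.any(self.activity < 0):
            raise SchemaError("activity must be nonnegative")
        n = self.activity.shape[0]
        if len(self.neuron_ids) != n or len(self.regions) != n:
            raise SchemaError("neuron_ids/regions length must equal neuron count")
        if len(np.unique(self.neuron_ids)) != n:
            raise SchemaError("neuron_ids must be unique")
        self.trials = validate_trials(self.trials)
        nf = self.activity.shape[1]
        for col in ("stimulus_onset_frame", "go_cue_frame"):
            if ((self.trials[col] < 0) | (self.trials[col] >= nf)).any():
                raise SchemaError(f"{col} outside [0, n_frames)")

    # -- convenience ------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    def region_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.regions == region)

    def subset_neurons(self, idx: np.ndarray) -> "Session":
        idx = np.asarray(idx)
        return Session(
            activity=self.activity[idx],
            frame_rate=self.frame_rate,
            neuron_ids=self.neuron_ids[idx],
            regions=self.regions[idx],
            trials=self.trials,
            stage=self.stage,
        )

    def trial_epoch_means(self, epoch: "EpochSpec | str") -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron mean activity within *epoch*, per usable trial.

        Returns ``(means, trial_index)`` with ``means`` of shape
        (n_usable_trials, n_neurons).  Trials whose epoch leaves the
        recording are skipped with a warning.
        """
        means, kept = [], []
        for ti, trial in self.trials.iterrows():
            try:
                rng = epoch_frames(epoch, trial, self.frame_rate, self.n_frames)
            except EpochOutOfRangeError as exc:
                logger.warning("trial %s skipped: %s", ti, exc)
                continue
            means.append(self.activity[:, rng.start:rng.stop].mean(axis=1))
            kept.append(ti)
        if not means:
            return np.empty((0, self.n_neurons)), np.array([], dtype=int)
        return np.asarray(means), np.asarray(kept)


def filter_active_neurons(session: Session, z_threshold: float = 10.0,
                          window_s: float = 600.0) -> Session:
    """Keep neurons whose z-scored activity exceeds *z_threshold* at least
    once in every disjoint window of *window_s* seconds.

    Z-scores use whole-session per-neuron mean/SD; a trailing partial
    window is merged into the preceding full window, and a session
    shorter than one window is treated as a single window.
    """
    act = session.activity
    mu = act.mean(axis=1, keepdims=True)
    sd = act.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (act - mu) / sd, 0.0)
    win = max(1, int(window_s * session.frame_rate))
    edges = list(range(0, session.n_frames, win))
    if len(edges) > 1 and session.n_frames - edges[-1] < win:
        edges.pop()  # merge trailing partial window
    keep = np.ones(session.n_neurons, dtype=bool)
    for i, start in enumerate(edges):
        stop = edges[i + 1] if i + 1 < len(edges) else session.n_frames
        keep &= (z[:, start:stop] > z_threshold).any(axis=1)
    if not keep.any():
        raise EmptySessionError(
            f"no neuron passed the z>{z_threshold} per-{window_s}s-window filter"
        )
    if not keep.all():
        logger.info("inclusion filter removed %d/%d neurons", (~keep).sum(), keep.size)
    return session.subset_neurons(np.flatnonzero(keep))


# -- I/O -----------------------------------------------------------------

def write_session(session: Session, path: str) -> None:
    """Write a session to HDF5 (``.h5``/``.hdf5``) or NumPy ``.npz``."""
    path = str(path)
    if path.endswith(".npz"):
        np.savez_compressed(
            path,
            activity=session.activity,
            neuron_ids=session.neuron_ids,
            regions=np.asarray(session.regions, dtype=str),
            frame_rate=session.frame_rate,
            stage=session.stage,
            trials_json=json.dumps(session.trials.to_dict(orient="list")),
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity)
        f.create_dataset("neuron_ids", data=np.asarray(session.neuron_ids, dtype=np.int64))
        f.create_dataset(
            "regions", data=np.asarray(session.regions, dtype="S32")
        )
        f.attrs["frame_rate"] = session.frame_rate
        f.attrs["stage"] = session.stage
        g = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            vals = session.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                vals = np.asarray(vals, dtype="S8")
            g.create_dataset(col, data=vals)


def read_session(path: str) -> Session:
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            for key in ("activity", "neuron_ids", "regions", "frame_rate", "stage", "trials_json"):
                if key not in z:
                    raise SchemaError(f"session file missing field {key!r}")
            trials = pd.DataFrame(json.loads(str(z["trials_json"])))
            return Session(
                activity=z["activity"],
                frame_rate=float(z["frame_rate"]),
                neuron_ids=z["neuron_ids"],
                regions=np.asarray(z["regions"], dtype=object),
                trials=trials,
                stage=str(z["stage"]),
            )
    with h5py.File(path, "r") as f:
        for key in ("activity", "neuron_ids", "regions", "trials"):
            if key not in f:
                raise SchemaError(f"session file missing field {key!r}")
        for attr in ("frame_rate", "stage"):
            if attr not in f.attrs:
                raise SchemaError(f"session file missing attribute {attr!r}")
        cols = {}
        for col in TRIAL_COLUMNS:
            if col not in f["trials"]:
                raise SchemaError(f"trial table missing column {col!r}")
            vals = f["trials"][col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
        return Session(
            activity=f["activity"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            neuron_ids=f["neuron_ids"][()],
            regions=f["regions"][()].astype(str).astype(object),
            trials=pd.DataFrame(cols),
            stage=str(f.attrs["stage"]),
        )


def write_trials_csv(trials: pd.DataFrame, path: str) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path: str) -> pd.DataFrame:
    trials = pd.read_csv(path, keep_default_na=False)
    return validate_trials(trials)
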