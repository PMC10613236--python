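"""Design-matrix construction for the per-neuron encoding model.

Task predictors are event boxcars convolved with raised-cosine basis
sets: stimulus onset (3 bases over 1 s, per side), delay onset (5 bases
over 1.5 s, per choice side), response (5 bases over 1.5 s anchored
0.75 s before the end of the delay, per choice side), reward (3 bases
over 1 s) and forelimb movement distance (3 bases over 1 s, per side
when available).  Cell-coupling predictors are every other neuron's
activity shifted backward by 1 and 2 frames.  All columns are z-scored;
constant columns are dropped and recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..session import Session
from .basis import BasisSet, convolve_events, raised_cosine_basis

logger = logging.getLogger(__name__)

TASK_GROUPS = ("stimL", "stimR", "delayL", "delayR", "respL", "respR",
               "reward", "moveL", "moveR")


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_frames, n_columns), z-scored
    column_names: list
    column_groups: list
    target_id: int
    frame_rate: float
    dropped: list = field(default_factory=list)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def groups(self) -> "dict[str, np.ndarray]":
        out: dict[str, list] = {}
        for i, g in enumerate(self.column_groups):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(ix) for g, ix in out.items()}

    def columns_for(self, groups) -> np.ndarray:
        wanted = set([groups] if isinstance(groups, str) else groups)
        known = set(self.column_groups)
        unknown = wanted - known
        if unknown:
            raise KeyError(f"unknown predictor groups: {sorted(unknown)}")
        return np.asarray(
            [i for i, g in enumerate(self.column_groups) if g in wanted]
        )

    def coupling_groups(self) -> list:
        return [g for g in dict.fromkeys(self.column_groups) if g.startswith("coupling:")]

    def task_groups(self) -> list:
        return [g for g in dict.fromkeys(self.column_groups)
                if not g.startswith("coupling:")]


def coupling_group_tag(source_id: int, lag: int) -> str:
    return f"coupling:{source_id}:{lag}"


def parse_coupling_tag(tag: str) -> tuple[int, int]:
    _, src, lag = tag.split(":")
    return int(src), int(lag)


def _event_indicator(n_frames: int, frames: np.ndarray) -> np.ndarray:
    v = np.zeros(n_frames)
    frames = frames[(frames >= 0) & (frames < n_frames)]
    v[frames] = 1.0
    return v


def default_basis_sets(frame_rate: float) -> "dict[str, BasisSet]":
    return {
        "stim": raised_cosine_basis(3, 1.0, frame_rate),
        "delay": raised_cosine_basis(5, 1.5, frame_rate),
        "resp": raised_cosine_basis(5, 1.5, frame_rate, anchor_s=-0.75),
        "reward": raised_cosine_basis(3, 1.0, frame_rate),
        "move": raised_cosine_basis(3, 1.0, frame_rate),
    }


def build_design_matrix(
    session: Session,
    target_neuron: int,
    movement_speed: "np.ndarray | dict[str, np.ndarray] | None" = None,
    source_neurons: "np.ndarray | None" = None,
    basis_sets: "dict[str, BasisSet] | None" = None,
    lags: tuple = (1, 2),
    zscore: bool = True,
) -> DesignMatrix:
    """Design matrix for predicting ``target_neuron`` (a neuron id).

    ``movement_speed`` is the per-imaging-frame travelled distance of a
    forelimb (or a dict ``{"L": ..., "R": ...}``); ``source_neurons``
    optionally restricts the coupling predictors to a set of neuron ids
    (the target itself is always excluded).
    """
    fr = session.frame_rate
    nf = session.n_frames
    bases = basis_sets or default_basis_sets(fr)
    trials = session.trials
    cols, names, groups = [], [], []

    def add(block: np.ndarray, group: str) -> None:
        for j in range(block.shape[1]):
            cols.append(block[:, j])
            names.append(f"{group}_b{j}")
            groups.append(group)

    stim_off = int(1.0 * fr)
    resp_anchor = int(0.75 * fr)
    for side in ("L", "R"):
        m = trials["stimulus_side"] == side
        ev = _event_indicator(nf, trials.loc[m, "stimulus_onset_frame"].to_numpy())
        add(convolve_events(ev, bases["stim"]), f"stim{side}")
    for side in ("L", "R"):
        m = trials["choice_side"] == side
        ev = _event_indicator(
            nf, trials.loc[m, "stimulus_onset_frame"].to_numpy() + stim_off
        )
        add(convolve_events(ev, bases["delay"]), f"delay{side}")
    for side in ("L", "R"):
        m = trials["choice_side"] == side
        ev = _event_indicator(nf, trials.loc[m, "go_cue_frame"].to_numpy() - resp_anchor)
        add(convolve_events(ev, bases["resp"]), f"resp{side}")
    ev = _event_indicator(
        nf, trials.loc[trials["rewarded"], "response_frame"].to_numpy()
    )
    add(convolve_events(ev, bases["reward"]), "reward")
    if movement_speed is not None:
        speeds = movement_speed if isinstance(movement_speed, dict) else {
            "R": movement_speed
        }
        for side, speed in speeds.items():
            speed = np.asarray(speed, dtype=float)
            if speed.shape != (nf,):
                raise ValueError("movement_speed length must equal n_frames")
            add(convolve_events(speed, bases["move"]), f"move{side}")

    # lagged cell-coupling predictors
    target_row = int(np.flatnonzero(session.neuron_ids == target_neuron)[0])
    if source_neurons is None:
        source_neurons = np.asarray(
            [nid for nid in session.neuron_ids if nid != target_neuron]
        )
    else:
        source_neurons = np.asarray(source_neurons)
        if target_neuron in source_neurons:
            raise ValueError("the target neuron cannot be its own predictor")
    for src in source_neurons:
        row = int(np.flatnonzero(session.neuron_ids == src)[0])
        a = session.activity[row]
        for lag in lags:
            shifted = np.zeros(nf)
            shifted[lag:] = a[:-lag]
            cols.append(shifted)
            names.append(coupling_group_tag(int(src), lag))
            groups.append(coupling_group_tag(int(src), lag))

    X = np.column_stack(cols) if cols else np.empty((nf, 0))
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    dropped = [names[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning("dropping %d constant design columns for target %s",
                       len(dropped), target_neuron)
    X = X[:, keep]
    means, sds = means[keep], sds[keep]
    names = [n for n, k in zip(names, keep) if k]
    groups = [g for g, k in zip(groups, keep) if k]
    if zscore:
        X = (X - means) / sds
    return DesignMatrix(
        X=X,
        column_names=names,
        column_groups=groups,
        target_id=int(target_neuron),
        frame_rate=fr,
        dropped=dropped,
        column_means=means,
        column_sds=sds,
    )
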