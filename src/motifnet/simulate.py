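"""Synthetic multi-region session generator with planted ground truth.

Activity is drawn from a log-link point process: each neuron's per-frame
rate is ``exp(baseline + task kernels + lagged coupling + movement term +
noise)`` and events are Poisson.  Every planted effect (directed lagged
coupling, per-neuron tuning, movement gain) is returned in a
:class:`GroundTruth` record so downstream estimators can be scored
against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .session import Session, validate_trials

KERNEL_NAMES = ("stimL", "stimR", "delayL", "delayR", "actionL", "actionR", "reward")


class UnstableCouplingError(ValueError):
    """Planted lag-1 coupling has spectral radius >= the stability margin."""


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one synthetic session (or one learning stage)."""

    n_neurons_per_region: int = 30
    regions: tuple = ("PPC", "ALM")
    n_trials: int = 100
    frame_rate: float = 9.35
    coupling_density: float = 0.1
    enrichment_level: float = 0.5
    tuning_snr: float = 1.0
    choice_noise: float = 0.15
    coupling_weight: float = 0.5
    baseline_rate: float = 0.15
    coupling_input_cap: float = 2.0  # source counts saturate at this value
    excitatory_fraction: float = 0.5
    noise_sd: float = 0.05
    movement_gain_sd: float = 0.03
    # task timing (seconds)
    iti_s: float = 2.0
    stim_s: float = 1.0
    delay_s: float = 2.0
    response_s: float = 4.0
    # movement generator
    movement_dropout: float = 0.02
    movement_outliers: int = 5
    movement_stereotypy: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coupling_density", "enrichment_level", "choice_noise",
                     "movement_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_trials < 20:
            raise ConfigError("need n_trials >= 20 (>= 10 per trial type)")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "regions" in data:
            data["regions"] = tuple(data["regions"])
        return cls(**data)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted generative structure of one synthetic session."""

    coupling: pd.DataFrame  # columns: source, target, lag, weight
    tuning: pd.DataFrame  # per neuron: kernel weights + preferred side
    movement_gain: np.ndarray
    baseline_log_rate: np.ndarray
    neuron_ids: np.ndarray

    def edge_set(self) -> set:
        return set(zip(self.coupling["source"], self.coupling["target"]))

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "coupling": self.coupling.to_dict(orient="list"),
                "tuning": self.tuning.to_dict(orient="list"),
                "movement_gain": self.movement_gain.tolist(),
                "baseline_log_rate": self.baseline_log_rate.tolist(),
                "neuron_ids": self.neuron_ids.tolist(),
            }
        )


@dataclass
class MovementGroundTruth:
    outlier_frames: np.ndarray
    dropout_frames: np.ndarray


def _sec(cfg: SimConfig, s: float) -> int:
    return int(round(s * cfg.frame_rate))


def make_trial_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced L/R trial sequence with errors at rate ``choice_noise``."""
    n = cfg.n_trials
    sides = np.array(["L", "R"] * (n // 2 + 1))[:n]
    rng.shuffle(sides)
    flip = rng.random(n) < cfg.choice_noise
    choices = np.where(flip, np.where(sides == "L", "R", "L"), sides)
    trial_len = _sec(cfg, cfg.iti_s + cfg.stim_s + cfg.delay_s + cfg.response_s)
    starts = np.arange(n) * trial_len
    stim_on = starts + _sec(cfg, cfg.iti_s)
    go_cue = stim_on + _sec(cfg, cfg.stim_s + cfg.delay_s)
    response = go_cue + _sec(cfg, 0.3)
    trials = pd.DataFrame(
        {
            "stimulus_side": sides,
            "choice_side": choices,
            "correct": sides == choices,
            "rewarded": sides == choices,
            "stimulus_onset_frame": stim_on,
            "go_cue_frame": go_cue,
            "response_frame": response,
            "distractor": False,
        }
    )
    return validate_trials(trials)


def _plant_tuning(cfg: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Per-neuron kernel weights; preferred side alternates L/R."""
    side = np.array(["L", "R"])[np.arange(n) % 2]
    rng.shuffle(side)
    amp = cfg.tuning_snr * (0.5 + 0.5 * rng.random(n))
    w = {k: np.zeros(n) for k in KERNEL_NAMES}
    for i in range(n):
        s = side[i]
        w[f"stim{s}"][i] = amp[i]
        w[f"delay{s}"][i] = amp[i]
        w[f"action{s}"][i] = 0.5 * amp[i]
    w["reward"] = 0.3 * cfg.tuning_snr * rng.random(n)
    tuning = pd.DataFrame(w)
    tuning["preferred_side"] = side
    return tuning


def _plant_edges(
    cfg: SimConfig,
    n: int,
    side: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Directed edges at density ``coupling_density`` with the configured
    fraction joining same-preferred-side pairs."""
    rows = []
    for tgt in range(n):
        candidates = np.setdiff1d(np.arange(n), [tgt])
        k = rng.binomial(candidates.size, cfg.coupling_density)
        if k == 0:
            continue
        same = candidates[side[candidates] == side[tgt]]
        diff = candidates[side[candidates] != side[tgt]]
        # exact same-tuned quota (fractional part randomized) so realized
        # enrichment tracks the configured level tightly
        quota = cfg.enrichment_level * k
        k_same = int(quota) + (rng.random() < quota - int(quota))
        k_same = min(k_same, same.size)
        k_diff = min(k - k_same, diff.size)
        chosen = list(rng.choice(same, k_same, replace=False)) + \
            list(rng.choice(diff, k_diff, replace=False))
        for src in chosen:
            # mixed excitatory/inhibitory weights keep the recurrent drive
            # balanced so dense networks do not saturate
            sign = 1.0 if rng.random() < cfg.excitatory_fraction else -1.0
            rows.append((src, tgt, int(rng.integers(1, 3)), sign * cfg.coupling_weight))
    return pd.DataFrame(rows, columns=["source", "target", "lag", "weight"]).astype(
        {"source": int, "target": int, "lag": int, "weight": float}
    )


def _check_stability(coupling: pd.DataFrame, n: int, rate_gain: float,
                     margin: float = 0.95) -> None:
    """Guard against runaway excitation.

    The coupling acts multiplicatively on the log rate, so the relevant
    linearized loop gain is the lag-1 weight matrix scaled by the
    operating-point rate (``rate_gain``); its spectral radius must stay
    below the margin.
    """
    w1 = np.zeros((n, n))
    lag1 = coupling[coupling["lag"] == 1]
    w1[lag1["target"], lag1["source"]] = np.abs(lag1["weight"]) * rate_gain
    if len(lag1):
        radius = np.max(np.abs(np.linalg.eigvals(w1)))
        if radius >= margin:
            raise UnstableCouplingError(
                f"lag-1 coupling linearized spectral radius {radius:.3f} >= "
                f"{margin}; reduce coupling_weight or density"
            )


def _task_drive(cfg: SimConfig, trials: pd.DataFrame, tuning: pd.DataFrame,
                n_frames: int) -> np.ndarray:
    """Sum of planted task-kernel contributions to the log rate (n x T).

    Stimulus kernels follow the stimulus side; delay and action kernels
    follow the choice side, so stimulus and choice coding dissociate on
    error trials.
    """
    n = len(tuning)
    drive = np.zeros((n, n_frames))
    stim_f = _sec(cfg, cfg.stim_s)
    delay_f = _sec(cfg, cfg.delay_s)
    resp_f = _sec(cfg, min(cfg.response_s, 1.5))
    rew_f = _sec(cfg, 1.0)
    for _, tr in trials.iterrows():
        s0 = int(tr.stimulus_onset_frame)
        go = int(tr.go_cue_frame)
        stim_key = f"stim{tr.stimulus_side}"
        drive[:, s0:s0 + stim_f] += tuning[stim_key].to_numpy()[:, None]
        if tr.choice_side in ("L", "R"):
            drive[:, s0 + stim_f:s0 + stim_f + delay_f] += (
                tuning[f"delay{tr.choice_side}"].to_numpy()[:, None]
            )
            drive[:, go:go + resp_f] += tuning[f"action{tr.choice_side}"].to_numpy()[:, None]
        if tr.rewarded:
            r0 = int(tr.response_frame)
            drive[:, r0:r0 + rew_f] += tuning["reward"].to_numpy()[:, None]
    return drive


def movement_speed_per_frame(trace_xy: np.ndarray, n_frames: int, ratio: int) -> np.ndarray:
    """Downsample a 60-Hz trajectory to per-imaging-frame travelled distance."""
    d = np.sqrt(np.sum(np.diff(trace_xy, axis=0) ** 2, axis=1))
    d = np.concatenate([[0.0], d])
    out = np.zeros(n_frames)
    for i in range(n_frames):
        seg = d[i * ratio:(i + 1) * ratio]
        out[i] = seg.sum()
    return out


def generate_movement(
    cfg: SimConfig, trials: pd.DataFrame, seed: int, n_frames: int | None = None
) -> tuple[pd.DataFrame, MovementGroundTruth]:
    """60-Hz forelimb x/y traces with trial-locked components, confidence
    dropouts and isolated outliers.

    Returns a tracking-export-style table (bodypart, frame, x, y,
    likelihood) for the right forelimb plus a ground-truth sidecar with
    the injected outlier/dropout frames.
    """
    rng = np.random.default_rng(seed)
    cam_rate = 60.0
    ratio = cam_rate / cfg.frame_rate
    if n_frames is None:
        trial_len = _sec(cfg, cfg.iti_s + cfg.stim_s + cfg.delay_s + cfg.response_s)
        n_frames = int(trials["stimulus_onset_frame"].iloc[-1]) + trial_len
    n_cam = int(np.ceil(n_frames * ratio))
    t = np.arange(n_cam) / cam_rate
    x = 400.0 + np.zeros(n_cam)
    y = 300.0 + np.zeros(n_cam)
    # stereotyped response-epoch reach, direction by choice side
    for _, tr in trials.iterrows():
        if tr.choice_side not in ("L", "R"):
            continue
        go_t = tr.go_cue_frame / cfg.frame_rate
        mask = (t >= go_t) & (t < go_t + 1.0)
        phase = (t[mask] - go_t) / 1.0
        bump = 30.0 * np.sin(np.pi * phase) ** 2
        x[mask] += bump * (1 if tr.choice_side == "R" else -1)
        y[mask] += 0.5 * bump
    jitter = (1.0 - cfg.movement_stereotypy) * 20.0 + 0.5
    slow = np.cumsum(rng.normal(0, 0.08 * jitter, size=(n_cam, 2)), axis=0)
    slow -= slow.mean(axis=0)
    x += slow[:, 0] + rng.normal(0, 0.3 * jitter, n_cam)
    y += slow[:, 1] + rng.normal(0, 0.3 * jitter, n_cam)
    likelihood = np.minimum(1.0, 0.96 + 0.04 * rng.random(n_cam))
    drop = np.flatnonzero(rng.random(n_cam) < cfg.movement_dropout)
    likelihood[drop] = 0.5 * rng.random(drop.size)
    out_frames = rng.choice(n_cam - 2, size=min(cfg.movement_outliers, n_cam - 2),
                            replace=False) + 1
    for fr in out_frames:
        x[fr] += rng.choice([-1, 1]) * 200.0
        y[fr] += rng.choice([-1, 1]) * 200.0
    table = pd.DataFrame(
        {
            "bodypart": "right_forelimb",
            "frame": np.arange(n_cam),
            "x": x,
            "y": y,
            "likelihood": likelihood,
        }
    )
    return table, MovementGroundTruth(outlier_frames=np.sort(out_frames),
                                      dropout_frames=drop)


def generate_session(
    cfg: SimConfig, seed: int | None = None
) -> tuple[Session, GroundTruth]:
    """Draw one session from the planted generative model."""
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    n = cfg.n_neurons_per_region * len(cfg.regions)
    tuning = _plant_tuning(cfg, n, rng)
    coupling = _plant_edges(cfg, n, tuning["preferred_side"].to_numpy(), rng)
    _check_stability(coupling, n, rate_gain=2.0 * cfg.baseline_rate)
    movement_gain = np.abs(rng.normal(0, cfg.movement_gain_sd, n))
    return _generate_from_structure(
        cfg, tuning, coupling, movement_gain, seed=int(rng.integers(2**31))
    )


def _resample_edges_for_stage(
    cfg: SimConfig,
    prev: pd.DataFrame,
    side: np.ndarray,
    n: int,
    retained_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Next-stage edge set: ``retained_fraction`` of the previous stage's
    edges survive; the remainder is drawn fresh at this stage's density
    and enrichment."""
    n_keep = int(round(retained_fraction * len(prev)))
    keep_idx = rng.choice(len(prev), size=n_keep, replace=False) if n_keep else []
    kept = prev.iloc[np.sort(keep_idx)].reset_index(drop=True)
    fresh = _plant_edges(cfg, n, side, rng)
    kept_set = set(zip(kept["source"], kept["target"]))
    prev_set = set(zip(prev["source"], prev["target"]))
    new_rows = fresh[
        [
            (s, t) not in kept_set and (s, t) not in prev_set
            for s, t in zip(fresh["source"], fresh["target"])
        ]
    ]
    n_total = len(fresh)
    n_new = max(0, n_total - len(kept))
    # rebalance same-tuned counts so the stage's realized enrichment
    # matches its configured level despite the inherited retained edges
    def _same(df: pd.DataFrame) -> np.ndarray:
        return side[df["source"].to_numpy()] == side[df["target"].to_numpy()]

    want_same = int(round(cfg.enrichment_level * n_total)) - int(_same(kept).sum())
    want_same = max(0, min(want_same, n_new))
    new_same = new_rows[_same(new_rows)]
    new_diff = new_rows[~_same(new_rows)]
    take_same = new_same.iloc[
        rng.permutation(len(new_same))[:min(want_same, len(new_same))]
    ]
    take_diff = new_diff.iloc[
        rng.permutation(len(new_diff))[:min(n_new - len(take_same), len(new_diff))]
    ]
    picked = pd.concat([take_same, take_diff], ignore_index=True)
    if len(picked) < n_new:  # pools exhausted; top up with whatever remains
        leftover = new_rows.drop(take_same.index.union(take_diff.index))
        picked = pd.concat([picked, leftover.iloc[:n_new - len(picked)]],
                           ignore_index=True)
    return pd.concat([kept, picked], ignore_index=True)


def generate_learning_series(
    stage_configs: "list[SimConfig]",
    seed: int,
    retained_fraction: float = 0.32,
) -> list[tuple[Session, GroundTruth]]:
    """Matched naive/intermediate/expert sessions with shared neuron ids,
    shared tuning, and a configured retained-edge structure between
    consecutive stages."""
    if len({(c.n_neurons_per_region, c.regions, c.n_trials) for c in stage_configs}) != 1:
        raise ConfigError("stage configs must share layout (neurons, regions, trials)")
    rng = np.random.default_rng(seed)
    base = stage_configs[0]
    n = base.n_neurons_per_region * len(base.regions)
    tuning = _plant_tuning(base, n, rng)
    side = tuning["preferred_side"].to_numpy()
    movement_gain = np.abs(rng.normal(0, base.movement_gain_sd, n))
    edges: pd.DataFrame | None = None
    out = []
    for si, cfg in enumerate(stage_configs):
        if edges is None:
            edges = _plant_edges(cfg, n, side, rng)
        else:
            edges = _resample_edges_for_stage(cfg, edges, side, n, retained_fraction, rng)
        _check_stability(edges, n, rate_gain=2.0 * cfg.baseline_rate)
        sess, truth = _generate_from_structure(
            cfg, tuning, edges, movement_gain, seed=int(rng.integers(2**31))
        )
        sess.stage = ("naive", "intermediate", "expert")[si] if len(stage_configs) == 3 \
            else f"stage{si}"
        out.append((sess, truth))
    return out


def _generate_from_structure(
    cfg: SimConfig,
    tuning: pd.DataFrame,
    coupling: pd.DataFrame,
    movement_gain: np.ndarray,
    seed: int,
) -> tuple[Session, GroundTruth]:
    """Session draw with externally fixed tuning/coupling (stage series)."""
    rng = np.random.default_rng(seed)
    n = len(tuning)
    regions = np.repeat(list(cfg.regions), cfg.n_neurons_per_region).astype(object)
    trials = make_trial_table(cfg, rng)
    trial_len = _sec(cfg, cfg.iti_s + cfg.stim_s + cfg.delay_s + cfg.response_s)
    n_frames = int(trials["stimulus_onset_frame"].iloc[-1]) - _sec(cfg, cfg.iti_s) \
        + trial_len
    baseline = np.log(cfg.baseline_rate) * np.ones(n)
    move_table, _ = generate_movement(cfg, trials, seed=seed + 7919, n_frames=n_frames)
    speed = movement_speed_per_frame(
        move_table[["x", "y"]].to_numpy(), n_frames, int(round(60.0 / cfg.frame_rate))
    )
    speed_z = (speed - speed.mean()) / (speed.std() + 1e-12)
    eta0 = (
        baseline[:, None]
        + _task_drive(cfg, trials, tuning, n_frames)
        + movement_gain[:, None] * speed_z[None, :]
        + rng.normal(0, cfg.noise_sd, size=(n, n_frames))
    )
    w1 = np.zeros((n, n))
    w2 = np.zeros((n, n))
    for _, e in coupling.iterrows():
        (w1 if e.lag == 1 else w2)[int(e.target), int(e.source)] += e.weight
    activity = np.zeros((n, n_frames))
    cap = cfg.coupling_input_cap
    for t in range(n_frames):
        eta = eta0[:, t]
        # coupling acts on saturating source counts so the recurrent
        # excitation loop stays bounded
        if t >= 1:
            eta = eta + w1 @ np.minimum(activity[:, t - 1], cap)
        if t >= 2:
            eta = eta + w2 @ np.minimum(activity[:, t - 2], cap)
        activity[:, t] = rng.poisson(np.exp(np.minimum(eta, 2.5)))
    session = Session(
        activity=activity,
        frame_rate=cfg.frame_rate,
        neuron_ids=np.arange(n),
        regions=regions,
        trials=trials,
        stage="expert",
    )
    truth = GroundTruth(
        coupling=coupling.reset_index(drop=True),
        tuning=tuning,
        movement_gain=movement_gain,
        baseline_log_rate=baseline,
        neuron_ids=np.arange(n),
    )
    return session, truth
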