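"""FORCE-trained rate RNN with distractor and connection-ablation assays.

Dynamics (Euler, dt = 1 ms, tau = 10 ms):

    x(t) = x(t-1) + (dt/tau) * [-x(t-1) + z(t)]
    z(t) = J r(t) + W_stim I_stim + W_cue I_cue + noise
    r(t) = 1 / (1 + exp(-beta * (x - theta)))

Recurrent weights are trained by recursive least squares (FORCE): the
per-timestep error ``e = z - f`` against the target current ``f`` drives
the rank-1 update ``J <- J - a_learn * (e / (1 + r'Pr)) (P r)'`` with the
running inverse-correlation estimate ``P`` downdated accordingly.  Trial
types alternate across training epochs.

The trial clock runs from -3.5 s to 0 (delay offset = action): stimulus
pulse on [-3.0, -2.0] s (triangular, right trials only), go/delay cue on
[-2.1, -2.0] s, optional distractor boxcar on [-1.75, -1.25] s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

# integration / transfer-function constants
TAU_MS = 10.0
DT_MS = 1.0
BETA = 0.8
THETA = 3.0
NOISE_SD = 0.15
EPOCH_MS = 3500  # -0.5 s before stimulus onset to delay offset
TARGET_HZ = 93.5
SOURCE_HZ = 9.35


@dataclass
class RNNModel:
    J: np.ndarray
    W_stimulus: np.ndarray
    W_cue: np.ndarray
    P: np.ndarray
    g: float
    n_principal: int
    n_external: int
    beta: float = BETA
    theta: float = THETA
    tau_ms: float = TAU_MS
    dt_ms: float = DT_MS
    noise_sd: float = NOISE_SD

    @property
    def n_total(self) -> int:
        return self.J.shape[0]

    def copy(self) -> "RNNModel":
        return RNNModel(
            J=self.J.copy(), W_stimulus=self.W_stimulus.copy(),
            W_cue=self.W_cue.copy(), P=self.P.copy(), g=self.g,
            n_principal=self.n_principal, n_external=self.n_external,
            beta=self.beta, theta=self.theta, tau_ms=self.tau_ms,
            dt_ms=self.dt_ms, noise_sd=self.noise_sd,
        )


@dataclass
class TargetSet:
    """Target currents ``f`` per trial type at 93.5 Hz over the 3.5-s
    training epoch; the first ``n_principal`` rows mimic region activity,
    the rest reconstructed external input activity.  ``x0`` optionally
    records the trial-start current (defaults to the left-trial target
    at t=0)."""

    f_right: np.ndarray  # (n_units, n_samples)
    f_left: np.ndarray
    n_principal: int
    x0: "np.ndarray | None" = None

    def start_state(self) -> np.ndarray:
        return self.f_left[:, 0].copy() if self.x0 is None else self.x0.copy()

    @property
    def n_units(self) -> int:
        return self.f_right.shape[0]

    @property
    def n_samples(self) -> int:
        return self.f_right.shape[1]


def inverse_sigmoid(r: np.ndarray, beta: float = BETA, theta: float = THETA) -> np.ndarray:
    return theta + np.log(r / (1.0 - r)) / beta


def _boxcar_smooth(x: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def prepare_targets(
    activity_right: np.ndarray,
    activity_left: np.ndarray,
    external_right: "np.ndarray | None" = None,
    external_left: "np.ndarray | None" = None,
    n_external: int = 128,
    seed: int = 0,
    upsample: int = 10,
    smooth_ms: float = 400.0,
) -> TargetSet:
    """Transform trial-averaged activity into target currents.

    Activity (units x frames at 9.35 Hz) is clipped to [0.01, 4.99],
    normalized by 5, passed through the inverse sigmoid, upsampled by
    linear interpolation to 93.5 Hz and smoothed with a ~400 ms boxcar.
    Units whose normalized activity never reaches 1 SD (computed across
    all timesteps and units, per source) are excluded; external targets
    are sampled with replacement to ``n_external`` rows.
    """
    rng = np.random.default_rng(seed)

    def _norm(right: np.ndarray, left: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        right = np.clip(np.asarray(right, dtype=float), 0.01, 4.99) / 5.0
        left = np.clip(np.asarray(left, dtype=float), 0.01, 4.99) / 5.0
        sd = np.concatenate([right, left], axis=1).std()
        keep = np.maximum(right.max(axis=1), left.max(axis=1)) >= sd
        return right[keep], left[keep], keep

    pr, pl, keep = _norm(activity_right, activity_left)
    if pr.shape[0] == 0:
        raise ValueError("all principal units excluded by the 1-SD criterion")
    rows = [pr, pl]
    n_principal = pr.shape[0]
    if external_right is not None:
        er, el, _ = _norm(external_right, external_left)
        if er.shape[0] == 0:
            raise ValueError("all external units excluded by the 1-SD criterion")
        pick = rng.integers(0, er.shape[0], size=n_external)
        rows = [np.vstack([pr, er[pick]]), np.vstack([pl, el[pick]])]
    right, left = rows

    def _to_current(r: np.ndarray) -> np.ndarray:
        f = inverse_sigmoid(r)
        n_in = f.shape[1]
        t_in = np.arange(n_in)
        t_out = np.linspace(0, n_in - 1, n_in * upsample)
        out = np.vstack([np.interp(t_out, t_in, row) for row in f])
        win = max(1, int(round(smooth_ms / 1000.0 * TARGET_HZ)))
        return np.vstack([_boxcar_smooth(row, win) for row in out])

    return TargetSet(f_right=_to_current(right), f_left=_to_current(left),
                     n_principal=n_principal)


def init_rnn(n_total: int, g: float = 1.2, seed: int = 0,
             n_external: int = 0, p_alpha: float = 0.01,
             p_inverse: bool = False) -> RNNModel:
    """Random initial model: J ~ N(0, g/sqrt(n)), W_stim ~ N(0, 1),
    W_cue ~ N(0, 0.1).

    ``p_inverse=False`` initializes ``P = p_alpha * I`` (as stated in the
    training recipe); ``p_inverse=True`` uses the classic FORCE scaling
    ``P = I / p_alpha``, which converges far faster in practice and is
    what the working training configurations use.
    """
    if n_total < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    J = rng.normal(0.0, g / np.sqrt(n_total), size=(n_total, n_total))
    P = (np.eye(n_total) / p_alpha) if p_inverse else (p_alpha * np.eye(n_total))
    return RNNModel(
        J=J,
        W_stimulus=rng.normal(0.0, 1.0, n_total),
        W_cue=rng.normal(0.0, 0.1, n_total),
        P=P,
        g=g,
        n_principal=n_total - n_external,
        n_external=n_external,
    )


def trial_clock_inputs(
    n_steps: int = EPOCH_MS,
    stim_peak: float = 1.0,
    distractor_amp: float = 0.0,
) -> np.ndarray:
    """Stimulus-channel and cue-channel drive per integration step.

    Returns (2, n_steps): row 0 is the stimulus channel (triangular
    stimulus pulse plus any distractor boxcar), row 1 the cue channel.
    """
    t = np.arange(n_steps) - float(n_steps)  # ms relative to delay offset
    stim = np.zeros(n_steps)
    on = (t >= -3000) & (t <= -2000)
    stim[on] = stim_peak * (1.0 - np.abs(t[on] + 2500.0) / 500.0)
    cue = np.zeros(n_steps)
    on = (t >= -2100) & (t <= -2000)
    cue[on] = 1.0 - np.abs(t[on] + 2050.0) / 50.0
    if distractor_amp:
        stim[(t >= -1750) & (t <= -1250)] += distractor_amp
    return np.vstack([stim, cue])


@njit(cache=True)
def _sigmoid(x, beta, theta):
    return 1.0 / (1.0 + np.exp(-beta * (x - theta)))


@njit(cache=True)
def _force_epoch(J, P, Ws, Wc, x0, f, fmap, drive, noise, dt_tau, beta, theta,
                 a_learn):
    """One training epoch of per-timestep RLS updates; J and P are
    modified in place.  Returns the summed squared output error."""
    n = J.shape[0]
    T = noise.shape[1]
    x = x0.copy()
    r = _sigmoid(x, beta, theta)
    sse = 0.0
    for t in range(T):
        z = J @ r + Ws * drive[0, t] + Wc * drive[1, t] + noise[:, t]
        x = x + dt_tau * (-x + z)
        r = _sigmoid(x, beta, theta)
        ft = f[:, fmap[t]]
        e = z - ft
        for i in range(n):
            sse += e[i] * e[i]
        Pr = P @ r
        denom = 1.0 + r @ Pr
        scale = a_learn / denom
        for i in range(n):
            ei = e[i] * scale
            for j in range(n):
                J[i, j] -= ei * Pr[j]
        inv = 1.0 / denom
        for i in range(n):
            pi = Pr[i] * inv
            for j in range(n):
                P[i, j] -= pi * Pr[j]
    return sse / (n * T)


@njit(cache=True)
def _run_trial(J, Ws, Wc, x0, drive, noise, dt_tau, beta, theta, keep_every):
    n = J.shape[0]
    T = noise.shape[1]
    x = x0.copy()
    r = _sigmoid(x, beta, theta)
    n_keep = T // keep_every
    out = np.empty((n, n_keep))
    k = 0
    for t in range(T):
        z = J @ r + Ws * drive[0, t] + Wc * drive[1, t] + noise[:, t]
        x = x + dt_tau * (-x + z)
        r = _sigmoid(x, beta, theta)
        if (t + 1) % keep_every == 0 and k < n_keep:
            for i in range(n):
                out[i, k] = r[i]
            k += 1
    return out


def _target_step_map(n_steps: int, n_samples: int) -> np.ndarray:
    m = np.minimum((np.arange(n_steps) * n_samples) // n_steps, n_samples - 1)
    return m.astype(np.int64)


def force_train(
    model: RNNModel,
    targets: TargetSet,
    epochs: int = 500,
    a_learn: float = 0.05,
    seed: int = 0,
) -> tuple[RNNModel, float]:
    """FORCE-train a copy of ``model`` on the two-condition targets.

    Trial types alternate (right, left, ...) across epochs; each epoch
    runs the full 3.5-s trial with fresh stimulus amplitude and noise.
    Returns (trained model, MSE) where the MSE compares output to target
    on a pair of frozen-weight evaluation trials, averaged over time and
    units.
    """
    if targets.n_units != model.n_total:
        raise ValueError(
            f"targets have {targets.n_units} units, model {model.n_total}"
        )
    rng = np.random.default_rng(seed)
    model = model.copy()
    n = model.n_total
    T = EPOCH_MS
    fmap = _target_step_map(T, targets.n_samples)
    dt_tau = model.dt_ms / model.tau_ms
    for ep in range(epochs):
        right = ep % 2 == 0
        f = targets.f_right if right else targets.f_left
        stim_peak = rng.normal(1.0, 0.1) if right else 0.0
        drive = trial_clock_inputs(T, stim_peak=stim_peak)
        noise = rng.normal(0.0, model.noise_sd, size=(n, T))
        x0 = targets.start_state()
        _force_epoch(model.J, model.P, model.W_stimulus, model.W_cue, x0,
                     f, fmap, drive, noise, dt_tau, model.beta, model.theta,
                     a_learn)
        if not np.all(np.isfinite(model.J)):
            raise FloatingPointError(f"non-finite weights at epoch {ep}")
    mse = evaluate_mse(model, targets, seed=seed + 1)
    return model, mse


def evaluate_mse(model: RNNModel, targets: TargetSet, seed: int = 0,
                 noise_sd: "float | None" = None) -> float:
    """Frozen-weight output-vs-target MSE averaged over time, units and
    both trial types (``noise_sd=0`` evaluates the deterministic
    trajectory)."""
    rng = np.random.default_rng(seed)
    n, T = model.n_total, EPOCH_MS
    if noise_sd is None:
        noise_sd = model.noise_sd
    fmap = _target_step_map(T, targets.n_samples)
    dt_tau = model.dt_ms / model.tau_ms
    sse = 0.0
    for right in (True, False):
        f = targets.f_right if right else targets.f_left
        drive = trial_clock_inputs(T, stim_peak=1.0 if right else 0.0)
        noise = rng.normal(0.0, noise_sd, size=(n, T)) if noise_sd else np.zeros((n, T))
        x0 = targets.start_state()
        J_frozen = model.J.copy()
        P_dummy = np.eye(n) * 0.0  # no updates: use run kernel on z error
        # reuse training kernel with a_learn = 0 so errors are measured
        sse += _force_epoch(J_frozen, P_dummy, model.W_stimulus, model.W_cue,
                            x0, f, fmap, drive, noise, dt_tau, model.beta,
                            model.theta, 0.0)
    return sse / 2.0


def normalized_mse(model: RNNModel, targets: TargetSet, seed: int = 0,
                   noise_sd: "float | None" = None) -> float:
    """MSE divided by the across-time/unit variance of the targets."""
    mse = evaluate_mse(model, targets, seed=seed, noise_sd=noise_sd)
    f = np.concatenate([targets.f_right, targets.f_left], axis=1)
    return mse / float(f.var())


def mse_filter(models_with_mse: "list[tuple[RNNModel, float]]"):
    """Keep models whose MSE does not exceed mean + 1 SD of all MSEs."""
    if len(models_with_mse) < 2:
        raise ValueError("need at least 2 models")
    mses = np.array([m for _, m in models_with_mse])
    thresh = mses.mean() + mses.std()
    return [(mod, m) for mod, m in models_with_mse if m <= thresh]


def run_trials(
    model: RNNModel,
    trial_type: str,
    n_trials: int = 100,
    distractor_amp: float = 0.0,
    distractor_sd: float = 0.025,
    seed: int = 0,
    x0: "np.ndarray | None" = None,
    keep_every: int = 10,
) -> np.ndarray:
    """Forward-simulate frozen-weight trials.

    Returns unit activity (n_trials, n_units, n_kept_steps) sampled
    every ``keep_every`` ms.
    """
    if trial_type not in ("left", "right"):
        raise ValueError("trial_type must be 'left' or 'right'")
    rng = np.random.default_rng(seed)
    n, T = model.n_total, EPOCH_MS
    dt_tau = model.dt_ms / model.tau_ms
    if x0 is None:
        x0 = np.full(n, model.theta)
    out = np.empty((n_trials, n, T // keep_every))
    for k in range(n_trials):
        stim_peak = rng.normal(1.0, 0.1) if trial_type == "right" else 0.0
        amp = rng.normal(distractor_amp, distractor_sd) if distractor_amp else 0.0
        drive = trial_clock_inputs(T, stim_peak=stim_peak, distractor_amp=amp)
        noise = rng.normal(0.0, model.noise_sd, size=(n, T))
        out[k] = _run_trial(model.J, model.W_stimulus, model.W_cue, x0, drive,
                            noise, dt_tau, model.beta, model.theta, keep_every)
    return out


@dataclass
class ChoiceReadout:
    """Choice-mode axis over principal units plus reference end-of-delay
    values from unperturbed trials, normalized by the right-trial
    maximum."""

    axis: np.ndarray
    norm: float
    right_end: float
    left_end: float
    right_mean: np.ndarray
    left_mean: np.ndarray

    @property
    def halfway(self) -> float:
        return 0.5 * (self.right_end + self.left_end)


def choice_readout(
    model: RNNModel,
    targets: TargetSet,
    n_trials: int = 50,
    seed: int = 0,
    x0: "np.ndarray | None" = None,
) -> ChoiceReadout:
    """Compute the choice axis from unperturbed left/right trials.

    The axis is the unit-norm right-minus-left difference of principal
    unit activity averaged over the pre-action window (last second of
    the delay); projections are normalized by the maximum of the mean
    right-trial choice trajectory.
    """
    np_units = model.n_principal
    right = run_trials(model, "right", n_trials, seed=seed, x0=x0)[:, :np_units]
    left = run_trials(model, "left", n_trials, seed=seed + 1, x0=x0)[:, :np_units]
    n_kept = right.shape[2]
    pre = slice(int(n_kept * (1.0 - 1000.0 / EPOCH_MS)), n_kept)
    delta = right[:, :, pre].mean(axis=(0, 2)) - left[:, :, pre].mean(axis=(0, 2))
    nrm = np.linalg.norm(delta)
    if nrm == 0:
        raise ValueError("degenerate choice axis (right and left identical)")
    axis = delta / nrm
    right_proj = np.einsum("kut,u->kt", right, axis)
    left_proj = np.einsum("kut,u->kt", left, axis)
    right_mean = right_proj.mean(axis=0)
    left_mean = left_proj.mean(axis=0)
    norm = float(np.max(np.abs(right_mean)))
    if norm == 0:
        norm = 1.0
    right_mean = right_mean / norm
    left_mean = left_mean / norm
    end = slice(n_kept - max(1, n_kept // 35), n_kept)  # last ~100 ms
    right_end = float(right_mean[end].mean())
    left_end = float(left_mean[end].mean())
    if right_end <= left_end:
        raise ValueError(
            "reference trajectories unseparated at delay end; model is "
            "untrained or unstable"
        )
    return ChoiceReadout(axis=axis, norm=norm, right_end=right_end,
                         left_end=left_end, right_mean=right_mean,
                         left_mean=left_mean)


def decision_switch_fraction(
    model: RNNModel,
    readout: ChoiceReadout,
    distractor_amp: float = 0.25,
    n_trials: int = 100,
    seed: int = 0,
    x0: "np.ndarray | None" = None,
    return_end_values: bool = False,
):
    """Fraction of left-with-distractor trials whose end-of-delay choice
    value ends above the halfway point between the unperturbed right and
    left trajectories."""
    np_units = model.n_principal
    trials = run_trials(model, "left", n_trials, distractor_amp=distractor_amp,
                        seed=seed, x0=x0)[:, :np_units]
    n_kept = trials.shape[2]
    proj = np.einsum("kut,u->kt", trials, readout.axis) / readout.norm
    end = slice(n_kept - max(1, n_kept // 35), n_kept)
    end_vals = proj[:, end].mean(axis=1)
    frac = float(np.mean(end_vals > readout.halfway))
    if return_end_values:
        return frac, end_vals
    return frac


def ablate_external(
    model: RNNModel,
    readout: ChoiceReadout,
    fraction: float,
    iters: int = 100,
    distractor_amp: float = 0.25,
    n_trials: int = 25,
    seed: int = 0,
    x0: "np.ndarray | None" = None,
) -> dict:
    """Switch fraction after random ablation of principal<->external
    connections.

    Per iteration the stated fraction of entries in both off-diagonal
    blocks of J is zeroed and the distractor switch fraction recomputed.
    Iterations where the mean distractor end-of-delay choice value falls
    below the unperturbed left trajectory are excluded (counted).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if model.n_external == 0:
        raise ValueError("model has no external units")
    rng = np.random.default_rng(seed)
    npr, nex = model.n_principal, model.n_external
    fractions = []
    excluded = 0
    for it in range(iters):
        m = model.copy()
        for block in ((slice(0, npr), slice(npr, npr + nex)),
                      (slice(npr, npr + nex), slice(0, npr))):
            sub = m.J[block]
            mask = rng.random(sub.shape) < fraction
            sub[mask] = 0.0
            m.J[block] = sub
        frac, end_vals = decision_switch_fraction(
            m, readout, distractor_amp, n_trials,
            seed=int(rng.integers(2**31)), x0=x0, return_end_values=True,
        )
        if end_vals.mean() < readout.left_end:
            excluded += 1
            continue
        fractions.append(frac)
    return {
        "switch_fractions": np.asarray(fractions),
        "mean_switch_fraction": float(np.mean(fractions)) if fractions else float("nan"),
        "excluded_iterations": excluded,
    }


# -- checkpoints ---------------------------------------------------------

def save_model(model: RNNModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        for name in ("J", "W_stimulus", "W_cue", "P"):
            f.create_dataset(name, data=getattr(model, name))
        for attr in ("g", "n_principal", "n_external", "beta", "theta",
                     "tau_ms", "dt_ms", "noise_sd"):
            f.attrs[attr] = getattr(model, attr)


def load_model(path: str) -> RNNModel:
    with h5py.File(path, "r") as f:
        return RNNModel(
            J=f["J"][()], W_stimulus=f["W_stimulus"][()], W_cue=f["W_cue"][()],
            P=f["P"][()], g=float(f.attrs["g"]),
            n_principal=int(f.attrs["n_principal"]),
            n_external=int(f.attrs["n_external"]),
            beta=float(f.attrs["beta"]), theta=float(f.attrs["theta"]),
            tau_ms=float(f.attrs["tau_ms"]), dt_ms=float(f.attrs["dt_ms"]),
            noise_sd=float(f.attrs["noise_sd"]),
        )


def record_trajectory(
    model: RNNModel,
    stim_peak: float,
    x0: "np.ndarray | None" = None,
    J: "np.ndarray | None" = None,
) -> np.ndarray:
    """Noise-free total-input trajectory ``z(t)`` of a network, sampled
    on the 93.5-Hz target grid (a realizable training target)."""
    n, T = model.n_total, EPOCH_MS
    drive = trial_clock_inputs(T, stim_peak=stim_peak)
    if x0 is None:
        x0 = np.zeros(n)
    Juse = model.J if J is None else J
    r = _run_trial(Juse, model.W_stimulus, model.W_cue, x0, drive,
                   np.zeros((n, T)), model.dt_ms / model.tau_ms, model.beta,
                   model.theta, 1)
    z = Juse @ r + np.outer(model.W_stimulus, drive[0]) \
        + np.outer(model.W_cue, drive[1])
    n_samples = int(round(EPOCH_MS / 1000.0 * TARGET_HZ))
    idx = np.linspace(0, T - 1, n_samples).astype(int)
    return z[:, idx]


def make_innate_targets(model: RNNModel, n_external: "int | None" = None) -> TargetSet:
    """Targets recorded from the model's own untrained dynamics under
    right/left inputs (exactly realizable; training mainly stabilizes
    the innate trajectory against noise)."""
    x0 = np.zeros(model.n_total)
    fr = record_trajectory(model, 1.0, x0)
    fl = record_trajectory(model, 0.0, x0)
    return TargetSet(f_right=fr, f_left=fl, n_principal=model.n_principal,
                     x0=x0.copy())


def make_attractor_targets(
    model: RNNModel,
    self_excitation: float = 7.0,
    inhibition: float = 2.5,
    background: float = 0.5,
    ready_level: float = 4.0,
    external_bias: float = 2.5,
) -> TargetSet:
    """Two-condition targets recorded from an engineered winner-take-all
    teacher network.

    The teacher adds, on top of a scaled copy of the model's random
    recurrence, self-excitation within two pools (the units driven
    positively vs negatively by the stimulus channel) and mutual
    inhibition between them.  Trials start with the "left" pool active;
    a right stimulus flips the network into the opposing attractor, so
    the recorded trajectories carry a genuine bistable choice geometry
    whose distractor-switch threshold falls near the assayed amplitudes.
    """
    Ws = model.W_stimulus
    dA = np.maximum(Ws, 0.0)
    dB = np.maximum(-Ws, 0.0)
    # the holding (left) pool leans on the external units so that
    # ablating principal<->external connections weakens its attractor,
    # while the flipped (right) pool is purely principal
    ext = np.arange(model.n_principal, model.n_total)
    dA[ext] = 0.0
    dB[ext] *= external_bias
    dA /= np.linalg.norm(dA)
    dB /= np.linalg.norm(dB)
    J_teacher = (
        background * model.J
        + self_excitation * (np.outer(dA, dA) + np.outer(dB, dB))
        - inhibition * (np.outer(dA, dB) + np.outer(dB, dA))
    )
    x0 = np.where(dB > 0, ready_level, 0.0)
    fr = record_trajectory(model, 1.0, x0, J=J_teacher)
    fl = record_trajectory(model, 0.0, x0, J=J_teacher)
    return TargetSet(f_right=fr, f_left=fl, n_principal=model.n_principal,
                     x0=x0.copy())


def _teacher_pieces(model: RNNModel, external_bias: float):
    Ws = model.W_stimulus
    dA = np.maximum(Ws, 0.0)
    dB = np.maximum(-Ws, 0.0)
    ext = np.arange(model.n_principal, model.n_total)
    dA[ext] = 0.0
    dB[ext] *= external_bias
    dA /= np.linalg.norm(dA)
    dB /= np.linalg.norm(dB)
    return dA, dB


def calibrate_attractor_targets(
    model: RNNModel,
    threshold_target: float = 0.30,
    self_excitation: float = 7.0,
    background: float = 0.5,
    ready_level: float = 4.0,
    external_bias: float = 2.5,
    inhibition_range: tuple = (0.5, 8.0),
    n_bisect: int = 9,
) -> TargetSet:
    """Attractor targets with the teacher's mutual inhibition bisected so
    its deterministic distractor-switch threshold sits near
    ``threshold_target`` (stronger inhibition raises the threshold).

    Raises ValueError when no inhibition level in the range produces a
    valid teacher (left holds without input, right stimulus switches).
    """
    dA, dB = _teacher_pieces(model, external_bias)
    x0 = np.where(dB > 0, ready_level, 0.0)
    n, T = model.n_total, EPOCH_MS
    dt_tau = model.dt_ms / model.tau_ms

    def teacher_J(ki: float) -> np.ndarray:
        return (background * model.J
                + self_excitation * (np.outer(dA, dA) + np.outer(dB, dB))
                - ki * (np.outer(dA, dB) + np.outer(dB, dA)))

    def end_state(J: np.ndarray, stim: float, amp: float) -> float:
        drive = trial_clock_inputs(T, stim_peak=stim, distractor_amp=amp)
        r = _run_trial(J, model.W_stimulus, model.W_cue, x0, drive,
                       np.zeros((n, T)), dt_tau, model.beta, model.theta, 50)
        return float((dA - dB) @ r[:, -1])

    def switch_threshold(ki: float) -> "float | None":
        J = teacher_J(ki)
        left = end_state(J, 0.0, 0.0)
        right = end_state(J, 1.0, 0.0)
        if right - left < 1.0:  # not bistable / stimulus fails
            return None
        half = 0.5 * (left + right)
        lo, hi = 0.05, 0.8
        if end_state(J, 0.0, hi) < half:
            return None  # even a strong distractor never switches
        if end_state(J, 0.0, lo) > half:
            return lo
        for _ in range(7):
            mid = 0.5 * (lo + hi)
            if end_state(J, 0.0, mid) > half:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    ki_lo, ki_hi = inhibition_range
    best = None
    for _ in range(n_bisect):
        ki = 0.5 * (ki_lo + ki_hi)
        thr = switch_threshold(ki)
        if thr is None:
            ki_hi = ki  # too much inhibition (or invalid); soften
            continue
        if best is None or abs(thr - threshold_target) < abs(best[1] - threshold_target):
            best = (ki, thr)
        if thr > threshold_target:
            ki_hi = ki
        else:
            ki_lo = ki
    if best is None:
        raise ValueError("no valid attractor teacher in the inhibition range")
    return make_attractor_targets(
        model, self_excitation=self_excitation, inhibition=best[0],
        background=background, ready_level=ready_level,
        external_bias=external_bias,
    )
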