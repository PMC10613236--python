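"""Reduced-rank regression between source and target populations.

The rank-r solution is the ordinary-least-squares coefficient matrix
projected onto the top-r right singular structure of the fitted values;
predictive performance is cross-validated fraction of variance
explained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .session import Session, get_epoch

logger = logging.getLogger(__name__)


@dataclass
class RRRFit:
    coefficients: np.ndarray  # (p, q), rank <= rank
    intercept: np.ndarray  # (q,)
    rank: int
    r2_train: float
    r2_cv: float


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xm = X.mean(axis=0)
    Ym = Y.mean(axis=0)
    Xc, Yc = X - Xm, Y - Ym
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return B, Ym - Xm @ B


def _truncate(B: np.ndarray, X: np.ndarray, Y: np.ndarray, rank: int) -> np.ndarray:
    """Project the OLS solution onto the top-``rank`` singular structure
    of the fitted values."""
    Xc = X - X.mean(axis=0)
    fitted = Xc @ B
    _, _, vt = np.linalg.svd(fitted, full_matrices=False)
    V = vt[:rank].T
    return B @ V @ V.T


def fit_rrr(
    X: np.ndarray,
    Y: np.ndarray,
    rank: int,
    cv_folds: int = 10,
    fold_of: "np.ndarray | None" = None,
) -> RRRFit:
    """Rank-constrained linear prediction of ``Y`` from ``X``.

    ``fold_of`` optionally assigns each sample to a CV fold (e.g. by
    trial); contiguous folds are used otherwise.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if rank > min(p, q):
        raise ValueError(f"rank {rank} exceeds min(p, q) = {min(p, q)}")
    if n <= max(p, q):
        logger.warning("fewer samples (%d) than features; OLS may be unstable", n)
    B_full, _ = _ols(X, Y)
    B = _truncate(B_full, X, Y, rank)
    intercept = Y.mean(axis=0) - X.mean(axis=0) @ B
    pred = X @ B + intercept
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2)
    r2_train = 1.0 - np.sum((Y - pred) ** 2) / ss_tot
    if fold_of is None:
        fold_of = np.repeat(np.arange(cv_folds), np.diff(
            np.linspace(0, n, cv_folds + 1).astype(int)
        ))
    ss_res_cv = 0.0
    ss_tot_cv = 0.0
    for k in np.unique(fold_of):
        val = fold_of == k
        if val.sum() == 0 or (~val).sum() <= p:
            continue
        Bk_full, _ = _ols(X[~val], Y[~val])
        Bk = _truncate(Bk_full, X[~val], Y[~val], rank)
        ck = Y[~val].mean(axis=0) - X[~val].mean(axis=0) @ Bk
        pk = X[val] @ Bk + ck
        ss_res_cv += np.sum((Y[val] - pk) ** 2)
        ss_tot_cv += np.sum((Y[val] - Y[~val].mean(axis=0)) ** 2)
    r2_cv = 1.0 - ss_res_cv / ss_tot_cv if ss_tot_cv > 0 else float("nan")
    return RRRFit(coefficients=B, intercept=intercept, rank=rank,
                  r2_train=float(r2_train), r2_cv=float(r2_cv))


def _trial_frames_and_folds(session: Session, cv_folds: int) -> tuple[np.ndarray, np.ndarray]:
    """All trial-window frames plus a per-frame fold id assigned by trial."""
    frames, fold = [], []
    trials = session.trials
    n_trials = len(trials)
    trial_fold = np.repeat(np.arange(cv_folds), np.diff(
        np.linspace(0, n_trials, cv_folds + 1).astype(int)
    ))
    fr = session.frame_rate
    for ti, (_, trial) in enumerate(trials.iterrows()):
        s0 = int(trial.stimulus_onset_frame)
        stop = min(int(trial.go_cue_frame) + int(1.0 * fr), session.n_frames)
        idx = np.arange(s0, stop)
        frames.append(idx)
        fold.append(np.full(idx.size, trial_fold[ti]))
    return np.concatenate(frames), np.concatenate(fold)


def mean_iti_correlation(session: Session) -> np.ndarray:
    """Per-neuron mean pairwise Pearson correlation over spontaneous ITI
    frames (averaged across all pairs involving the neuron)."""
    from .motifs import _epoch_frame_lists

    frames, _ = _epoch_frame_lists(session, "spontaneous_iti")
    data = session.activity[:, np.asarray(frames)]
    sd = data.std(axis=1)
    n = session.n_neurons
    z = np.zeros_like(data)
    ok = sd > 0
    z[ok] = (data[ok] - data[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    r = z @ z.T / data.shape[1]
    np.fill_diagonal(r, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(r, axis=1)


def correlation_matched_rrr(
    session: Session,
    source_region: str,
    target_region: str,
    rank: int = 5,
    corr_threshold: float = 0.0274,
    n_sample: int = 20,
    iters: int = 20,
    cv_folds: int = 10,
    seed: int = 0,
) -> "float | None":
    """Correlation-matched, subsampled RRR performance for one region pair.

    Neurons whose mean pairwise ITI correlation falls below
    ``corr_threshold`` are removed (matching correlation distributions
    across learning stages); ``n_sample`` source and target neurons are
    then repeatedly sampled and the cross-validated performance averaged
    over iterations.  Returns None (with a log report) when a region has
    fewer than ``n_sample`` qualifying neurons.
    """
    rng = np.random.default_rng(seed)
    mean_corr = mean_iti_correlation(session)
    qualified = mean_corr >= corr_threshold
    src_idx = np.flatnonzero((session.regions == source_region) & qualified)
    tgt_idx = np.flatnonzero((session.regions == target_region) & qualified)
    if src_idx.size < n_sample or tgt_idx.size < n_sample:
        logger.warning(
            "region pair %s->%s skipped: %d/%d qualifying neurons (< %d)",
            source_region, target_region, src_idx.size, tgt_idx.size, n_sample,
        )
        return None
    frames, fold = _trial_frames_and_folds(session, cv_folds)
    perf = []
    for _ in range(iters):
        s = rng.choice(src_idx, n_sample, replace=False)
        t = rng.choice(tgt_idx, n_sample, replace=False)
        X = session.activity[np.ix_(s, frames)].T
        Y = session.activity[np.ix_(t, frames)].T
        perf.append(fit_rrr(X, Y, rank, fold_of=fold).r2_cv)
    return float(np.mean(perf))
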