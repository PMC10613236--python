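"""Cross-validated GLM fitting, pseudo explained variance, predictor
significance and partial-model reconstruction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..stats import bh_fdr
from .design import DesignMatrix, parse_coupling_tag
from .solver import ETA_CLIP, enet_poisson_path

logger = logging.getLogger(__name__)


@dataclass
class GLMFit:
    beta: np.ndarray  # coefficients at the selected lambda
    beta0: float
    alpha: float
    lambdas: np.ndarray
    selected_lambda_index: int
    beta_path: np.ndarray  # (p, n_lambda) on the training set
    beta0_path: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    cv_fold_of_frame: np.ndarray  # fold id per training frame
    pseudo_ev_test: float
    column_names: list
    column_groups: list
    target_id: int

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_lambda_index])


@dataclass
class PredictorSignificance:
    """Per-predictor-group removal effect and shuffle-null p-values."""

    table: pd.DataFrame  # columns: group, delta_ev, p, significant
    n_shuffles: int
    q: float


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """``2 * sum[y*log(y/mu) - (y - mu)]`` with ``y*log(y/mu) = 0`` at y=0."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu[y > 0] <= 0):
        raise ValueError("mu must be positive wherever y > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y / mu, 1.0)), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def pseudo_ev(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - D(y_hat)/D(mean(y)): deviance-based explained variance."""
    y = np.asarray(y, dtype=float)
    d_null = poisson_deviance(y, np.full_like(y, y.mean()))
    if d_null == 0:
        raise ValueError("constant y: null deviance is 0, pseudo-EV undefined")
    return 1.0 - poisson_deviance(y, y_hat) / d_null


def contiguous_split(n_frames: int, train_frac: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous 70/30 frame split (interleaved frames would leak
    autocorrelation into the test set)."""
    n_train = int(round(train_frac * n_frames))
    return np.arange(n_train), np.arange(n_train, n_frames)


def fit_poisson_glm(
    design: DesignMatrix,
    y: np.ndarray,
    alpha: float = 0.95,
    n_lambda: int = 100,
    cv_folds: int = 5,
    train_frac: float = 0.7,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-5,
    cv_tol: float = 3e-5,
    cv_patience: int = 5,
    seed: int = 0,
) -> GLMFit:
    """Poisson elastic-net fit with lambda chosen by K-fold CV deviance.

    Frames are split into contiguous train/test blocks; the training
    block is cut into contiguous CV folds.  All fold paths advance down
    a shared lambda path in lockstep and stop early once the mean CV
    deviance has not improved for ``cv_patience`` consecutive lambdas
    (the dense low-lambda tail is never visited).  Coefficients are
    refit on the full training block at the selected path position.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")
    X = design.X
    if X.shape[0] != len(y):
        raise ValueError("design and response are misaligned")
    train_idx, test_idx = contiguous_split(len(y), train_frac)
    Xtr, ytr = X[train_idx], y[train_idx]
    fold_of = np.repeat(np.arange(cv_folds), np.diff(
        np.linspace(0, len(train_idx), cv_folds + 1).astype(int)
    ))
    # shared path so CV deviances are comparable across folds
    from .solver import PathState, lambda_path

    lambdas = lambda_path(Xtr, ytr, alpha, n_lambda, lambda_min_ratio)
    fold_states = []
    for k in range(cv_folds):
        val = fold_of == k
        fold_states.append(
            (PathState(Xtr[~val], ytr[~val], alpha, tol=cv_tol), val)
        )
    full_state = PathState(Xtr, ytr, alpha, tol=tol)
    p = X.shape[1]
    B = np.zeros((p, len(lambdas)))
    b0s = np.zeros(len(lambdas))
    mean_dev = np.full(len(lambdas), np.inf)
    best = 0
    n_done = 0
    for li, lam in enumerate(lambdas):
        dev = 0.0
        for state, val in fold_states:
            bk, b0k = state.advance(lam)
            mu_val = np.exp(np.minimum(Xtr[val] @ bk + b0k, ETA_CLIP))
            dev += poisson_deviance(ytr[val], np.maximum(mu_val, 1e-12))
        mean_dev[li] = dev / cv_folds
        B[:, li], b0s[li] = full_state.advance(lam)
        n_done = li + 1
        if mean_dev[li] < mean_dev[best]:
            best = li
        elif li - best >= cv_patience:
            break
    lambdas = lambdas[:n_done]
    B = B[:, :n_done]
    b0s = b0s[:n_done]
    beta, b0 = B[:, best], float(b0s[best])
    mu_test = np.exp(np.minimum(X[test_idx] @ beta + b0, ETA_CLIP))
    ev = pseudo_ev(y[test_idx], mu_test)
    return GLMFit(
        beta=beta,
        beta0=b0,
        alpha=alpha,
        lambdas=lambdas,
        selected_lambda_index=best,
        beta_path=B,
        beta0_path=b0s,
        train_idx=train_idx,
        test_idx=test_idx,
        cv_fold_of_frame=fold_of,
        pseudo_ev_test=ev,
        column_names=list(design.column_names),
        column_groups=list(design.column_groups),
        target_id=design.target_id,
    )


def _subset_columns(fit: GLMFit, subset) -> np.ndarray:
    groups = list(dict.fromkeys(fit.column_groups))
    if isinstance(subset, str):
        if subset == "full":
            wanted = set(groups)
        elif subset == "task_only":
            wanted = {g for g in groups if not g.startswith("coupling:")}
        elif subset == "coupling_only":
            wanted = {g for g in groups if g.startswith("coupling:")}
        else:
            raise KeyError(f"unknown subset {subset!r}")
    else:
        wanted = set(subset)
        unknown = wanted - set(groups)
        if unknown:
            raise KeyError(f"unknown predictor groups: {sorted(unknown)}")
    return np.asarray([i for i, g in enumerate(fit.column_groups) if g in wanted],
                      dtype=int)


def reconstruct(fit: GLMFit, X: np.ndarray, subset="full") -> np.ndarray:
    """``exp(X_subset @ beta_subset + beta0)``; excluded predictor groups
    are marginalized out (contribute nothing)."""
    cols = _subset_columns(fit, subset)
    eta = np.full(X.shape[0], fit.beta0)
    if cols.size:
        eta = eta + X[:, cols] @ fit.beta[cols]
    return np.exp(np.minimum(eta, ETA_CLIP))


def summarize_weights(fit: GLMFit, group: str) -> float:
    """Highest coefficient within a predictor group (signed maximum)."""
    cols = _subset_columns(fit, [group])
    if cols.size == 0:
        return 0.0
    return float(np.max(fit.beta[cols]))


def _deviance_rows(y: np.ndarray, eta_rows: np.ndarray) -> np.ndarray:
    """Poisson deviance per row of an (n_rows, n_frames) eta matrix."""
    mu = np.exp(np.minimum(eta_rows, ETA_CLIP))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu), axis=-1)


def significant_predictors(
    fit: GLMFit,
    design: DesignMatrix,
    y: np.ndarray,
    n_shuffles: int = 1000,
    block_s: float = 2.0,
    q: float = 0.05,
    seed: int = 0,
    groups: "list | None" = None,
) -> PredictorSignificance:
    """Removal significance of each predictor group.

    For each group, ``delta_ev`` is pseudo-EV(full) minus pseudo-EV with
    the group's columns zeroed (coefficients fixed, no refit), evaluated
    on the held-out test frames.  The null replaces the group's fitted
    contribution by a circularly rotated copy (random 2-s-block offsets)
    and recomputes the same statistic; the one-tailed add-one p compares
    observed against null.  Groups with all-zero coefficients have
    ``delta_ev`` 0 and are never significant.  BH-FDR is applied across
    groups within the neuron.
    """
    y = np.asarray(y, dtype=float)
    nf = len(y)
    block = int(block_s * design.frame_rate)
    if block < 1 or nf // block < 2:
        raise ValueError("need at least 2 shuffle blocks")
    rng = np.random.default_rng(seed)
    test = fit.test_idx
    yt = y[test]
    eta_full = design.X @ fit.beta + fit.beta0
    d_null = _deviance_rows(yt, np.full(len(test), np.log(max(yt.mean(), 1e-12))))
    ev_full = 1.0 - _deviance_rows(yt, eta_full[test]) / d_null
    if groups is None:
        groups = list(dict.fromkeys(fit.column_groups))
    rows = []
    n_blocks = nf // block
    for g in groups:
        cols = _subset_columns(fit, [g])
        bg = fit.beta[cols]
        if not np.any(bg):
            rows.append((g, 0.0, 1.0))
            continue
        contrib = design.X[:, cols] @ bg
        eta_removed = eta_full - contrib
        ev_removed = 1.0 - _deviance_rows(yt, eta_removed[test]) / d_null
        delta_obs = ev_full - ev_removed
        shifts = rng.integers(1, n_blocks, size=n_shuffles) * block
        rolled_idx = (test[None, :] - shifts[:, None]) % nf
        eta_shuf = eta_removed[test][None, :] + contrib[rolled_idx]
        ev_shuf = 1.0 - _deviance_rows(yt, eta_shuf) / d_null
        delta_null = ev_shuf - ev_removed
        p = (1 + np.sum(delta_null >= delta_obs)) / (1 + n_shuffles)
        rows.append((g, float(delta_obs), float(p)))
    table = pd.DataFrame(rows, columns=["group", "delta_ev", "p"])
    table["significant"] = bh_fdr(table["p"].to_numpy(), q)
    return PredictorSignificance(table=table, n_shuffles=n_shuffles, q=q)


def coupling_edges(fit: GLMFit, significance: PredictorSignificance) -> pd.DataFrame:
    """Directed edge list (source -> target) from coupling-group
    significance: an edge is significant if either lag's group is."""
    rows: dict[int, dict] = {}
    for _, r in significance.table.iterrows():
        if not str(r["group"]).startswith("coupling:"):
            continue
        src, lag = parse_coupling_tag(r["group"])
        e = rows.setdefault(
            src,
            {"source": src, "target": fit.target_id, "lag1_sig": False,
             "lag2_sig": False, "delta_ev": -np.inf, "p": 1.0},
        )
        e[f"lag{lag}_sig"] = bool(r["significant"])
        e["delta_ev"] = max(e["delta_ev"], float(r["delta_ev"]))
        e["p"] = min(e["p"], float(r["p"]))
    edges = pd.DataFrame(list(rows.values()))
    if len(edges):
        edges["significant"] = edges["lag1_sig"] | edges["lag2_sig"]
    else:
        edges = pd.DataFrame(
            columns=["source", "target", "lag1_sig", "lag2_sig", "delta_ev",
                     "p", "significant"]
        )
    return edges
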