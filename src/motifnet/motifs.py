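"""Connectivity-derived motif statistics and in-silico coupling ablation.

A :class:`CouplingGraph` holds directed significant functional couplings
(source/predictor -> target/predicted neuron).  Convergence counts a
neuron's significant incoming edges from a source region against all
candidate source neurons; enrichment is the fraction of a neuron's
incoming edges whose source shares its tuning label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glm.design import build_design_matrix
from .glm.fit import GLMFit, reconstruct
from .modes import ModeAxis
from .session import Session, get_epoch

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["source", "target", "lag1_sig", "lag2_sig", "delta_ev", "p",
                "significant"]


@dataclass
class CouplingGraph:
    """Directed functional-coupling graph over one session's neurons."""

    edges: pd.DataFrame  # EDGE_COLUMNS; rows are significant couplings
    regions: pd.Series  # neuron_id -> region label
    stage: str = "expert"

    def __post_init__(self) -> None:
        missing = [c for c in ("source", "target") if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing {missing}")
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        known = set(self.regions.index)
        bad = (~self.edges["source"].isin(known)) | (~self.edges["target"].isin(known))
        if bad.any():
            raise ValueError("edge endpoints missing from the neuron set")

    @classmethod
    def from_edge_lists(cls, per_neuron_edges: "list[pd.DataFrame]",
                        regions: pd.Series, stage: str = "expert",
                        significant_only: bool = True) -> "CouplingGraph":
        edges = pd.concat(per_neuron_edges, ignore_index=True) if per_neuron_edges \
            else pd.DataFrame(columns=EDGE_COLUMNS)
        if significant_only and "significant" in edges.columns and len(edges):
            edges = edges[edges["significant"]].reset_index(drop=True)
        return cls(edges=edges, regions=regions, stage=stage)

    @classmethod
    def from_ground_truth(cls, coupling: pd.DataFrame, regions: pd.Series,
                          stage: str = "expert") -> "CouplingGraph":
        uniq = coupling.drop_duplicates(subset=["source", "target"])
        edges = pd.DataFrame(
            {
                "source": uniq["source"].to_numpy(),
                "target": uniq["target"].to_numpy(),
                "lag1_sig": True,
                "lag2_sig": False,
                "delta_ev": np.nan,
                "p": 0.0,
                "significant": True,
            }
        )
        return cls(edges=edges, regions=regions, stage=stage)

    def edge_set(self) -> set:
        return set(zip(self.edges["source"], self.edges["target"]))

    def incoming(self, target: int) -> pd.DataFrame:
        return self.edges[self.edges["target"] == target]

    def neurons_in(self, region: str) -> np.ndarray:
        return self.regions.index[self.regions == region].to_numpy()

    def to_tsv(self, path: str) -> None:
        out = self.edges.copy()
        out["source_region"] = out["source"].map(self.regions)
        out["target_region"] = out["target"].map(self.regions)
        out.to_csv(path, sep="\t", index=False)


def convergence_index(graph: CouplingGraph, target: int, source_region: str) -> float:
    """Significant incoming edges from a source region over candidate
    source neurons (the target itself excluded when intra-regional)."""
    candidates = [n for n in graph.neurons_in(source_region) if n != target]
    if not candidates:
        logger.warning("no candidate sources in %s for neuron %s",
                       source_region, target)
        return float("nan")
    inc = graph.incoming(target)
    n_coupled = inc["source"].isin(candidates).sum()
    return float(n_coupled / len(candidates))


def mean_convergence(graph: CouplingGraph, source_region: str,
                     target_region: str) -> float:
    """Convergence index averaged over the target region's neurons."""
    vals = [
        convergence_index(graph, t, source_region)
        for t in graph.neurons_in(target_region)
    ]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _same_tuned(labels: pd.DataFrame, a: int, b: int, variable: str,
                side: "str | None") -> bool:
    col = f"{variable}_encoding"
    la = labels.set_index("neuron_id")[col]
    return _same_tuned_fast(la, a, b, side)


def _same_tuned_fast(label_of: pd.Series, a: int, b: int, side) -> bool:
    va, vb = label_of.get(a, "none"), label_of.get(b, "none")
    if va == "none" or vb == "none" or va != vb:
        return False
    return side is None or va == side


def enrichment_index(
    graph: CouplingGraph,
    labels: pd.DataFrame,
    target: int,
    variable: str = "choice",
    side: "str | None" = None,
    source_pool: "np.ndarray | None" = None,
) -> float:
    """Fraction of a neuron's significant incoming couplings whose source
    shares its tuning label (optionally restricted to one preferred
    side and/or a source-neuron pool)."""
    col = f"{variable}_encoding"
    label_of = labels.set_index("neuron_id")[col]
    inc = graph.incoming(target)
    if source_pool is not None:
        inc = inc[inc["source"].isin(source_pool)]
    if len(inc) == 0:
        return float("nan")
    tgt_label = label_of.get(target, "none")
    if tgt_label == "none" or (side is not None and tgt_label != side):
        return float("nan")
    same = sum(label_of.get(s, "none") == tgt_label for s in inc["source"])
    return float(same / len(inc))


def mean_enrichment(graph: CouplingGraph, labels: pd.DataFrame,
                    variable: str = "choice", side: "str | None" = None) -> float:
    """Enrichment index averaged over neurons with defined values."""
    vals = [
        enrichment_index(graph, labels, t, variable, side)
        for t in graph.regions.index
    ]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def region_pair_enrichment(
    graph: CouplingGraph,
    labels: pd.DataFrame,
    source_region: str,
    target_region: str,
    variable: str = "choice",
    side: "str | None" = None,
) -> float:
    """Per-target enrichment restricted to couplings from one source
    region, averaged over the target region's neurons."""
    pool = np.asarray([n for n in graph.neurons_in(source_region)])
    vals = []
    for t in graph.neurons_in(target_region):
        v = enrichment_index(graph, labels, t, variable, side,
                             source_pool=pool[pool != t])
        if np.isfinite(v):
            vals.append(v)
    if not vals:
        logger.warning("no qualifying %s->%s neurons for enrichment",
                       source_region, target_region)
        return float("nan")
    return float(np.mean(vals))


def null_enrichment(
    graph_first: CouplingGraph,
    graph_last: CouplingGraph,
    labels_first: pd.DataFrame,
    labels_last: pd.DataFrame,
    variable: str = "choice",
    side: "str | None" = None,
    iters: int = 1000,
    seed: int = 0,
) -> dict:
    """Random-coupling null for the stage change in mean enrichment.

    Null graphs redraw each neuron's couplings uniformly from its
    candidate sources, preserving edge counts; the observed
    (last - first) change is compared against the null-change
    distribution (one-tailed, add-one p).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    obs = (
        mean_enrichment(graph_last, labels_last, variable, side)
        - mean_enrichment(graph_first, labels_first, variable, side)
    )
    null_changes = np.empty(iters)
    for i in range(iters):
        g1 = _rewired(graph_first, rng)
        g2 = _rewired(graph_last, rng)
        null_changes[i] = (
            mean_enrichment(g2, labels_last, variable, side)
            - mean_enrichment(g1, labels_first, variable, side)
        )
    finite = null_changes[np.isfinite(null_changes)]
    p = (1 + np.sum(finite >= obs)) / (1 + finite.size)
    return {"observed_change": obs, "null_changes": null_changes, "p": float(p)}


def _rewired(graph: CouplingGraph, rng: np.random.Generator) -> CouplingGraph:
    all_ids = graph.regions.index.to_numpy()
    rows = []
    for t, inc in graph.edges.groupby("target"):
        candidates = all_ids[all_ids != t]
        src = rng.choice(candidates, size=len(inc), replace=False)
        for s in src:
            rows.append({"source": s, "target": t, "lag1_sig": True,
                         "lag2_sig": False, "delta_ev": np.nan, "p": np.nan,
                         "significant": True})
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS) if rows else \
        pd.DataFrame(columns=EDGE_COLUMNS)
    return CouplingGraph(edges=edges, regions=graph.regions, stage=graph.stage)


# -- retained / eliminated ----------------------------------------------

def retained_eliminated(graph_1: CouplingGraph, graph_2: CouplingGraph) -> dict:
    """Partition stage-1 edges into retained (also present at stage 2)
    and eliminated (absent at stage 2)."""
    ids1 = set(graph_1.regions.index)
    ids2 = set(graph_2.regions.index)
    if not (ids1 & ids2):
        raise ValueError("graphs share no neurons (cells not matched)")
    e1 = graph_1.edge_set()
    e2 = graph_2.edge_set()
    retained = e1 & e2
    eliminated = e1 - e2
    n1 = len(e1)
    return {
        "retained": retained,
        "eliminated": eliminated,
        "retained_fraction": len(retained) / n1 if n1 else float("nan"),
        "eliminated_fraction": len(eliminated) / n1 if n1 else float("nan"),
    }


def reconstruct_retained_eliminated(
    fits: "dict[int, tuple[GLMFit, np.ndarray]]",
    partition: dict,
    seed: int = 0,
) -> tuple[dict, dict, list]:
    """Coupling-only reconstructions from equal-sized subsamples of each
    neuron's retained and eliminated coupling terms.

    ``fits`` maps target neuron id -> (stage-1 fit, design X).  Neurons
    lacking either retained or eliminated couplings are excluded (their
    ids are returned).  Returns (activity_retained, activity_eliminated,
    skipped_ids); the activity dicts map neuron id -> reconstructed
    series.
    """
    rng = np.random.default_rng(seed)
    retained_by_target: dict[int, list] = {}
    eliminated_by_target: dict[int, list] = {}
    for s, t in partition["retained"]:
        retained_by_target.setdefault(t, []).append(s)
    for s, t in partition["eliminated"]:
        eliminated_by_target.setdefault(t, []).append(s)
    act_ret, act_elim, skipped = {}, {}, []
    for t, (fit, X) in fits.items():
        ret = retained_by_target.get(t, [])
        elim = eliminated_by_target.get(t, [])
        if not ret or not elim:
            skipped.append(t)
            continue
        k = min(len(ret), len(elim))
        ret_s = list(rng.choice(ret, size=k, replace=False))
        elim_s = list(rng.choice(elim, size=k, replace=False))
        groups = set(fit.column_groups)
        ret_groups = [g for g in groups if _is_coupling_from(g, ret_s)]
        elim_groups = [g for g in groups if _is_coupling_from(g, elim_s)]
        act_ret[t] = reconstruct(fit, X, ret_groups)
        act_elim[t] = reconstruct(fit, X, elim_groups)
    if skipped:
        logger.info("retained/eliminated reconstruction skipped %d neurons",
                    len(skipped))
    return act_ret, act_elim, skipped


def _is_coupling_from(group: str, sources: list) -> bool:
    if not group.startswith("coupling:"):
        return False
    src = int(group.split(":")[1])
    return src in sources


# -- selective ablation --------------------------------------------------

def ablate_coupling(
    session: Session,
    fits: "dict[int, tuple[GLMFit, np.ndarray]]",
    graph: CouplingGraph,
    axis: ModeAxis,
    target_region: str,
    source_region: str,
    mode: str = "targeted",
    iters: int = 100,
    seed: int = 0,
    replace_with: str = "zero",
    n_ablate: "int | None" = None,
) -> dict:
    """Choice-axis readout of coupling-only reconstructions after
    in-silico ablation of couplings from one source region.

    Per iteration and target neuron, ``k`` significant couplings from
    ``source_region`` are ablated (``mode='targeted'``) or the same
    count drawn from the neuron's couplings from other regions
    (``mode='control'``).  Ablation either zeroes the terms
    (``replace_with='zero'``) or substitutes uniformly scrambled ITI
    activity of the source (``replace_with='scrambled_iti'``).  The
    population of reconstructions is projected onto the (observed-
    activity) choice axis per trial, baseline-subtracted at stimulus
    offset and normalized by its SD, then averaged across iterations.

    Returns per-side mean projected trajectories over the trial window
    plus the pre-action right-left separation (``selectivity``).
    """
    if mode not in ("targeted", "control"):
        raise ValueError("mode must be 'targeted' or 'control'")
    if replace_with not in ("zero", "scrambled_iti"):
        raise ValueError("replace_with must be 'zero' or 'scrambled_iti'")
    rng = np.random.default_rng(seed)
    targets = [t for t in graph.neurons_in(target_region)
               if t in fits and t in set(axis.neuron_ids)]
    if not targets:
        raise ValueError(f"no fitted neurons in target region {target_region}")
    axis_pos = {nid: i for i, nid in enumerate(axis.neuron_ids)}
    weights = axis.weights[[axis_pos[t] for t in targets]]
    from .modes import default_trial_window

    window = default_trial_window(session)
    trials = session.trials
    go_offset = int(
        (trials["go_cue_frame"] - trials["stimulus_onset_frame"]).iloc[0]
    )
    stim_off_frame = int(1.0 * session.frame_rate)  # rel. stimulus onset
    fr = session.frame_rate
    pre_action = range(go_offset - int(1.0 * fr), go_offset)

    iti_frames = np.asarray(_epoch_frame_lists(session, "spontaneous_iti")[0])
    pre_frames = np.asarray(_epoch_frame_lists(session, "pre_action")[0])
    # SD reference from the unablated coupling-only reconstruction so the
    # normalized readout is comparable between targeted and control modes
    recon_full = np.zeros((len(targets), session.n_frames))
    for ti, t in enumerate(targets):
        fit, X = fits[t]
        recon_full[ti] = reconstruct(
            fit, X,
            [g for g in dict.fromkeys(fit.column_groups)
             if g.startswith("coupling:")],
        )
    proj_full = _project_window(recon_full, weights, trials, window,
                                session.n_frames)
    base_col = int(1.0 * session.frame_rate) - window.start
    sf = proj_full["series"]
    sd_ref = float((sf - sf[:, base_col][:, None]).std())
    left_mean = np.zeros(len(window))
    right_mean = np.zeros(len(window))
    sel_sum = 0.0
    for it in range(iters):
        recon = np.zeros((len(targets), session.n_frames))
        for ti, t in enumerate(targets):
            fit, X = fits[t]
            inc = graph.incoming(t)
            from_src = inc.loc[inc["source"].isin(graph.neurons_in(source_region)),
                               "source"].tolist()
            k = len(from_src) if n_ablate is None else min(n_ablate, len(from_src))
            if mode == "targeted":
                ablated = list(rng.choice(from_src, size=k, replace=False)) if k else []
            else:
                others = inc.loc[~inc["source"].isin(graph.neurons_in(source_region)),
                                 "source"].tolist()
                if k > len(others):
                    raise ValueError(
                        f"neuron {t}: control ablation needs {k} edges but only "
                        f"{len(others)} couplings from other regions exist"
                    )
                ablated = list(rng.choice(others, size=k, replace=False)) if k else []
            ablated_set = set(int(a) for a in ablated)
            keep_groups = [
                g for g in dict.fromkeys(fit.column_groups)
                if g.startswith("coupling:")
                and int(g.split(":")[1]) not in ablated_set
            ]
            recon[ti] = reconstruct(fit, X, keep_groups)
            if replace_with == "scrambled_iti" and ablated_set:
                # ablated terms stay in the model but their pre-action
                # activity is replaced by scrambled ITI activity
                abl_cols = np.asarray(
                    [i for i, g in enumerate(fit.column_groups)
                     if g.startswith("coupling:")
                     and int(g.split(":")[1]) in ablated_set]
                )
                Xa = X[:, abl_cols].copy()
                sub = rng.choice(iti_frames, size=pre_frames.size, replace=True)
                Xa[pre_frames] = X[np.ix_(sub, abl_cols)]
                recon[ti] *= np.exp(Xa @ fit.beta[abl_cols])
        proj = _project_window(recon, weights, trials, window, session.n_frames)
        sides = trials["choice_side"].to_numpy()[proj["kept"]]
        series = proj["series"]
        # baseline at stimulus offset, then SD normalization
        series = series - series[:, stim_off_frame - window.start][:, None]
        sd = sd_ref if sd_ref > 0 else series.std()
        if sd > 0:
            series = series / sd
        lm = series[sides == "L"].mean(axis=0)
        rm = series[sides == "R"].mean(axis=0)
        left_mean += lm
        right_mean += rm
        pa = slice(pre_action.start - window.start, pre_action.stop - window.start)
        sel_sum += rm[pa].mean() - lm[pa].mean()
    return {
        "left": left_mean / iters,
        "right": right_mean / iters,
        "selectivity": sel_sum / iters,
        "window": window,
    }


def _project_window(activity: np.ndarray, weights: np.ndarray,
                    trials: pd.DataFrame, window: range, n_frames: int) -> dict:
    series, kept = [], []
    for ti, (_, trial) in enumerate(trials.iterrows()):
        s0 = int(trial.stimulus_onset_frame)
        start, stop = s0 + window.start, s0 + window.stop
        if start < 0 or stop > n_frames:
            continue
        series.append(activity[:, start:stop].T @ weights)
        kept.append(ti)
    return {"series": np.asarray(series), "kept": np.asarray(kept, dtype=int)}


def scramble_iti_activity(session: Session, region: str, seed: int = 0) -> np.ndarray:
    """Activity matrix with each of one region's neurons' pre-action
    frames replaced by uniformly permuted spontaneous-ITI frames."""
    rng = np.random.default_rng(seed)
    act = session.activity.copy()
    iti, _ = _epoch_frame_lists(session, "spontaneous_iti")
    pre, _ = _epoch_frame_lists(session, "pre_action")
    rows = session.region_indices(region)
    iti = np.asarray(iti)
    pre = np.asarray(pre)
    for r in rows:
        act[r, pre] = act[r, rng.choice(iti, size=pre.size, replace=True)]
    return act


def _epoch_frame_lists(session: Session, epoch_name: str) -> tuple[list, list]:
    from .session import EpochOutOfRangeError, epoch_frames

    frames, kept = [], []
    for ti, trial in session.trials.iterrows():
        try:
            rng = epoch_frames(epoch_name, trial, session.frame_rate,
                               session.n_frames)
        except EpochOutOfRangeError:
            continue
        frames.extend(rng)
        kept.append(ti)
    return frames, kept


# -- correlation-based connectivity --------------------------------------

def corr_connectivity(
    session: Session,
    epoch: str = "spontaneous_iti",
    p_thresh: float = 1e-4,
) -> CouplingGraph:
    """Undirected functional connectivity from pairwise Pearson
    correlations of concatenated epoch frames (edge where the
    correlation p-value is below ``p_thresh``; each undirected pair is
    stored as two directed edges)."""
    frames, _ = _epoch_frame_lists(session, epoch)
    if len(frames) < 10:
        raise ValueError("need at least 10 epoch samples")
    data = session.activity[:, np.asarray(frames)]
    n = session.n_neurons
    sd = data.std(axis=1)
    ok = sd > 0
    if not ok.all():
        logger.warning("%d constant neurons excluded from correlation graph",
                       int((~ok).sum()))
    z = np.zeros_like(data)
    z[ok] = (data[ok] - data[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    m = data.shape[1]
    r = z @ z.T / m
    np.clip(r, -0.9999999, 0.9999999, out=r)
    # two-sided p from the t distribution
    t = r * np.sqrt((m - 2) / (1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df=m - 2)
    rows = []
    ids = session.neuron_ids
    for i in range(n):
        for j in range(i + 1, n):
            if ok[i] and ok[j] and p[i, j] < p_thresh:
                for s, tgt in ((ids[i], ids[j]), (ids[j], ids[i])):
                    rows.append({"source": s, "target": tgt, "lag1_sig": False,
                                 "lag2_sig": False, "delta_ev": np.nan,
                                 "p": p[i, j], "significant": True})
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS) if rows else \
        pd.DataFrame(columns=EDGE_COLUMNS)
    regions = pd.Series(session.regions, index=session.neuron_ids)
    return CouplingGraph(edges=edges, regions=regions, stage=session.stage)
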