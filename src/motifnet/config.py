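"""Pipeline configuration, seed derivation and end-to-end runs."""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, modes, motifs, rrr, stats
from .glm import build_design_matrix, coupling_edges, fit_poisson_glm, significant_predictors
from .session import Session
from .simulate import SimConfig, generate_session, generate_movement, movement_speed_per_frame

logger = logging.getLogger(__name__)


@dataclass
class GLMParams:
    alpha: float = 0.95
    n_lambda: int = 100
    cv_folds: int = 5
    train_frac: float = 0.7
    lambda_min_ratio: float = 1e-3
    n_shuffles: int = 1000
    block_s: float = 2.0
    q: float = 0.05


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; round-trips through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    glm: GLMParams = field(default_factory=GLMParams)
    seed: int = 0
    n_glm_targets: "int | None" = None  # cap on fitted neurons (None = all)
    min_mode_neurons: int = 20
    rrr_rank: int = 5
    rrr_iters: int = 5
    run_rrr: bool = True
    out_dir: str = "motifnet_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        glm = GLMParams(**data.pop("glm", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"sim", "glm"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, glm=glm, **data)

    def to_yaml(self, path: str) -> None:
        data = dataclasses.asdict(self)
        data["sim"]["regions"] = list(data["sim"]["regions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed from the global seed and stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> behavior -> modes -> decode -> fit-glm -> motifs -> rrr.

    Returns a JSON-serializable report of indices, p-values and
    ground-truth comparisons.
    """
    report: dict = {"seeds": {}, "stages": {}}

    def seed_for(stage: str) -> int:
        s = derive_seed(config.seed, stage)
        report["seeds"][stage] = s
        return s

    stage = "simulate"
    try:
        session, truth = generate_session(config.sim, seed=seed_for(stage))
        move_table, move_truth = generate_movement(
            config.sim, session.trials, seed=seed_for("movement"),
            n_frames=session.n_frames,
        )
        report["stages"][stage] = {
            "n_neurons": session.n_neurons,
            "n_frames": session.n_frames,
            "n_trials": len(session.trials),
            "planted_edges": int(len(truth.coupling)),
        }

        stage = "behavior"
        trace = behavior.MovementTrace.from_table(move_table)
        clean = behavior.clean_movement_trace(trace)
        go_off = int((session.trials["go_cue_frame"]
                      - session.trials["stimulus_onset_frame"]).iloc[0])
        epochs = []
        for _, tr in session.trials.iterrows():
            s0 = int(tr.stimulus_onset_frame)
            epochs.append(range(s0 + go_off - int(session.frame_rate),
                                s0 + go_off))
        trajs = behavior.trial_trajectories(clean, session.trials, epochs,
                                            session.frame_rate)
        right = [t for t, side in zip(trajs, session.trials["choice_side"])
                 if side == "R"]
        _, stereotypy_median, _ = behavior.movement_stereotypy(right)
        report["stages"][stage] = {"stereotypy_median_right": stereotypy_median}

        stage = "modes"
        region_a, region_b = config.sim.regions[0], config.sim.regions[1]
        axes = {}
        sel = {}
        for region in (region_a, region_b):
            choice_ax = modes.compute_mode_axis(
                session, region, "choice", min_neurons=config.min_mode_neurons)
            stim_ax = modes.compute_mode_axis(
                session, region, "stimulus", min_neurons=config.min_mode_neurons)
            choice_ax, stim_ax = modes.orthogonalize_axes(choice_ax, stim_ax)
            proj = modes.project_trials(session, region, choice_ax)
            sel[region] = modes.choice_selectivity(proj, go_off)
            axes[region] = (choice_ax, proj)
        coord = modes.interregion_coordination(
            axes[region_a][1], axes[region_b][1], go_off, "pre_action",
            scope="both_types",
        )
        report["stages"][stage] = {
            "choice_selectivity": sel,
            "interregion_coordination": coord,
        }

        stage = "decode"
        labels = stats.tuning_labels(session)
        means, kept = session.trial_epoch_means("pre_action")
        lick = session.trials.loc[kept, "choice_side"]
        usable = lick.isin(["L", "R"]).to_numpy()
        proj = axes[region_a][1]
        pa = proj.epoch_mean("pre_action", go_off)
        sides = proj.choice_side
        pop = stats.shuffle_null_decoding(
            pa[np.isin(sides, ["L", "R"])],
            (sides[np.isin(sides, ["L", "R"])] == "R"),
            n_shuffles=config.glm.n_shuffles, seed=seed_for("decode"),
        )
        report["stages"][stage] = {
            "population_choice_accuracy": pop.accuracy,
            "population_choice_p": pop.p_value,
            "n_choice_encoding": int((labels["choice_encoding"] != "none").sum()),
        }

        stage = "fit-glm"
        speed = movement_speed_per_frame(
            np.column_stack([clean.x, clean.y]), session.n_frames,
            int(round(60.0 / session.frame_rate)),
        )
        rng = np.random.default_rng(seed_for(stage))
        target_ids = list(session.neuron_ids)
        if config.n_glm_targets is not None and config.n_glm_targets < len(target_ids):
            target_ids = sorted(rng.choice(target_ids, config.n_glm_targets,
                                           replace=False))
        per_neuron_edges = []
        evs = []
        for tid in target_ids:
            design = build_design_matrix(session, tid, movement_speed=speed)
            row = int(np.flatnonzero(session.neuron_ids == tid)[0])
            fit = fit_poisson_glm(
                design, session.activity[row], alpha=config.glm.alpha,
                n_lambda=config.glm.n_lambda, cv_folds=config.glm.cv_folds,
                train_frac=config.glm.train_frac,
                lambda_min_ratio=config.glm.lambda_min_ratio,
            )
            sig = significant_predictors(
                fit, design, session.activity[row],
                n_shuffles=config.glm.n_shuffles, block_s=config.glm.block_s,
                q=config.glm.q, seed=derive_seed(config.seed, f"sig{tid}"),
            )
            per_neuron_edges.append(coupling_edges(fit, sig))
            evs.append(fit.pseudo_ev_test)
        report["stages"][stage] = {
            "n_targets": len(target_ids),
            "mean_pseudo_ev": float(np.mean(evs)),
        }

        stage = "motifs"
        regions_s = pd.Series(session.regions, index=session.neuron_ids)
        graph = motifs.CouplingGraph.from_edge_lists(per_neuron_edges, regions_s)
        est_edges = graph.edge_set()
        true_edges = truth.edge_set()
        candidates = {
            (s, t) for t in target_ids for s in session.neuron_ids if s != t
        }
        true_in_scope = true_edges & candidates
        tp = len(est_edges & true_in_scope)
        fp = len(est_edges - true_edges)
        fn = len(true_in_scope - est_edges)
        tn = len(candidates) - tp - fp - fn
        report["stages"][stage] = {
            "n_edges": len(est_edges),
            "coupling_sensitivity": tp / (tp + fn) if tp + fn else None,
            "coupling_specificity": tn / (tn + fp) if tn + fp else None,
            "mean_convergence": motifs.mean_convergence(graph, region_a, region_b),
            "mean_choice_enrichment": motifs.mean_enrichment(graph, labels),
        }

        if config.run_rrr:
            stage = "rrr"
            perf = rrr.correlation_matched_rrr(
                session, region_a, region_b, rank=config.rrr_rank,
                iters=config.rrr_iters, seed=seed_for(stage),
            )
            report["stages"][stage] = {"performance": perf}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def write_report(report: dict, path: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
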