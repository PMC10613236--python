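"""ROC decoding, encoding classification, shuffle/bootstrap nulls and FDR.

All resampling tests use add-one (pseudo-count) p-values,
``p = (1 + #{null >= obs}) / (1 + n_resamples)``, and are reproducible
under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import Session, get_epoch

logger = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    auc: float
    accuracy: float
    p_value: float
    n_shuffles: int


def auc(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """ROC area for separating group B from group A.

    Equals the Mann-Whitney U statistic over ``n_a * n_b`` with midrank
    tie handling, i.e. ``P(b > a) + 0.5 P(b == a)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic").statistic
    return float(u / (a.size * b.size))


def decoding_accuracy(auc_value: float) -> float:
    """Absolute deviation of AUC from chance, scaled to [0, 1]."""
    return 2.0 * abs(auc_value - 0.5)


def _auc_from_labels(values: np.ndarray, labels: np.ndarray) -> float:
    return auc(values[~labels], values[labels])


def shuffle_null_decoding(
    values: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> DecodingResult:
    """One-tailed permutation test of decoding accuracy against a
    label-shuffle null."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 observations per class")
    rng = np.random.default_rng(seed)
    observed_auc = _auc_from_labels(values, labels)
    observed = decoding_accuracy(observed_auc)
    null = np.empty(n_shuffles)
    lab = labels.copy()
    for i in range(n_shuffles):
        rng.shuffle(lab)
        null[i] = decoding_accuracy(_auc_from_labels(values, lab))
    p = (1 + np.sum(null >= observed)) / (1 + n_shuffles)
    return DecodingResult(auc=observed_auc, accuracy=observed, p_value=float(p),
                          n_shuffles=n_shuffles)


def learning_trend_null(
    values_by_stage: "dict[str, tuple[np.ndarray, np.ndarray]]",
    n_shuffles: int = 1000,
    seed: int = 0,
    first: str = "naive",
    last: str = "expert",
) -> float:
    """One-tailed p for an increase in decoding accuracy from *first* to
    *last* stage: the observed accuracy difference is compared with the
    distribution of differences between stagewise label-shuffle nulls.

    ``values_by_stage`` maps stage -> (values, boolean labels).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for stage in (first, last):
        if stage not in values_by_stage:
            raise ValueError(f"missing stage {stage!r}")
    rng = np.random.default_rng(seed)
    obs, nulls = {}, {}
    for stage in (first, last):
        values, labels = values_by_stage[stage]
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        obs[stage] = decoding_accuracy(_auc_from_labels(values, labels))
        lab = labels.copy()
        null = np.empty(n_shuffles)
        for i in range(n_shuffles):
            rng.shuffle(lab)
            null[i] = decoding_accuracy(_auc_from_labels(values, lab))
        nulls[stage] = null
    observed_diff = obs[last] - obs[first]
    null_diff = nulls[last] - nulls[first]
    return float((1 + np.sum(null_diff >= observed_diff)) / (1 + n_shuffles))


def bootstrap_increase(
    values_by_stage: "dict[str, np.ndarray]",
    n_boot: int = 1000,
    statistic=np.mean,
    seed: int = 0,
    first: str = "naive",
    last: str = "expert",
    max_redraws: int = 100,
) -> float:
    """One-tailed bootstrap p for an increase of *statistic* from *first*
    to *last* stage; units (sessions or neurons) are resampled with
    replacement within each stage."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    a = np.asarray(values_by_stage[first], dtype=float)
    b = np.asarray(values_by_stage[last], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 units per stage")
    n_nonincrease = 0
    redraws = 0
    for _ in range(n_boot):
        for attempt in range(max_redraws):
            sa = statistic(rng.choice(a, a.size, replace=True))
            sb = statistic(rng.choice(b, b.size, replace=True))
            if np.isfinite(sa) and np.isfinite(sb):
                break
            redraws += 1
        n_nonincrease += sb - sa <= 0
    if redraws:
        logger.info("redrew %d bootstrap replicates with undefined statistic", redraws)
    return float((1 + n_nonincrease) / (1 + n_boot))


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level *q*."""
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        reject[order[: k + 1]] = True
    return reject


def classify_encoding(
    session: Session,
    region: str | None = None,
    variable: str = "choice",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tuning labels per neuron.

    Stimulus encoding compares stimulus-epoch activity on correct left vs
    correct right trials; choice encoding compares pre-action activity
    grouped by lick side (error trials included).  Label is the preferred
    side when p < alpha, else "none".
    """
    if variable not in ("stimulus", "choice"):
        raise ValueError("variable must be 'stimulus' or 'choice'")
    sub = session if region is None else session.subset_neurons(
        session.region_indices(region)
    )
    epoch = get_epoch("stimulus" if variable == "stimulus" else "pre_action")
    means, kept = sub.trial_epoch_means(epoch)
    trials = sub.trials.loc[kept]
    if variable == "stimulus":
        usable = trials["correct"].to_numpy()
        sides = trials["stimulus_side"].to_numpy()
    else:
        usable = trials["choice_side"].isin(["L", "R"]).to_numpy()
        sides = trials["choice_side"].to_numpy()
    left = usable & (sides == "L")
    right = usable & (sides == "R")
    labels, pvals = [], []
    for i in range(sub.n_neurons):
        vl, vr = means[left, i], means[right, i]
        if vl.size < 2 or vr.size < 2:
            logger.warning("neuron %s: <2 trials per group; label 'none'",
                           sub.neuron_ids[i])
            labels.append("none")
            pvals.append(np.nan)
            continue
        p = sps.ranksums(vr, vl).pvalue
        pvals.append(p)
        if p < alpha:
            labels.append("R" if vr.mean() > vl.mean() else "L")
        else:
            labels.append("none")
    return pd.DataFrame(
        {"neuron_id": sub.neuron_ids, f"{variable}_encoding": labels, "p": pvals}
    )


def tuning_labels(session: Session, region: str | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Stimulus and choice labels in one table (columns
    ``stimulus_encoding``, ``choice_encoding``)."""
    stim = classify_encoding(session, region, "stimulus", alpha)
    choice = classify_encoding(session, region, "choice", alpha)
    return pd.DataFrame(
        {
            "neuron_id": stim["neuron_id"],
            "stimulus_encoding": stim["stimulus_encoding"],
            "choice_encoding": choice["choice_encoding"],
        }
    )
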