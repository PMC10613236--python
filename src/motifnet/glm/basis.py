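"""Temporal basis functions for event predictors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BasisSet:
    """``matrix`` is (frames, n_bases); each basis is nonnegative with
    peak value 1.  ``anchor_s`` is the offset of the basis origin from
    the anchoring event, in seconds (negative = basis starts before the
    event)."""

    matrix: np.ndarray
    kind: str
    span_s: float
    anchor_s: float = 0.0

    @property
    def n_bases(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def raised_cosine_basis(
    n_bases: int, span_s: float, frame_rate: float, anchor_s: float = 0.0
) -> BasisSet:
    """Evenly spaced raised cosines tiling ``[0, span_s)``.

    Each basis is ``0.5 * (1 + cos(pi * (t - c_j) / d))`` on
    ``|t - c_j| <= d`` and zero outside, with peaks ``c_j`` evenly
    spaced over the span and half-width ``d`` equal to the peak spacing,
    which makes interior bases sum to a constant.  Columns are rescaled
    so the sampled peak is exactly 1.
    """
    if n_bases < 1:
        raise ValueError("n_bases must be >= 1")
    n_frames = int(span_s * frame_rate)
    if n_frames < 1:
        raise ValueError("span shorter than one frame")
    t = np.arange(n_frames, dtype=float)
    if n_bases == 1:
        centers = np.array([(n_frames - 1) / 2.0])
        width = max((n_frames - 1) / 2.0, 1.0)
    else:
        centers = np.linspace(0.0, n_frames - 1, n_bases)
        width = centers[1] - centers[0]
    mat = np.zeros((n_frames, n_bases))
    for j, c in enumerate(centers):
        arg = (t - c) / width
        on = np.abs(arg) <= 1.0
        mat[on, j] = 0.5 * (1.0 + np.cos(np.pi * arg[on]))
        peak = mat[:, j].max()
        if peak > 0:
            mat[:, j] /= peak
    return BasisSet(matrix=mat, kind="raised_cosine", span_s=span_s, anchor_s=anchor_s)


def boxcar_basis(n_frames: int, anchor_s: float = 0.0) -> BasisSet:
    """Single-frame boxcars (identity), used for lagged coupling terms."""
    return BasisSet(matrix=np.eye(n_frames), kind="boxcar", span_s=0.0,
                    anchor_s=anchor_s)


def convolve_events(event_vector: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Convolve a per-frame event indicator with each basis column
    (causal: basis extends forward in time from the event)."""
    n = len(event_vector)
    out = np.zeros((n, basis.n_bases))
    for j in range(basis.n_bases):
        out[:, j] = np.convolve(event_vector, basis.matrix[:, j])[:n]
    return out
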