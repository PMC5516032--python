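"""Memory quantification: response binarization, memory index, weight statistics.

A memory test presents the same input pattern ``n_trials`` times (20 by
default) and reduces each trial's output to a binary vector: neuron j is
1 if it fired at least once during that trial's window.  The *memory
index* is the average pairwise dot product of those vectors normalized
by the number of neurons that fired at all,

    MI = (1 / N_pair) * sum_{m<n} (S_m . S_n) / N_firing,

so perfectly repeatable responses give MI = 1 and non-overlapping ones
MI = 0.  The *maintained memory ratio* MI(T)/MI(0) quantifies how much
of a stored memory survives a perturbation (noise decay or appended
training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stdpmem.stimuli import SpikeTrains

__all__ = [
    "ResponseSet",
    "MemoryIndexResult",
    "binarize_responses",
    "memory_index",
    "maintained_ratio",
    "output_pattern",
    "pattern_correlation",
    "convergence_ratio",
]


@dataclass(frozen=True)
class ResponseSet:
    """Binary per-trial response vectors, shape ``(n_trials, n_neurons)``."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.uint8)
        if v.ndim != 2:
            raise ValueError("vectors must be 2-D (trials x neurons)")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("response entries must be 0 or 1")
        object.__setattr__(self, "vectors", v)

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class MemoryIndexResult:
    """Memory index with its normalization counts."""

    mi: float
    n_pair: int
    n_firing: int


def binarize_responses(
    output: SpikeTrains, window: float, n_trials: int
) -> ResponseSet:
    """Fold an output raster into per-trial binary response vectors.

    The raster must cover exactly ``n_trials`` consecutive windows of
    ``window`` ms; a neuron scores 1 for a trial if it spiked at least
    once inside that trial's window (multiple spikes still count as 1).
    """
    steps = int(round(window / output.dt))
    if output.n_steps != n_trials * steps:
        raise ValueError(
            f"raster has {output.n_steps} steps, expected n_trials*window = "
            f"{n_trials * steps}"
        )
    folded = output.raster.reshape(output.n_neurons, n_trials, steps)
    return ResponseSet(vectors=folded.any(axis=2).T.astype(np.uint8))


def memory_index(responses: ResponseSet) -> MemoryIndexResult:
    """Average pairwise overlap of response vectors, normalized by N_firing.

    ``N_firing`` counts neurons that fired in at least one of the trials.
    An entirely silent response set returns MI = 0 by convention so that
    decay curves stay defined if activity collapses.
    """
    if responses.n_trials < 2:
        raise ValueError("memory index needs at least 2 trials")
    v = responses.vectors.astype(np.float64)
    m = responses.n_trials
    n_pair = m * (m - 1) // 2
    n_firing = int((responses.vectors.any(axis=0)).sum())
    if n_firing == 0:
        return MemoryIndexResult(mi=0.0, n_pair=n_pair, n_firing=0)
    gram = v @ v.T
    total = (gram.sum() - np.trace(gram)) / 2.0
    return MemoryIndexResult(
        mi=float(total / (n_pair * n_firing)), n_pair=n_pair, n_firing=n_firing
    )


def maintained_ratio(mi_start: float, mi_end: float) -> float:
    """Maintained memory ratio ``MI(T) / MI(0)``."""
    if mi_start <= 0:
        raise ZeroDivisionError(
            "maintained ratio undefined: starting memory index is not positive"
        )
    return mi_end / mi_start


def output_pattern(responses: ResponseSet, threshold: float = 0.8) -> np.ndarray:
    """Consistently responding neurons: fired in strictly more than
    ``threshold * n_trials`` trials.  The binary vector is the model's
    proxy for an engram."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    counts = responses.vectors.sum(axis=0)
    return (counts > threshold * responses.n_trials).astype(np.uint8)


def pattern_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two binary vectors of equal length."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D with equal lengths")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def convergence_ratio(W: np.ndarray, mask: np.ndarray, eps: float = 0.1,
                      w_min: float = 0.0, w_max: float = 1.0) -> float:
    """Fraction of connected weights saturated near either bound.

    A weight counts as converged if ``w <= w_min + eps`` or
    ``w >= w_max - eps``; converged synapses are where the network
    stores pattern information.
    """
    if not 0.0 < eps < (w_max - w_min) / 2.0:
        raise ValueError("eps must lie in (0, (w_max - w_min)/2)")
    w = np.asarray(W)[np.asarray(mask, dtype=bool)]
    if w.size == 0:
        return 0.0
    return float(((w <= w_min + eps) | (w >= w_max - eps)).mean())
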