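"""Change-point detection and level labeling for noisy intensity channels.

Fluorescence channels in this assay are piecewise-constant between a small
set of levels (dark / base / PIFE-enhanced) plus Gaussian camera noise.
:func:`detect_steps` segments a channel by exact minimization of the
penalized within-segment squared error

    sum_k SSE(segment_k)  +  penalty * (#change points),

solved by optimal-partitioning dynamic programming, so the result equals
exhaustive search over all admissible partitions by construction.  The
default penalty is the BIC-style 2 * sigma^2 * log(n) per change point with
sigma estimated robustly from the median absolute deviation of first
differences.  Segments shorter than 2 frames (0.8 s) are not admissible;
that is the same coincidence tolerance the classifier uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StepSegmentation",
    "detect_steps",
    "default_penalty",
    "estimate_noise_sd",
    "label_levels",
    "MIN_SEGMENT",
]

#: Minimum admissible segment length in frames.
MIN_SEGMENT = 2

#: Order used to break label ties toward the lower level.
_LEVEL_ORDER = ("dark", "base", "pife")


@dataclass(frozen=True)
class StepSegmentation:
    """Piecewise-constant idealization of one channel.

    ``change_points`` are the frame indices starting each new segment
    (strictly increasing, excluding 0 and n); segment k covers frames
    ``[boundary_k, boundary_{k+1})``.  ``segment_labels`` is None until
    :func:`label_levels` assigns discrete levels.
    """

    n_frames: int
    change_points: tuple[int, ...]
    segment_means: tuple[float, ...]
    segment_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        cps = self.change_points
        if any(cps[i] >= cps[i + 1] for i in range(len(cps) - 1)):
            raise ValueError("change points must be strictly increasing")
        if cps and not (0 < cps[0] and cps[-1] < self.n_frames):
            raise ValueError("change points outside trace bounds")
        if len(self.segment_means) != len(cps) + 1:
            raise ValueError("need exactly one mean per segment")
        if self.segment_labels is not None and len(self.segment_labels) != len(self.segment_means):
            raise ValueError("need exactly one label per segment")

    @property
    def boundaries(self) -> tuple[int, ...]:
        return (0, *self.change_points, self.n_frames)

    def merged_label_runs(self) -> list[tuple[int, int, str]]:
        """(start_frame, end_frame, label) runs with equal neighbors merged.

        Spurious change points inside a constant-level stretch vanish here,
        so downstream logic sees only genuine level transitions.
        """
        if self.segment_labels is None:
            raise ValueError("segmentation is unlabeled; run label_levels first")
        runs: list[tuple[int, int, str]] = []
        bounds = self.boundaries
        for i, lab in enumerate(self.segment_labels):
            if runs and runs[-1][2] == lab:
                runs[-1] = (runs[-1][0], bounds[i + 1], lab)
            else:
                runs.append((bounds[i], bounds[i + 1], lab))
        return runs


def estimate_noise_sd(signal: np.ndarray) -> float:
    """Robust noise SD from the MAD of first differences.

    Differences of adjacent frames within a segment are N(0, 2 sigma^2);
    the few differences straddling change points are outliers the median
    absolute deviation ignores.
    """
    diffs = np.diff(np.asarray(signal, dtype=float))
    if len(diffs) == 0:
        return 0.0
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(mad / (0.6744897501960817 * np.sqrt(2.0)))


def default_penalty(signal: np.ndarray) -> float:
    """BIC-style per-change-point penalty 2 * sigma_hat^2 * log(n)."""
    signal = np.asarray(signal, dtype=float)
    sigma = estimate_noise_sd(signal)
    return 2.0 * sigma * sigma * np.log(len(signal))


def detect_steps(
    signal: Sequence[float] | np.ndarray,
    penalty: float | None = None,
    min_segment: int = MIN_SEGMENT,
) -> StepSegmentation:
    """Exact penalized least-squares segmentation of one channel.

    Parameters
    ----------
    signal
        Intensity vector, length >= 2.
    penalty
        Cost per added change point; defaults to :func:`default_penalty`.
        Must be > 0 when given.
    min_segment
        Minimum admissible segment length in frames.

    Returns
    -------
    StepSegmentation
        The global minimizer of SSE + penalty * (#change points); ties are
        broken toward fewer change points.  A constant signal yields zero
        change points.  On noiseless piecewise-constant input with all true
        segments >= ``min_segment`` frames the change points are exact.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("signal must be 1-D with at least 2 frames")
    if penalty is None:
        penalty = default_penalty(x)
    elif not penalty > 0:
        raise ValueError("penalty must be positive")
    n = len(x)
    if n < 2 * min_segment:
        return StepSegmentation(n, (), (float(x.mean()),))

    # Floating-point floor: cumulative-sum SSEs of a truly constant segment
    # can come out ~1e-12 above zero; never let such phantom gains pay for a
    # change point.
    scale = float(np.max(np.abs(x))) or 1.0
    penalty = max(float(penalty), 1e-9 * n * scale * scale)

    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(starts: np.ndarray, t: int) -> np.ndarray:
        length = t - starts
        total = s1[t] - s1[starts]
        return (s2[t] - s2[starts]) - total * total / length

    F = np.full(n + 1, np.inf)
    K = np.zeros(n + 1, dtype=int)  # number of segments in the optimum
    parent = np.zeros(n + 1, dtype=int)
    F[0] = -penalty
    # PELT pruning: a predecessor whose unpenalized cost already exceeds the
    # optimum can never become optimal later (SSE cost is superadditive), so
    # the candidate set stays small.  A tolerance protects tied candidates
    # so the fewer-segments tie-break is preserved.
    cands = np.array([0], dtype=int)
    for t in range(min_segment, n + 1):
        new_s = t - min_segment
        if new_s >= min_segment:
            cands = np.append(cands, new_s)
        vals = F[cands] + seg_cost(cands, t) + penalty
        best = float(np.min(vals))
        tie = 1e-9 * (1.0 + abs(best))
        close = np.flatnonzero(vals <= best + tie)
        # prefer fewer segments, then the earliest predecessor
        pick = close[np.argmin(K[cands[close]])]
        s = int(cands[pick])
        F[t] = float(vals[pick])
        K[t] = K[s] + 1
        parent[t] = s
        cands = cands[vals - penalty <= F[t] + tie]

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(parent[bounds[-1]]))
    bounds.reverse()
    cps = tuple(bounds[1:-1])
    means = tuple(float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:]))
    return StepSegmentation(n, cps, means)


def label_levels(
    seg: StepSegmentation, level_table: Mapping[str, float]
) -> StepSegmentation:
    """Assign dark/base/pife labels to segments by nearest level.

    ``level_table`` maps the three label names to intensities with
    dark < base < pife.  A mean exactly midway between two levels takes the
    lower label.
    """
    try:
        levels = [float(level_table[name]) for name in _LEVEL_ORDER]
    except KeyError as exc:
        raise ValueError(f"level table missing {exc}") from exc
    if not levels[0] < levels[1] < levels[2]:
        raise ValueError("levels must satisfy dark < base < pife")
    labels = []
    for mean in seg.segment_means:
        dists = [abs(mean - lv) for lv in levels]
        best = min(range(3), key=lambda i: (dists[i], i))  # tie -> lower level
        labels.append(_LEVEL_ORDER[best])
    return replace(seg, segment_labels=tuple(labels))
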