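"""Step detector: exactness vs exhaustive search, penalties, labeling."""

import itertools

import numpy as np
import pytest

from smterm.stepfinder import (
    MIN_SEGMENT,
    default_penalty,
    detect_steps,
    estimate_noise_sd,
    label_levels,
)

LEVELS = {"dark": 0.0, "base": 5.0, "pife": 10.0}


def exhaustive_segmentation(x, penalty, max_cp=3, min_seg=MIN_SEGMENT):
    """Brute force: minimize SSE + penalty*k over every partition (<= max_cp
    change points, segments >= min_seg), preferring fewer change points on
    ties.  Independent oracle for the dynamic program."""
    n = len(x)
    best = None
    for k in range(max_cp + 1):
        for cps in itertools.combinations(range(min_seg, n - min_seg + 1), k):
            bounds = (0, *cps, n)
            if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            sse = sum(
                float(((x[a:b] - x[a:b].mean()) ** 2).sum())
                for a, b in zip(bounds[:-1], bounds[1:])
            )
            cost = sse + penalty * k
            if best is None or cost < best[0] - 1e-9:
                best = (cost, k, cps)
    return best[2]


def random_staircase(rng, max_frames=50, max_cp=3):
    n = int(rng.integers(4 * MIN_SEGMENT, max_frames + 1))
    k = int(rng.integers(0, max_cp + 1))
    while True:
        cps = np.sort(rng.choice(np.arange(MIN_SEGMENT, n - MIN_SEGMENT + 1),
                                 size=k, replace=False))
        bounds = [0, *cps.tolist(), n]
        if all(b - a >= MIN_SEGMENT for a, b in zip(bounds[:-1], bounds[1:])):
            break
    # adjacent levels differ by >= 1 so every true step is worth the penalty
    levels = [float(rng.uniform(0, 5))]
    for _ in range(k):
        levels.append(levels[-1] + float(rng.choice([-1, 1]) * rng.uniform(1, 3)))
    x = np.concatenate([np.full(b - a, lv)
                        for a, b, lv in zip(bounds[:-1], bounds[1:], levels)])
    return x, tuple(int(c) for c in cps)


def test_single_step_noiseless():
    seg = detect_steps(np.array([5.0, 5, 5, 1, 1, 1]), penalty=0.5)
    assert seg.change_points == (3,)
    assert seg.segment_means == (5.0, 1.0)


def test_constant_signal_has_no_change_points():
    seg = detect_steps(np.full(30, 2.5))
    assert seg.change_points == ()
    assert seg.segment_means == (2.5,)


def test_matches_exhaustive_oracle_on_random_staircases():
    """100 random noiseless piecewise-constant signals <= 50 frames, <= 3 steps."""
    rng = np.random.default_rng(77)
    for _ in range(100):
        x, true_cps = random_staircase(rng)
        penalty = 0.5
        got = detect_steps(x, penalty=penalty)
        assert got.change_points == exhaustive_segmentation(x, penalty)
        assert got.change_points == true_cps  # exact recovery, noiseless


def test_noiseless_recovery_is_exact_for_long_trace_shapes():
    x = np.concatenate([np.full(12, 2.0), np.full(120, 1.0), np.full(630, 0.0)])
    seg = detect_steps(x)
    assert seg.change_points == (12, 132)
    assert seg.segment_means == (2.0, 1.0, 0.0)


def test_heavier_penalty_never_adds_change_points():
    rng = np.random.default_rng(3)
    for _ in range(20):
        x, _ = random_staircase(rng)
        x = x + rng.normal(0, 0.3, len(x))
        counts = [
            len(detect_steps(x, penalty=p).change_points)
            for p in (0.1, 0.5, 2.0, 8.0, 32.0)
        ]
        assert counts == sorted(counts, reverse=True)


def test_segment_means_are_arithmetic_means():
    rng = np.random.default_rng(8)
    x = np.concatenate([np.full(20, 1.0), np.full(20, 3.0)]) + rng.normal(0, 0.2, 40)
    seg = detect_steps(x)
    for (a, b), mean in zip(
        zip(seg.boundaries[:-1], seg.boundaries[1:]), seg.segment_means
    ):
        assert mean == pytest.approx(float(x[a:b].mean()))


def test_noise_sd_estimator_is_robust_to_steps():
    rng = np.random.default_rng(4)
    x = np.concatenate([np.full(200, 0.0), np.full(200, 5.0)]) + rng.normal(0, 0.3, 400)
    assert estimate_noise_sd(x) == pytest.approx(0.3, rel=0.2)
    assert default_penalty(x) > 0


def test_label_by_nearest_level():
    seg = detect_steps(np.array([10.0, 10, 5, 5, 0, 0]), penalty=0.5)
    labeled = label_levels(seg, LEVELS)
    assert labeled.segment_labels == ("pife", "base", "dark")


def test_label_tie_breaks_toward_lower_level():
    from smterm.stepfinder import StepSegmentation

    seg = StepSegmentation(4, (), (7.5,))  # midway between base=5 and pife=10
    assert label_levels(seg, LEVELS).segment_labels == ("base",)


def test_noisy_segment_labels_match_truth():
    """>=99% correct labels on noisy segments with sd = 0.15 x level gap."""
    rng = np.random.default_rng(15)
    gap = 5.0
    correct = total = 0
    for _ in range(100):  # 100 signals x 5 segments = 500 segments
        labels_true = rng.choice(["dark", "base", "pife"], size=5)
        x = np.concatenate([
            np.full(12, LEVELS[l]) + rng.normal(0, 0.15 * gap, 12)
            for l in labels_true
        ])
        seg = label_levels(detect_steps(x), LEVELS)
        runs = seg.merged_label_runs()
        # read back the label at each true segment's midpoint
        for i, lt in enumerate(labels_true):
            mid = i * 12 + 6
            lab = next(l for s, e, l in runs if s <= mid < e)
            correct += lab == lt
            total += 1
    assert correct / total >= 0.99


def test_merged_label_runs_collapse_equal_neighbors():
    from smterm.stepfinder import StepSegmentation

    seg = StepSegmentation(12, (4, 8), (5.0, 5.4, 0.1),
                           segment_labels=("base", "base", "dark"))
    assert seg.merged_label_runs() == [(0, 8, "base"), (8, 12, "dark")]


def test_rejects_bad_inputs():
    with pytest.raises(ValueError):
        detect_steps(np.array([1.0]))
    with pytest.raises(ValueError):
        detect_steps(np.zeros(10), penalty=0.0)
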