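"""Ensemble statistics for termination efficiency, timing and comparisons.

Termination efficiency is the fraction of classified active complexes that
terminated rather than read through; its uncertainty is the sample SD over
replicate groups (emulating independent experiments), not a binomial SE.
Timing statistics summarize the arrival time tau_e (readthrough traces) and
the release time tau_t (termination traces); the fold delay tau_t/tau_e
uses means (medians are also reported).  Rank-sum comparison of two timing
samples uses the Wilcoxon/Mann-Whitney statistic with mid-ranks, a
tie-corrected normal approximation with continuity correction, and exact
enumeration of all rank assignments for small samples.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trace_model import Label, TraceClassification

__all__ = [
    "TimingSummary",
    "EnsembleReport",
    "RankSumResult",
    "MismatchScan",
    "MismatchPeak",
    "termination_efficiency",
    "recycling_fraction",
    "timing_stats",
    "rank_sum_test",
    "mismatch_peak",
]

_CLASSIFIED = (Label.READTHROUGH, Label.DECOMPOSING, Label.RECYCLING)


@dataclass(frozen=True)
class TimingSummary:
    """Moments of one dwell-time sample (seconds)."""

    n: int
    mean: float | None
    sd: float | None
    median: float | None

    @classmethod
    def from_sample(cls, values: Sequence[float]) -> "TimingSummary":
        arr = np.asarray(values, dtype=float)
        if len(arr) == 0:
            return cls(n=0, mean=None, sd=None, median=None)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        return cls(n=len(arr), mean=float(np.mean(arr)), sd=sd, median=float(np.median(arr)))


@dataclass(frozen=True)
class EnsembleReport:
    """Outcome counts and derived statistics for one classified ensemble."""

    replicate_counts: Mapping[int, Mapping[str, int]]
    efficiency_mean: float
    efficiency_sd: float
    decomposing_efficiency: float
    recycling_efficiency: float
    tau_e: TimingSummary
    tau_t: TimingSummary
    fold_delay: float | None
    fold_delay_median: float | None
    recycling_fraction_pooled: float

    def __post_init__(self) -> None:
        for name in ("efficiency_mean", "decomposing_efficiency", "recycling_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fold_delay is not None and not self.fold_delay > 0:
            raise ValueError("fold_delay must be positive when defined")

    @property
    def total_counts(self) -> dict[str, int]:
        totals: Counter[str] = Counter()
        for counts in self.replicate_counts.values():
            totals.update(counts)
        return dict(totals)

    def to_dict(self) -> dict:
        return {
            "replicate_counts": {str(k): dict(v) for k, v in self.replicate_counts.items()},
            "total_counts": self.total_counts,
            "efficiency_mean": self.efficiency_mean,
            "efficiency_sd": self.efficiency_sd,
            "decomposing_efficiency": self.decomposing_efficiency,
            "recycling_efficiency": self.recycling_efficiency,
            "tau_e": vars(self.tau_e).copy(),
            "tau_t": vars(self.tau_t).copy(),
            "fold_delay": self.fold_delay,
            "fold_delay_median": self.fold_delay_median,
            "recycling_fraction_pooled": self.recycling_fraction_pooled,
        }


def _replicate_efficiencies(
    classifications: Sequence[TraceClassification],
) -> tuple[dict[int, dict[str, int]], list[float], list[float], list[float]]:
    by_rep: dict[int, Counter] = {}
    for c in classifications:
        by_rep.setdefault(c.replicate_id, Counter())[c.outcome.value] += 1
    counts: dict[int, dict[str, int]] = {}
    eff, dec_eff, rec_eff = [], [], []
    for rep in sorted(by_rep):
        cnt = by_rep[rep]
        counts[rep] = {lab.value: cnt.get(lab.value, 0) for lab in Label}
        rt = cnt.get(Label.READTHROUGH.value, 0)
        dec = cnt.get(Label.DECOMPOSING.value, 0)
        rec = cnt.get(Label.RECYCLING.value, 0)
        classified = rt + dec + rec
        if classified == 0:
            raise ValueError(f"replicate {rep} has no classified traces")
        eff.append((dec + rec) / classified)
        dec_eff.append(dec / classified)
        rec_eff.append(rec / classified)
    return counts, eff, dec_eff, rec_eff


def termination_efficiency(
    classifications: Sequence[TraceClassification],
) -> EnsembleReport:
    """Full ensemble report from per-trace classifications.

    Per replicate, efficiency = (decomposing + recycling) / classified,
    with censored/unclassified and inactive traces excluded from the
    denominator; the report carries the mean and sample SD across
    replicates (SD 0 by convention for a single replicate).  The
    decomposing and recycling efficiencies decompose the total exactly.
    """
    if not classifications:
        raise ValueError("no classifications given")
    counts, eff, dec_eff, rec_eff = _replicate_efficiencies(classifications)
    timing = timing_stats(classifications)
    totals: Counter[str] = Counter()
    for cnt in counts.values():
        totals.update(cnt)
    classified_total = sum(totals[lab.value] for lab in _CLASSIFIED)
    pooled_rec = totals[Label.RECYCLING.value] / classified_total
    sd = float(np.std(eff, ddof=1)) if len(eff) > 1 else 0.0
    return EnsembleReport(
        replicate_counts=counts,
        efficiency_mean=float(np.mean(eff)),
        efficiency_sd=sd,
        decomposing_efficiency=float(np.mean(dec_eff)),
        recycling_efficiency=float(np.mean(rec_eff)),
        tau_e=timing["tau_e"],
        tau_t=timing["tau_t"],
        fold_delay=timing["fold_delay"],
        fold_delay_median=timing["fold_delay_median"],
        recycling_fraction_pooled=pooled_rec,
    )


def recycling_fraction(
    counts: Sequence[tuple[int, int]],
) -> tuple[float, list[float]]:
    """Pooled and per-pair recycling fractions.

    ``counts`` holds one (n_recycling, n_classified) pair per
    polymerase-terminator combination; the pooled fraction divides the
    summed recycling events by the summed classified active complexes.
    """
    if not counts:
        raise ValueError("no counts given")
    per_pair = []
    for rec, total in counts:
        if rec < 0 or total < 0:
            raise ValueError("counts must be non-negative")
        if total == 0:
            raise ValueError("zero classified complexes in one pair")
        if rec > total:
            raise ValueError("recycling count exceeds total")
        per_pair.append(rec / total)
    pooled = sum(rec for rec, _ in counts) / sum(total for _, total in counts)
    return pooled, per_pair


def timing_stats(
    classifications: Sequence[TraceClassification],
) -> dict:
    """tau_e / tau_t summaries plus mean- and median-based fold delays.

    tau_e is taken from readthrough traces, tau_t from termination traces
    (decomposing and recycling).  An empty class leaves its summary with
    n = 0 and the corresponding fold delay undefined (None).
    """
    tau_e = [c.tau_e_hat_s for c in classifications if c.outcome is Label.READTHROUGH]
    tau_t = [
        c.tau_t_hat_s
        for c in classifications
        if c.outcome in (Label.DECOMPOSING, Label.RECYCLING)
    ]
    se = TimingSummary.from_sample(tau_e)
    st = TimingSummary.from_sample(tau_t)
    fold = st.mean / se.mean if se.n and st.n and se.mean else None
    fold_med = st.median / se.median if se.n and st.n and se.median else None
    return {"tau_e": se, "tau_t": st, "fold_delay": fold, "fold_delay_median": fold_med}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum outcome: W is the rank sum of the first sample."""

    statistic: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        lo = self.n1 * (self.n1 + 1) / 2
        hi = self.n1 * self.n2 + lo
        if not lo - 1e-9 <= self.statistic <= hi + 1e-9:
            raise ValueError("rank sum outside attainable range")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank of the tie group
        i = j
    return ranks


#: Combined sample size at or below which the exact permutation branch runs.
EXACT_LIMIT = 12


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of samples x and y.

    Mid-ranks handle ties.  For n1 + n2 <= 12 the null distribution of the
    rank sum W is enumerated exactly over all C(n1+n2, n1) assignments of
    the pooled (possibly tied) ranks, and the two-sided p-value is
    2 * min(P(W <= w), P(W >= w)) capped at 1.  Larger samples use the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.  Identical samples give p ~= 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    # tie-corrected variance of W
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var > 0:
        cc = 0.5 * np.sign(w - mu)
        z = (w - mu - cc) / math.sqrt(var)
    else:
        z = 0.0

    if n <= EXACT_LIMIT:
        sums = [sum(c) for c in itertools.combinations(ranks, n1)]
        total = len(sums)
        p_le = sum(1 for s in sums if s <= w + 1e-9) / total
        p_ge = sum(1 for s in sums if s >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        from scipy.stats import norm

        p = min(1.0, 2.0 * float(norm.sf(abs(z)))) if var > 0 else 1.0
        method = "normal"
    return RankSumResult(statistic=w, z=float(z), p_two_sided=p, n1=n1, n2=n2, method=method)


# ---------------------------------------------------------------------------
# Mismatch scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MismatchScan:
    """Per-position termination efficiencies of a terminator mismatch scan."""

    positions: tuple[int, ...]
    efficiencies: tuple[float, ...]
    wildtype_efficiency: float
    termination_site: int = 130

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.efficiencies):
            raise ValueError("positions and efficiencies must align")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("positions must be distinct")
        for e in (*self.efficiencies, self.wildtype_efficiency):
            if not 0.0 <= e <= 1.0:
                raise ValueError("efficiencies must lie in [0, 1]")


@dataclass(frozen=True)
class MismatchPeak:
    """Location of the strongest mismatch effect on termination."""

    peak_position: int
    offset_from_termination_site: int
    impaired: dict[int, bool]


def mismatch_peak(scan: MismatchScan) -> MismatchPeak:
    """Locate the position where the mismatch impairs termination most.

    The peak is the position of minimum efficiency; ties resolve to the
    position closest to the termination site, then to the most upstream
    (smallest coordinate).  The offset is termination_site - peak, so a
    positive offset means the peak lies upstream.  Each position is flagged
    impaired when its efficiency falls below the wildtype's.
    """
    if len(scan.positions) < 3:
        raise ValueError("need at least 3 scanned positions")
    site = scan.termination_site
    peak = min(
        zip(scan.positions, scan.efficiencies),
        key=lambda pe: (pe[1], abs(pe[0] - site), pe[0]),
    )[0]
    impaired = {
        pos: eff < scan.wildtype_efficiency
        for pos, eff in zip(scan.positions, scan.efficiencies)
    }
    return MismatchPeak(
        peak_position=peak,
        offset_from_termination_site=site - peak,
        impaired=impaired,
    )
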