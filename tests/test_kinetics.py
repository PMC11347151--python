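"""Ensemble statistics: efficiencies, timing, rank-sum test, mismatch scan."""

import itertools

import numpy as np
import pytest
from scipy import stats

from smterm.kinetics import (
    MismatchScan,
    mismatch_peak,
    rank_sum_test,
    recycling_fraction,
    termination_efficiency,
    timing_stats,
)
from smterm.trace_model import Label, TraceClassification


def _cls(outcome, tau_e=None, tau_t=None, rep=0, i=[0]):
    i[0] += 1
    return TraceClassification(
        trace_id=f"t{i[0]:05d}", outcome=outcome, tau_e_hat_s=tau_e,
        tau_t_hat_s=tau_t, censored=outcome is Label.UNCLASSIFIED, replicate_id=rep,
    )


def _batch(n_rt, n_dec, n_rec=0, n_cens=0, rep=0, tau_e=8.0, tau_t=50.0):
    out = []
    out += [_cls(Label.READTHROUGH, tau_e=tau_e, rep=rep) for _ in range(n_rt)]
    out += [_cls(Label.DECOMPOSING, tau_t=tau_t, rep=rep) for _ in range(n_dec)]
    out += [_cls(Label.RECYCLING, tau_t=tau_t, rep=rep) for _ in range(n_rec)]
    out += [_cls(Label.UNCLASSIFIED, rep=rep) for _ in range(n_cens)]
    return out


def test_single_replicate_efficiency_and_sd_convention():
    rep = termination_efficiency(_batch(46, 54))
    assert rep.efficiency_mean == pytest.approx(0.54)
    assert rep.efficiency_sd == 0.0


def test_all_readthrough_gives_zero_efficiency():
    rep = termination_efficiency(_batch(30, 0))
    assert rep.efficiency_mean == 0.0


def test_censored_traces_leave_the_denominator():
    rep = termination_efficiency(_batch(50, 50, n_cens=37))
    assert rep.efficiency_mean == pytest.approx(0.5)


def test_replicate_without_classified_traces_is_named():
    cls = _batch(10, 10, rep=0) + [_cls(Label.UNCLASSIFIED, rep=1)]
    with pytest.raises(ValueError, match="replicate 1"):
        termination_efficiency(cls)


def test_efficiency_decomposes_exactly():
    cls = (_batch(40, 50, n_rec=10, rep=0)
           + _batch(50, 45, n_rec=5, rep=1)
           + _batch(45, 50, n_rec=5, rep=2))
    rep = termination_efficiency(cls)
    assert rep.decomposing_efficiency + rep.recycling_efficiency == pytest.approx(
        rep.efficiency_mean
    )
    assert rep.efficiency_sd > 0


def test_recycling_fractions_from_event_counts():
    pooled, per_pair = recycling_fraction([(1, 474), (1, 351), (3, 672), (0, 3023)])
    assert round(100 * pooled, 1) == 0.1  # 5 / 4520
    assert round(100 * per_pair[0], 1) == 0.2
    assert round(100 * per_pair[1], 1) == 0.3
    assert round(100 * per_pair[2], 1) == 0.4
    assert per_pair[3] == 0.0
    with pytest.raises(ValueError, match="zero classified"):
        recycling_fraction([(0, 0)])


def test_fold_delay_from_reported_means():
    cls = _batch(10, 10, tau_e=7.5, tau_t=52.0)
    t = timing_stats(cls)
    assert t["fold_delay"] == pytest.approx(52.0 / 7.5)
    assert round(t["fold_delay"], 1) == 6.9


def test_identical_dwells_give_unit_fold_delay():
    cls = _batch(5, 5, tau_e=12.0, tau_t=12.0)
    assert timing_stats(cls)["fold_delay"] == pytest.approx(1.0)


def test_empty_class_flags_undefined_summary():
    t = timing_stats(_batch(0, 4))
    assert t["tau_e"].n == 0 and t["tau_e"].mean is None
    assert t["fold_delay"] is None


def test_gamma_dwell_mean_recovery():
    """Monte-Carlo: sample mean of gamma(52, 13) dwells within 3 SE."""
    rng = np.random.default_rng(6)
    n = 500
    shape, scale = (52 / 13) ** 2, 13**2 / 52
    draws = rng.gamma(shape, scale, n)
    cls = [_cls(Label.DECOMPOSING, tau_t=float(v)) for v in draws]
    t = timing_stats(cls)
    assert t["tau_t"].mean == pytest.approx(np.mean(draws))
    assert abs(t["tau_t"].mean - 52.0) < 3 * 13 / np.sqrt(n)


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------


def enumeration_oracle(x, y):
    """Independent two-sided rank-sum p by enumerating index subsets."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w = ranks[:n1].sum()
    sums = [sum(ranks[list(ix)]) for ix in itertools.combinations(range(len(pooled)), n1)]
    p_le = np.mean([s <= w + 1e-9 for s in sums])
    p_ge = np.mean([s >= w - 1e-9 for s in sums])
    return min(1.0, 2 * min(p_le, p_ge))


def test_rank_sum_small_sample_textbook_case():
    res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
    assert res.method == "exact"
    assert res.statistic == 3.0
    assert res.p_two_sided == pytest.approx(2 / 6)


def test_rank_sum_symmetric_input_p_is_one():
    res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_two_sided == pytest.approx(1.0)


@pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(1, 7)])
def test_rank_sum_exact_branch_matches_enumeration(n1, n2):
    rng = np.random.default_rng(n1 * 100 + n2)
    for _ in range(3):
        x = rng.integers(0, 5, n1).astype(float)  # integer values force ties
        y = rng.integers(0, 5, n2).astype(float)
        res = rank_sum_test(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(enumeration_oracle(x, y))


def test_rank_sum_large_shift_is_powerful():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 1, 100)
    y = rng.normal(2, 1, 100)  # shift of 2 pooled SD
    res = rank_sum_test(x, y)
    assert res.method == "normal"
    assert res.p_two_sided < 1e-6


def test_rank_sum_normal_branch_matches_reference_implementation():
    rng = np.random.default_rng(14)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0.4, 1, 25)
    res = rank_sum_test(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


def test_rank_sum_rejects_empty_sample():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


# ---------------------------------------------------------------------------
# Mismatch scan
# ---------------------------------------------------------------------------


def test_peak_offset_ten_bp_upstream():
    positions = tuple(range(112, 136, 2))
    effs = tuple(0.5 if p != 120 else 0.2 for p in positions)
    peak = mismatch_peak(MismatchScan(positions, effs, 0.54, termination_site=130))
    assert peak.peak_position == 120
    assert peak.offset_from_termination_site == 10
    assert all(peak.impaired.values())


def test_flat_scan_ties_resolve_near_termination_site():
    positions = tuple(range(112, 136, 2))
    effs = tuple(0.54 for _ in positions)
    peak = mismatch_peak(MismatchScan(positions, effs, 0.54, termination_site=130))
    assert peak.peak_position == 130
    assert not any(peak.impaired.values())


def test_random_scans_match_brute_force_argmin():
    rng = np.random.default_rng(9)
    positions = tuple(range(112, 136, 2))
    for _ in range(50):
        effs = tuple(float(e) for e in rng.uniform(0.1, 0.9, len(positions)))
        peak = mismatch_peak(MismatchScan(positions, effs, 0.54, termination_site=130))
        assert peak.peak_position == positions[int(np.argmin(effs))]


def test_scan_needs_three_positions():
    with pytest.raises(ValueError):
        mismatch_peak(MismatchScan((112, 114), (0.5, 0.5), 0.54))
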