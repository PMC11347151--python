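"""Outcome classification: decision rules, activity filter, invariants."""

import numpy as np
import pytest

from smterm.classify import activity_filter, classify_ensemble, classify_trace
from smterm.stepfinder import StepSegmentation, detect_steps, label_levels
from smterm.synthetic_data import (
    GeneratorConfig,
    ideal_profiles,
    observable_classification,
    render_trace,
    sample_event_times,
)
from smterm.trace_model import EventTimes, Label, Outcome

CFG0 = GeneratorConfig(noise_sd=0.0)


def _ideal_segmentation(signal, level_table):
    """Exact segmentation of a noiseless piecewise-constant vector (no DP)."""
    cps = tuple(int(i) for i in np.flatnonzero(np.diff(signal)) + 1)
    bounds = (0, *cps, len(signal))
    means = tuple(float(signal[a]) for a in bounds[:-1])
    return label_levels(StepSegmentation(len(signal), cps, means), level_table)


def _segment_events(ev, cfg=CFG0):
    donor, acceptor = ideal_profiles(ev, cfg)
    return (
        _ideal_segmentation(donor, cfg.level_table("donor")),
        _ideal_segmentation(acceptor, cfg.level_table("acceptor")),
    )


def _classify_events(ev, cfg=CFG0):
    dseg, aseg = _segment_events(ev, cfg)
    return classify_trace(
        dseg, aseg, t0_index=cfg.t0_index, window_s=cfg.window_s,
        frame_period_s=cfg.frame_period_s,
    )


def test_flat_pife_donor_is_inactive():
    ev = EventTimes(Outcome.INACTIVE, None, None, None, 1e6, 1e6)
    dseg, aseg = _segment_events(ev)
    active, t_resume = activity_filter(dseg, CFG0.t0_index, CFG0.frame_period_s, CFG0.window_s)
    assert not active and t_resume is None
    assert _classify_events(ev).outcome is Label.INACTIVE


def test_resumption_time_is_transition_frame():
    ev = EventTimes(Outcome.DECOMPOSING, 4.8, None, 20.0, 1e6, 1e6)
    dseg, _ = _segment_events(ev)
    active, t_resume = activity_filter(dseg, CFG0.t0_index, CFG0.frame_period_s, CFG0.window_s)
    assert active
    assert t_resume == pytest.approx(4.8)  # 12 frames after injection


def test_noiseless_decomposing_trace():
    ev = EventTimes(Outcome.DECOMPOSING, 2.0, None, 20.0, 1e6, 1e6)
    cls = _classify_events(ev)
    assert cls.outcome is Label.DECOMPOSING
    assert cls.tau_t_hat_s == pytest.approx(20.0, abs=CFG0.frame_period_s)
    assert cls.tau_e_hat_s is None


def test_noiseless_readthrough_trace():
    ev = EventTimes(Outcome.READTHROUGH, 2.0, 8.0, None, 1e6, 1e6)
    cls = _classify_events(ev)
    assert cls.outcome is Label.READTHROUGH
    assert cls.tau_e_hat_s == pytest.approx(8.0, abs=CFG0.frame_period_s)


def test_noiseless_recycling_trace():
    ev = EventTimes(Outcome.RECYCLING, 2.0, 35.0, 20.0, 1e6, 1e6)
    cls = _classify_events(ev)
    assert cls.outcome is Label.RECYCLING
    assert cls.tau_t_hat_s == pytest.approx(20.0, abs=CFG0.frame_period_s)


def test_acceptor_bleach_before_event_censors():
    ev = EventTimes(Outcome.DECOMPOSING, 2.0, None, 20.0, 1e6, 10.0)
    cls = _classify_events(ev)
    assert cls.outcome is Label.UNCLASSIFIED and cls.censored


def test_event_outside_window_censors():
    cfg = GeneratorConfig(noise_sd=0.0, window_s=30.0)
    ev = EventTimes(Outcome.DECOMPOSING, 2.0, None, 200.0, 1e6, 1e6)
    dseg, aseg = _segment_events(ev, cfg)
    cls = classify_trace(dseg, aseg, cfg.t0_index, cfg.window_s, cfg.frame_period_s)
    assert cls.outcome is Label.UNCLASSIFIED and cls.censored


def test_unlabeled_segmentation_is_a_contract_error():
    seg = StepSegmentation(10, (), (1.0,))
    with pytest.raises(ValueError, match="label"):
        classify_trace(seg, seg, 0, 300.0, 0.4)


def test_active_fraction_recovers_binomial_truth():
    """1000 schedules at p_active = 0.7: filter recovers the fraction."""
    cfg = GeneratorConfig(p_active=0.7)
    rng = np.random.default_rng(21)
    n = 1000
    active = 0
    for _ in range(n):
        ev = sample_event_times(cfg, rng)
        dseg, _ = _segment_events(ev, cfg)
        flag, _ = activity_filter(dseg, cfg.t0_index, cfg.frame_period_s, cfg.window_s)
        active += flag
    se = np.sqrt(0.7 * 0.3 / n)
    assert abs(active / n - 0.7) < 3 * se


def test_empty_ensemble_classifies_to_empty():
    assert classify_ensemble([], CFG0) == []


def test_all_inactive_ensemble():
    cfg = GeneratorConfig(n_traces=6, p_active=0.0, seed=5, window_s=40.0)
    from smterm.synthetic_data import simulate_ensemble

    traces, _ = simulate_ensemble(cfg)
    cls = classify_ensemble(traces, cfg)
    assert all(c.outcome is Label.INACTIVE for c in cls)


def test_noisy_ensemble_matches_observable_truth(noisy_ensemble_200):
    """Full pipeline at default noise: >= 98% agreement with the ideal
    observer, and active traces partition into exactly one label each."""
    cfg, traces, truth = noisy_ensemble_200
    cls = classify_ensemble(traces, cfg, replicate_ids=truth.replicate_ids)
    obs = [
        observable_classification(e, cfg, t.trace_id, r)
        for e, t, r in zip(truth.events, traces, truth.replicate_ids)
    ]
    agreement = np.mean([c.outcome == o.outcome for c, o in zip(cls, obs)])
    assert agreement >= 0.98
    # partition: one label per trace, counts conserved
    assert len(cls) == len(traces)
    n_active = sum(c.outcome is not Label.INACTIVE for c in cls)
    by_label = {
        lab: sum(c.outcome is lab for c in cls)
        for lab in (Label.READTHROUGH, Label.DECOMPOSING, Label.RECYCLING, Label.UNCLASSIFIED)
    }
    assert sum(by_label.values()) == n_active


def test_classification_invariant_to_uniform_scaling(noisy_ensemble_200):
    cfg, traces, _ = noisy_ensemble_200
    sub = traces[:15]
    factor = 37.0
    import dataclasses

    cfg_scaled = dataclasses.replace(
        cfg,
        donor_dark=cfg.donor_dark * factor, donor_base=cfg.donor_base * factor,
        donor_pife=cfg.donor_pife * factor, acceptor_dark=cfg.acceptor_dark * factor,
        acceptor_base=cfg.acceptor_base * factor, acceptor_pife=cfg.acceptor_pife * factor,
        noise_sd=cfg.noise_sd * factor,
    )
    base = classify_ensemble(sub, cfg)
    scaled = classify_ensemble([t.scaled(factor) for t in sub], cfg_scaled)
    assert [c.outcome for c in base] == [c.outcome for c in scaled]
    for a, b in zip(base, scaled):
        assert (a.tau_t_hat_s is None) == (b.tau_t_hat_s is None)
        if a.tau_t_hat_s is not None:
            assert a.tau_t_hat_s == pytest.approx(b.tau_t_hat_s, abs=cfg.frame_period_s)
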