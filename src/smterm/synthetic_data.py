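"""Stochastic generator of single-molecule termination trace ensembles.

The generator encodes the kinetic scheme of the single-molecule assay: a
stalled elongation complex shows donor (Cy3) PIFE; at NTP injection (time
zero) active complexes resume elongation and the donor PIFE drops to the
base level; a readthrough complex reaches the acceptor-labeled (Cy5) DNA
end at ``tau_e`` (acceptor PIFE pulse, then runoff ends both signals); a
decomposing termination releases the labeled RNA at ``tau_t`` (donor signal
lost, no acceptor PIFE); a recycling termination releases RNA at ``tau_t``
and the DNA-bound polymerase later reaches the acceptor end (acceptor PIFE
*after* the donor loss).  Dyes photobleach exponentially and every frame
carries additive Gaussian camera noise.

Dwell times use gamma distributions moment-matched to (mean, sd); only
means and SDs of the experimental dwell times are known, and the gamma
family keeps positivity while nesting the exponential.

Besides the latent :class:`~smterm.trace_model.EventTimes`, the module
derives the *observable* classification of each trace
(:func:`observable_classification`): the label an ideal observer would
assign at the instrument's frame resolution, accounting for photobleaching,
the finite observation window, and sub-resolution (< 2 frame) segments.
This is the ground truth the classifier is benchmarked against — a
readthrough whose donor bleaches before arrival is *observably* a release
event, and no detector can recover the latent label.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .trace_model import EventTimes, Label, Outcome, Trace, TraceClassification

__all__ = [
    "GeneratorConfig",
    "EnsembleTruth",
    "PRESETS",
    "preset",
    "sample_event_times",
    "ideal_profiles",
    "render_trace",
    "simulate_ensemble",
    "observable_classification",
    "mismatch_series",
    "MISMATCH_POSITIONS",
]

#: Coincidence tolerance (frames) shared with the classifier: the acceptor
#: PIFE offset and donor loss count as simultaneous within this many frames.
DEFAULT_TOL_FRAMES = 2
#: Shortest level segment (frames) the step detector is allowed to emit;
#: shorter true segments are unresolvable and the observable truth says so.
MIN_SEGMENT_FRAMES = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Flat parameter set for one simulated ensemble.

    Times are seconds, intensities arbitrary units.  Defaults reproduce the
    reference T7 RNAP / class-I terminator condition: 54% termination, all
    of it decomposing, arrival time 7.5 +/- 2.2 s, release time 52 +/- 13 s,
    0.4-s frames, 5-min event window, donor/acceptor bleaching means of 23
    and 39 min.
    """

    n_traces: int = 1400
    seed: int = 0
    frame_period_s: float = 0.4
    t0_index: int = 12
    window_s: float = 300.0
    p_active: float = 0.7
    p_termination: float = 0.54
    p_recycling_given_termination: float = 0.0
    tau_e_mean_s: float = 7.5
    tau_e_sd_s: float = 2.2
    tau_t_mean_s: float = 52.0
    tau_t_sd_s: float = 13.0
    t_resume_mean_s: float = 2.0
    t_resume_sd_s: float = 1.0
    recycle_arrival_mean_s: float = 10.0
    runoff_dwell_s: float = 2.0
    bleach_mean_donor_s: float = 1380.0
    bleach_mean_acceptor_s: float = 2340.0
    donor_dark: float = 0.0
    donor_base: float = 1.0
    donor_pife: float = 2.0
    acceptor_dark: float = 0.0
    acceptor_base: float = 1.0
    acceptor_pife: float = 2.0
    noise_sd: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_traces < 0:
            raise ValueError("n_traces must be >= 0")
        for name in ("p_active", "p_termination", "p_recycling_given_termination"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in (
            "frame_period_s", "window_s", "tau_e_mean_s", "tau_e_sd_s",
            "tau_t_mean_s", "tau_t_sd_s", "t_resume_mean_s", "t_resume_sd_s",
            "recycle_arrival_mean_s", "runoff_dwell_s",
            "bleach_mean_donor_s", "bleach_mean_acceptor_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t0_index < 0:
            raise ValueError("t0_index must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for ch in ("donor", "acceptor"):
            dark = getattr(self, f"{ch}_dark")
            base = getattr(self, f"{ch}_base")
            pife = getattr(self, f"{ch}_pife")
            if not dark < base < pife:
                raise ValueError(f"{ch} levels must satisfy dark < base < pife")
        if self.n_frames < 2:
            raise ValueError("observation window shorter than 2 frames")

    @property
    def n_frames(self) -> int:
        return self.t0_index + int(round(self.window_s / self.frame_period_s))

    def level_table(self, channel: str) -> dict[str, float]:
        return {
            "dark": getattr(self, f"{channel}_dark"),
            "base": getattr(self, f"{channel}_base"),
            "pife": getattr(self, f"{channel}_pife"),
        }

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# Named presets for the RNAP/terminator pairs most used in testing.  The
# recycling probabilities make the pooled recycling fractions land at the
# observed per-pair magnitudes (~0.2-0.3% of active complexes).
PRESETS: dict[str, dict[str, float]] = {
    "T7_Tphi": {"p_termination": 0.54, "p_recycling_given_termination": 0.0},
    "T3_Tphi": {"p_termination": 0.54, "p_recycling_given_termination": 0.004},
    "SP6_t5": {"p_termination": 0.86, "p_recycling_given_termination": 0.0035},
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a named preset plus overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return GeneratorConfig(**params)


def _gamma(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gamma draw moment-matched to (mean, sd)."""
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def _resume_before(rng: np.random.Generator, cfg: GeneratorConfig, deadline: float) -> float:
    """Resumption time conditioned on preceding the first downstream event."""
    for _ in range(1000):
        t = _gamma(rng, cfg.t_resume_mean_s, cfg.t_resume_sd_s)
        if t < deadline:
            return t
    # Pathological parameter sets only (deadline far in the left tail).
    return float(rng.uniform(0.0, deadline))


def sample_event_times(config: GeneratorConfig, rng: np.random.Generator) -> EventTimes:
    """Draw one complex's latent event schedule.

    Outcome: inactive w.p. 1 - p_active; otherwise termination w.p.
    p_termination (recycling w.p. p_recycling_given_termination within
    termination) else readthrough.  Dwells are gamma; bleach times are
    exponential; the recycling arrival is the release time plus an
    exponential lag; resumption is resampled to precede the first
    downstream event, since elongation cannot finish before it resumes.
    """
    bleach_d = float(rng.exponential(config.bleach_mean_donor_s))
    bleach_a = float(rng.exponential(config.bleach_mean_acceptor_s))
    if rng.random() >= config.p_active:
        return EventTimes(
            outcome=Outcome.INACTIVE,
            t_resume_s=None, tau_e_s=None, tau_t_s=None,
            bleach_donor_s=bleach_d, bleach_acceptor_s=bleach_a,
        )
    if rng.random() < config.p_termination:
        tau_t = _gamma(rng, config.tau_t_mean_s, config.tau_t_sd_s)
        t_resume = _resume_before(rng, config, tau_t)
        if rng.random() < config.p_recycling_given_termination:
            arrival = tau_t + float(rng.exponential(config.recycle_arrival_mean_s))
            return EventTimes(
                outcome=Outcome.RECYCLING,
                t_resume_s=t_resume, tau_e_s=arrival, tau_t_s=tau_t,
                bleach_donor_s=bleach_d, bleach_acceptor_s=bleach_a,
            )
        return EventTimes(
            outcome=Outcome.DECOMPOSING,
            t_resume_s=t_resume, tau_e_s=None, tau_t_s=tau_t,
            bleach_donor_s=bleach_d, bleach_acceptor_s=bleach_a,
        )
    tau_e = _gamma(rng, config.tau_e_mean_s, config.tau_e_sd_s)
    t_resume = _resume_before(rng, config, tau_e)
    return EventTimes(
        outcome=Outcome.READTHROUGH,
        t_resume_s=t_resume, tau_e_s=tau_e, tau_t_s=None,
        bleach_donor_s=bleach_d, bleach_acceptor_s=bleach_a,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _donor_terminal_s(events: EventTimes, config: GeneratorConfig) -> float:
    """Time the donor signal is lost for kinetic (non-bleach) reasons."""
    if events.outcome in (Outcome.DECOMPOSING, Outcome.RECYCLING):
        return events.tau_t_s
    if events.outcome is Outcome.READTHROUGH:
        return events.tau_e_s + config.runoff_dwell_s
    return math.inf


def ideal_profiles(events: EventTimes, config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free piecewise-constant channel profiles for one trace.

    Frame i shows the level holding at time ``(i - t0_index) * frame_period``;
    a transition at time tau first appears on the first frame at or after
    tau.  Bleaching clocks start at injection and force the dark level.
    """
    n = config.n_frames
    t = (np.arange(n) - config.t0_index) * config.frame_period_s
    donor = np.full(n, config.donor_pife)
    acceptor = np.full(n, config.acceptor_base)

    terminal = _donor_terminal_s(events, config)
    if events.outcome is not Outcome.INACTIVE:
        donor[(t >= events.t_resume_s) & (t < terminal)] = config.donor_base
        donor[t >= terminal] = config.donor_dark
    donor[t >= events.bleach_donor_s] = config.donor_dark

    if events.outcome in (Outcome.READTHROUGH, Outcome.RECYCLING):
        onset = events.tau_e_s
        acceptor[(t >= onset) & (t < onset + config.runoff_dwell_s)] = config.acceptor_pife
    acceptor[t >= events.bleach_acceptor_s] = config.acceptor_dark
    return donor, acceptor


def render_trace(
    events: EventTimes,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trace_id: str = "tr00000",
) -> Trace:
    """Render one trace: ideal profiles plus additive Gaussian camera noise."""
    donor, acceptor = ideal_profiles(events, config)
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd, size=donor.shape)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, size=acceptor.shape)
    return Trace(
        trace_id=trace_id,
        frame_period_s=config.frame_period_s,
        t0_index=config.t0_index,
        donor=donor,
        acceptor=acceptor,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleTruth:
    """Ground truth for a simulated ensemble: per-trace schedules + tally."""

    events: tuple[EventTimes, ...]
    replicate_ids: tuple[int, ...]
    config: GeneratorConfig
    tally: Mapping[str, int]

    def __post_init__(self) -> None:
        if sum(self.tally.values()) != len(self.events):
            raise ValueError("outcome tally does not sum to n_traces")

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "n_traces": len(self.events),
            "tally": dict(self.tally),
        }


def simulate_ensemble(config: GeneratorConfig) -> tuple[list[Trace], EnsembleTruth]:
    """Simulate a full ensemble, deterministic under ``config.seed``.

    Each trace gets an independent RNG stream spawned from the seed, so
    per-trace results do not depend on ensemble size or order.  Replicate
    ids partition the (exchangeable) traces into ``n_replicates`` equal
    groups round-robin, standing in for independent experiments.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_traces)
    traces: list[Trace] = []
    events_list: list[EventTimes] = []
    replicate_ids: list[int] = []
    tally = {o.value: 0 for o in Outcome}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        events = sample_event_times(config, rng)
        trace_id = f"tr{i:05d}"
        traces.append(render_trace(events, config, rng, trace_id=trace_id))
        events_list.append(events)
        replicate_ids.append(i % config.n_replicates)
        tally[events.outcome.value] += 1
    truth = EnsembleTruth(
        events=tuple(events_list),
        replicate_ids=tuple(replicate_ids),
        config=config,
        tally=tally,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Observable ground truth (ideal observer at frame resolution)
# ---------------------------------------------------------------------------


def _quantize_frames(t_s: float, dt: float) -> int:
    """Frame offset (since injection) of the first frame at or after t_s."""
    return int(math.ceil(t_s / dt - 1e-9))


def observable_classification(
    events: EventTimes,
    config: GeneratorConfig,
    trace_id: str = "tr00000",
    replicate_id: int = 0,
    tol_frames: int = DEFAULT_TOL_FRAMES,
    min_segment: int = MIN_SEGMENT_FRAMES,
) -> TraceClassification:
    """Label an ideal observer would assign to this trace.

    Works directly on the latent schedule, quantized to the frame clock as
    rendering does, and applies the same decision rules as the classifier:
    activity requires a resolvable donor pife->base drop; readthrough is an
    acceptor pulse whose offset coincides with the donor loss; recycling is
    an acceptor pulse strictly after the donor loss; decomposing is donor
    loss with no acceptor pulse; acceptor darkening before any terminal
    evidence, or no terminal event inside the window, censors the trace.
    Segments shorter than ``min_segment`` frames are unresolvable and treated
    as absent.
    """
    dt = config.frame_period_s
    window_frames = int(round(config.window_s / dt))
    last_frame = window_frames - 1  # frames run 0 .. window-1 (since t0)

    qb_d = _quantize_frames(events.bleach_donor_s, dt)
    qb_a = _quantize_frames(events.bleach_acceptor_s, dt)

    def censored() -> TraceClassification:
        return TraceClassification(
            trace_id=trace_id, outcome=Label.UNCLASSIFIED,
            censored=True, replicate_id=replicate_id,
        )

    # --- donor channel: resumption and terminal loss -----------------------
    resume_f: int | None = None
    dark_f: int | None = None
    if events.outcome is not Outcome.INACTIVE:
        r = _quantize_frames(events.t_resume_s, dt)
        d = min(_quantize_frames(_donor_terminal_s(events, config), dt), qb_d)
        base_len = min(d, window_frames) - r
        if base_len >= min_segment and r <= last_frame:
            resume_f = r
            dark_len = window_frames - d
            if dark_len >= min_segment:
                dark_f = d
    if resume_f is None:
        return TraceClassification(
            trace_id=trace_id, outcome=Label.INACTIVE, replicate_id=replicate_id,
        )

    # --- acceptor channel: pulse and darkening ------------------------------
    onset_f: int | None = None
    offset_f: int | None = None
    if events.outcome in (Outcome.READTHROUGH, Outcome.RECYCLING):
        on = _quantize_frames(events.tau_e_s, dt)
        off = min(
            _quantize_frames(events.tau_e_s + config.runoff_dwell_s, dt), qb_a
        )
        visible = min(off, window_frames) - on
        if visible >= min_segment and on <= last_frame:
            onset_f = on
            offset_f = off
    acc_dark_f = qb_a if qb_a <= last_frame else None

    return _decide(
        trace_id=trace_id,
        replicate_id=replicate_id,
        dt=dt,
        t0_index=config.t0_index,
        resume_f=resume_f,
        dark_f=dark_f,
        onset_f=onset_f,
        offset_f=offset_f,
        acc_dark_f=acc_dark_f,
        window_frames=window_frames,
        tol_frames=tol_frames,
    )


def _decide(
    *,
    trace_id: str,
    replicate_id: int,
    dt: float,
    t0_index: int,
    resume_f: int,
    dark_f: int | None,
    onset_f: int | None,
    offset_f: int | None,
    acc_dark_f: int | None,
    window_frames: int,
    tol_frames: int,
) -> TraceClassification:
    """Shared decision rules on frame-resolved event times (since injection).

    Used by both the observable-truth derivation and the classifier so that
    the two agree whenever they extract the same events.  The event window
    is anchored at the resumption.  Reported event times carry a mid-frame
    (-dt/2) correction: a transition first visible on frame f happened
    somewhere in the preceding inter-frame interval, whose conditional mean
    is (f - 0.5) * dt; the raw frame time would be biased late by half a
    frame.
    """
    end_f = min(resume_f + window_frames, window_frames - 1)

    def in_window(f: int | None) -> bool:
        return f is not None and resume_f <= f <= end_f

    dark_f = dark_f if in_window(dark_f) else None
    onset_ok = in_window(onset_f)

    def censored() -> TraceClassification:
        return TraceClassification(
            trace_id=trace_id, outcome=Label.UNCLASSIFIED,
            censored=True, replicate_id=replicate_id,
        )

    # (d) acceptor goes dark before any terminal evidence
    if acc_dark_f is not None and acc_dark_f <= end_f:
        before_dark = dark_f is None or acc_dark_f <= dark_f
        before_onset = not onset_ok or acc_dark_f <= onset_f
        if before_dark and before_onset:
            return censored()
    # (e) no terminal event inside the window
    if dark_f is None:
        return censored()
    if onset_ok:
        # (a) pulse precedes donor loss and ends with it -> readthrough
        if onset_f < dark_f and offset_f is not None and abs(offset_f - dark_f) <= tol_frames:
            return TraceClassification(
                trace_id=trace_id, outcome=Label.READTHROUGH,
                tau_e_hat_s=(onset_f - 0.5) * dt, replicate_id=replicate_id,
            )
        # (c) pulse strictly after donor loss -> recycling
        if onset_f - dark_f > tol_frames:
            return TraceClassification(
                trace_id=trace_id, outcome=Label.RECYCLING,
                tau_t_hat_s=(dark_f - 0.5) * dt, replicate_id=replicate_id,
            )
        # ambiguous coincidence
        return TraceClassification(
            trace_id=trace_id, outcome=Label.UNCLASSIFIED, replicate_id=replicate_id,
        )
    # (b) donor loss with no acceptor pulse anywhere in the window
    return TraceClassification(
        trace_id=trace_id, outcome=Label.DECOMPOSING,
        tau_t_hat_s=(dark_f - 0.5) * dt, replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Mismatch-scan series
# ---------------------------------------------------------------------------

#: Template positions (bp from the transcription start) of the 3-bp
#: mismatch centers scanned across the terminator; the major termination
#: site sits at +130.
MISMATCH_POSITIONS: tuple[int, ...] = tuple(range(112, 136, 2))
TERMINATION_SITE_BP = 130


def mismatch_series(
    positions: Sequence[int] = MISMATCH_POSITIONS,
    *,
    wildtype_efficiency: float = 0.54,
    min_position: int = 120,
    min_efficiency: float = 0.19,
    width_bp: float = 4.0,
    base_config: GeneratorConfig | None = None,
    seed: int = 0,
) -> dict[int, GeneratorConfig]:
    """Per-position generator configs for a terminator mismatch scan.

    Termination probability dips from the wildtype efficiency in a Gaussian
    profile centered on ``min_position``, emulating mismatches that disrupt
    bubble rewinding most when placed just upstream of the termination
    site.  Each position gets its own derived seed.
    """
    base = base_config or GeneratorConfig()
    depth = wildtype_efficiency - min_efficiency
    if depth < 0:
        raise ValueError("min_efficiency must not exceed wildtype_efficiency")
    configs: dict[int, GeneratorConfig] = {}
    for i, pos in enumerate(positions):
        eff = wildtype_efficiency - depth * math.exp(-((pos - min_position) ** 2) / (2 * width_bp**2))
        configs[int(pos)] = replace(
            base, p_termination=float(eff), seed=(seed * 1009 + i * 7919) % (2**31)
        )
    return configs
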