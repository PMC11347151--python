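"""Trace-pattern decision rules for transcription outcomes.

A trace enters as two labeled step segmentations (donor and acceptor).  The
activity filter keeps only complexes whose donor PIFE drops to the base
level after NTP injection — those resumed elongation.  Within a 5-minute
event window anchored at each trace's resumption, the outcome patterns are:

* readthrough — an acceptor PIFE pulse starts before the donor loss and
  ends together with it (polymerase reached the labeled DNA end, then ran
  off with the labeled RNA);
* decomposing termination — the donor signal is lost with no acceptor PIFE
  anywhere in the window (RNA and DNA released at once);
* recycling termination — the acceptor PIFE starts strictly *after* the
  donor loss (RNA released first, the DNA-bound polymerase reached the end
  later);
* censored — the acceptor dye went dark before any terminal evidence, or no
  terminal event fell inside the window.

Dye bleaching and RNA release both appear as a step to dark and cannot be
distinguished per trace; because bleaching (23 / 39 min means) is slow on
the 5-min window, dark transitions inside the window are treated as events
and no statistical bleaching correction is applied.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .stepfinder import MIN_SEGMENT, StepSegmentation, detect_steps, label_levels
from .synthetic_data import DEFAULT_TOL_FRAMES, GeneratorConfig, _decide
from .trace_model import Label, Trace, TraceClassification

__all__ = [
    "activity_filter",
    "classify_trace",
    "classify_ensemble",
]

logger = logging.getLogger(__name__)


def _first_transition(
    runs: list[tuple[int, int, str]], from_label: str | None, to_label: str, after: int
) -> int | None:
    """Frame index of the first run boundary entering ``to_label``.

    ``from_label`` None accepts any predecessor label; the boundary must
    fall strictly after frame ``after``.
    """
    for i in range(1, len(runs)):
        start, _, lab = runs[i]
        prev_lab = runs[i - 1][2]
        if lab == to_label and start > after and (from_label is None or prev_lab == from_label):
            return start
    return None


def activity_filter(
    donor_seg: StepSegmentation,
    t0_index: int,
    frame_period_s: float,
    window_s: float,
) -> tuple[bool, float | None]:
    """Decide whether a complex resumed transcription.

    Active iff the donor shows a pife -> base transition after the
    injection frame and before the window end; returns the estimated
    resumption time in seconds since injection (None if inactive).
    """
    runs = donor_seg.merged_label_runs()
    window_frames = int(round(window_s / frame_period_s))
    r_abs = _first_transition(runs, "pife", "base", after=t0_index)
    if r_abs is None or (r_abs - t0_index) >= window_frames:
        return False, None
    return True, (r_abs - t0_index) * frame_period_s


def classify_trace(
    donor_seg: StepSegmentation,
    acceptor_seg: StepSegmentation,
    t0_index: int,
    window_s: float,
    frame_period_s: float,
    tol_frames: int = DEFAULT_TOL_FRAMES,
    trace_id: str = "tr00000",
    replicate_id: int = 0,
) -> TraceClassification:
    """Classify one trace from its labeled segmentations.

    Extracts the resumption, donor-loss, acceptor-pulse and acceptor-dark
    frame times from the merged label runs and applies the shared decision
    rules (the same ones the ideal-observer ground truth uses).  Estimated
    event times are reported in seconds since injection.
    """
    if donor_seg.segment_labels is None or acceptor_seg.segment_labels is None:
        raise ValueError("segmentations must be labeled before classification")

    donor_runs = donor_seg.merged_label_runs()
    window_frames = int(round(window_s / frame_period_s))
    r_abs = _first_transition(donor_runs, "pife", "base", after=t0_index)
    if r_abs is None or (r_abs - t0_index) >= window_frames:
        return TraceClassification(
            trace_id=trace_id, outcome=Label.INACTIVE, replicate_id=replicate_id
        )
    resume_f = r_abs - t0_index

    dark_abs = _first_transition(donor_runs, None, "dark", after=r_abs)
    dark_f = dark_abs - t0_index if dark_abs is not None else None

    acc_runs = acceptor_seg.merged_label_runs()
    onset_f = offset_f = None
    for start, end, lab in acc_runs:
        if lab == "pife":
            onset_f = start - t0_index
            offset_f = end - t0_index
            break
    acc_dark_abs = _first_transition(acc_runs, None, "dark", after=0)
    if acc_dark_abs is None and acc_runs and acc_runs[0][2] == "dark":
        acc_dark_abs = 0
    acc_dark_f = acc_dark_abs - t0_index if acc_dark_abs is not None else None

    return _decide(
        trace_id=trace_id,
        replicate_id=replicate_id,
        dt=frame_period_s,
        t0_index=t0_index,
        resume_f=resume_f,
        dark_f=dark_f,
        onset_f=onset_f,
        offset_f=offset_f,
        acc_dark_f=acc_dark_f,
        window_frames=window_frames,
        tol_frames=tol_frames,
    )


def classify_ensemble(
    traces: Sequence[Trace],
    config: GeneratorConfig,
    tol_frames: int = DEFAULT_TOL_FRAMES,
    replicate_ids: Sequence[int] | None = None,
) -> list[TraceClassification]:
    """Run step detection, labeling and classification on every trace.

    Deterministic; a trace that errors out is recorded as unclassified with
    the reason logged rather than aborting the ensemble.  Replicate ids
    default to the generator's round-robin assignment.
    """
    results: list[TraceClassification] = []
    for i, trace in enumerate(traces):
        rep = replicate_ids[i] if replicate_ids is not None else i % config.n_replicates
        try:
            donor_seg = label_levels(detect_steps(trace.donor), config.level_table("donor"))
            acceptor_seg = label_levels(
                detect_steps(trace.acceptor), config.level_table("acceptor")
            )
            results.append(
                classify_trace(
                    donor_seg,
                    acceptor_seg,
                    t0_index=trace.t0_index,
                    window_s=config.window_s,
                    frame_period_s=trace.frame_period_s,
                    tol_frames=tol_frames,
                    trace_id=trace.trace_id,
                    replicate_id=rep,
                )
            )
        except Exception:
            logger.exception("trace %s failed classification", trace.trace_id)
            results.append(
                TraceClassification(
                    trace_id=trace.trace_id,
                    outcome=Label.UNCLASSIFIED,
                    replicate_id=rep,
                )
            )
    return results
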