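"""Core data types and file formats for single-molecule termination traces.

A :class:`Trace` holds the two demultiplexed fluorescence channels of one
immobilized transcription complex recorded under alternating laser
excitation: donor emission under donor (green) excitation and acceptor
emission under acceptor (red) excitation, sampled on a common frame clock.
NTP injection defines time zero; frames before ``t0_index`` show the stalled
complex.

The canonical interchange format is a plain tab-separated long table (one
row per frame) with per-trace metadata carried in ``#meta`` comment lines,
so fixtures stay diffable.  Genome site tables come in as BED (0-based,
half-open) or 1-based TSV with the dialect declared, never guessed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Outcome",
    "Label",
    "Trace",
    "EventTimes",
    "TraceClassification",
    "GenomeSites",
    "TraceFormatError",
    "SiteFormatError",
    "read_traces",
    "write_traces",
    "read_sites",
    "write_sites",
]


class TraceFormatError(ValueError):
    """Raised when a trace table violates the interchange format."""


class SiteFormatError(ValueError):
    """Raised when a genome site table is malformed or mis-declared."""


class Outcome(str, Enum):
    """Latent fate of one transcription complex after NTP injection."""

    INACTIVE = "inactive"
    READTHROUGH = "readthrough"
    DECOMPOSING = "decomposing"
    RECYCLING = "recycling"


class Label(str, Enum):
    """Classifier output label (latent outcomes plus the censored bucket)."""

    INACTIVE = "inactive"
    READTHROUGH = "readthrough"
    DECOMPOSING = "decomposing"
    RECYCLING = "recycling"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Trace:
    """Two-channel intensity time series of one immobilized complex.

    Parameters
    ----------
    trace_id
        Unique identifier within an ensemble.
    frame_period_s
        Frame clock period in seconds (0.4 s in the assay this models).
    t0_index
        Frame index of NTP injection; times are reported relative to it.
    donor, acceptor
        Per-frame intensities (arbitrary units), equal length >= 2.
    """

    trace_id: str
    frame_period_s: float
    t0_index: int
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        donor = np.asarray(self.donor, dtype=float)
        acceptor = np.asarray(self.acceptor, dtype=float)
        object.__setattr__(self, "donor", donor)
        object.__setattr__(self, "acceptor", acceptor)
        if donor.ndim != 1 or acceptor.ndim != 1:
            raise TraceFormatError(f"trace {self.trace_id}: channels must be 1-D")
        if len(donor) != len(acceptor):
            raise TraceFormatError(
                f"trace {self.trace_id}: ragged channels "
                f"(donor {len(donor)} vs acceptor {len(acceptor)})"
            )
        if len(donor) < 2:
            raise TraceFormatError(f"trace {self.trace_id}: fewer than 2 frames")
        if not (self.frame_period_s > 0):
            raise TraceFormatError(f"trace {self.trace_id}: frame_period_s must be > 0")
        if not (0 <= self.t0_index < len(donor)):
            raise TraceFormatError(
                f"trace {self.trace_id}: t0_index {self.t0_index} outside trace"
            )
        if not (np.isfinite(donor).all() and np.isfinite(acceptor).all()):
            raise TraceFormatError(f"trace {self.trace_id}: non-finite intensities")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    def times_s(self) -> np.ndarray:
        """Frame times in seconds relative to NTP injection."""
        return (np.arange(self.n_frames) - self.t0_index) * self.frame_period_s

    def scaled(self, factor: float) -> "Trace":
        """Return a copy with both channels multiplied by ``factor``."""
        return replace(self, donor=self.donor * factor, acceptor=self.acceptor * factor)


@dataclass(frozen=True)
class EventTimes:
    """Ground-truth latent event schedule of one simulated complex.

    All times are seconds since NTP injection.  ``tau_e_s`` is the acceptor
    PIFE onset: the Cy5-end arrival for readthrough, and the post-release
    arrival for recycling (where it must exceed ``tau_t_s``).  ``tau_t_s``
    is the terminational RNA release and is undefined for readthrough.
    """

    outcome: Outcome
    t_resume_s: float | None
    tau_e_s: float | None
    tau_t_s: float | None
    bleach_donor_s: float
    bleach_acceptor_s: float

    def __post_init__(self) -> None:
        for name in ("t_resume_s", "tau_e_s", "tau_t_s", "bleach_donor_s", "bleach_acceptor_s"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be positive when defined, got {value}")
        if self.outcome is Outcome.READTHROUGH:
            if self.tau_t_s is not None:
                raise ValueError("readthrough defines no release time tau_t")
            if self.tau_e_s is None:
                raise ValueError("readthrough requires an arrival time tau_e")
        elif self.outcome is Outcome.DECOMPOSING:
            if self.tau_e_s is not None:
                raise ValueError("decomposing termination defines no arrival time tau_e")
            if self.tau_t_s is None:
                raise ValueError("decomposing termination requires a release time tau_t")
        elif self.outcome is Outcome.RECYCLING:
            if self.tau_e_s is None or self.tau_t_s is None:
                raise ValueError("recycling requires both tau_t and a later arrival")
            if not self.tau_e_s > self.tau_t_s:
                raise ValueError("recycling arrival must follow the RNA release")


@dataclass(frozen=True)
class TraceClassification:
    """Inferred outcome of one trace with estimated event times.

    ``censored`` marks traces whose terminal event could not be asserted
    inside the observation window (window ran out, or the acceptor dye
    bleached first); censored traces carry the ``unclassified`` label.
    """

    trace_id: str
    outcome: Label
    tau_e_hat_s: float | None = None
    tau_t_hat_s: float | None = None
    censored: bool = False
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.outcome is Label.READTHROUGH and self.tau_e_hat_s is None:
            raise ValueError("readthrough classification requires tau_e_hat")
        if self.outcome in (Label.DECOMPOSING, Label.RECYCLING) and self.tau_t_hat_s is None:
            raise ValueError("termination classification requires tau_t_hat")
        if self.censored and self.outcome is not Label.UNCLASSIFIED:
            raise ValueError("censored traces must be unclassified")


@dataclass(frozen=True)
class GenomeSites:
    """Termination and transcription start sites on one genome.

    Positions are internal 0-based base-pair coordinates.  Strand is stored
    for provenance but deliberately ignored by the distance analysis, which
    uses plain linear base-pair separation.
    """

    term_sites: tuple[tuple[int, str], ...]
    start_sites: tuple[tuple[int, str], ...]
    genome_length: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise SiteFormatError("genome_length must be positive")
        for kind, sites in (("term", self.term_sites), ("start", self.start_sites)):
            for pos, strand in sites:
                if not (0 <= pos < self.genome_length):
                    raise SiteFormatError(
                        f"{kind} site position {pos} outside genome of "
                        f"length {self.genome_length}"
                    )
                if strand not in ("+", "-", "."):
                    raise SiteFormatError(f"bad strand {strand!r}")

    @property
    def term_positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.term_sites], dtype=np.int64)

    @property
    def start_positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.start_sites], dtype=np.int64)


# ---------------------------------------------------------------------------
# Trace table I/O
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]


def write_traces(traces: Iterable[Trace], path: str | Path) -> None:
    """Write traces to the canonical long-format TSV.

    Layout: one ``#meta`` comment line per trace carrying frame_period_s and
    t0_index, a header row, then one row per frame with columns
    trace_id / frame / time_s / donor / acceptor.  Floats are written with 6
    significant digits (%.6g); a write -> read -> write cycle is
    byte-identical.
    """
    traces = list(traces)
    path = Path(path)
    with path.open("w") as fh:
        for tr in traces:
            fh.write(
                f"#meta\ttrace_id={tr.trace_id}\t"
                f"frame_period_s={tr.frame_period_s:.6g}\tt0_index={tr.t0_index}\n"
            )
        fh.write("\t".join(_TRACE_COLUMNS) + "\n")
        for tr in traces:
            times = tr.times_s()
            for i in range(tr.n_frames):
                fh.write(
                    f"{tr.trace_id}\t{i}\t{times[i]:.6g}\t"
                    f"{tr.donor[i]:.6g}\t{tr.acceptor[i]:.6g}\n"
                )


def _parse_meta_line(line: str) -> dict[str, str]:
    fields = line.rstrip("\n").split("\t")[1:]
    meta: dict[str, str] = {}
    for item in fields:
        if "=" not in item:
            raise TraceFormatError(f"malformed metadata item {item!r}")
        key, value = item.split("=", 1)
        meta[key] = value
    return meta


def read_traces(path: str | Path) -> list[Trace]:
    """Read a long-format trace TSV written by :func:`write_traces`.

    Returns one :class:`Trace` per distinct trace_id, frames sorted.  Raises
    :class:`TraceFormatError` naming the offending trace for ragged
    channels, non-monotone frames or missing metadata.
    """
    path = Path(path)
    meta: dict[str, dict[str, str]] = {}
    with path.open() as fh:
        skip = 0
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("#meta\t"):
                fields = _parse_meta_line(line)
                if "trace_id" not in fields:
                    raise TraceFormatError("metadata line without trace_id")
                meta[fields["trace_id"]] = fields
    table = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"trace_id": str})
    missing = set(_TRACE_COLUMNS) - set(table.columns)
    if missing:
        raise TraceFormatError(f"missing columns: {sorted(missing)}")
    traces: list[Trace] = []
    for trace_id, group in table.groupby("trace_id", sort=True):
        if trace_id not in meta:
            raise TraceFormatError(f"trace {trace_id}: missing #meta line")
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy()
        if len(frames) and not np.array_equal(frames, np.arange(len(frames))):
            raise TraceFormatError(f"trace {trace_id}: non-contiguous or non-monotone frames")
        donor = group["donor"].to_numpy(dtype=float)
        acceptor = group["acceptor"].to_numpy(dtype=float)
        if np.isnan(donor).any() or np.isnan(acceptor).any():
            raise TraceFormatError(f"trace {trace_id}: ragged channels (missing values)")
        m = meta[trace_id]
        try:
            frame_period_s = float(m["frame_period_s"])
            t0_index = int(m["t0_index"])
        except KeyError as exc:
            raise TraceFormatError(f"trace {trace_id}: metadata missing {exc}") from exc
        traces.append(
            Trace(
                trace_id=str(trace_id),
                frame_period_s=frame_period_s,
                t0_index=t0_index,
                donor=donor,
                acceptor=acceptor,
            )
        )
    return traces


def write_manifest(path: str | Path, payload: Mapping) -> None:
    """Write a sidecar JSON manifest (config, seed, hash) next to a trace file."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


_CLS_COLUMNS = ["trace_id", "outcome", "tau_e_hat_s", "tau_t_hat_s", "censored", "replicate_id"]


def write_classifications(
    classifications: Iterable[TraceClassification], path: str | Path
) -> None:
    """Write per-trace classifications as a TSV mirroring the type's fields."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_CLS_COLUMNS) + "\n")
        for c in classifications:
            te = "" if c.tau_e_hat_s is None else f"{c.tau_e_hat_s:.6g}"
            tt = "" if c.tau_t_hat_s is None else f"{c.tau_t_hat_s:.6g}"
            fh.write(
                f"{c.trace_id}\t{c.outcome.value}\t{te}\t{tt}\t"
                f"{int(c.censored)}\t{c.replicate_id}\n"
            )


def read_classifications(path: str | Path) -> list[TraceClassification]:
    """Read a classification TSV written by :func:`write_classifications`."""
    table = pd.read_csv(path, sep="\t", dtype={"trace_id": str})
    missing = set(_CLS_COLUMNS) - set(table.columns)
    if missing:
        raise TraceFormatError(f"missing columns: {sorted(missing)}")
    out = []
    for row in table.itertuples(index=False):
        out.append(
            TraceClassification(
                trace_id=str(row.trace_id),
                outcome=Label(row.outcome),
                tau_e_hat_s=None if pd.isna(row.tau_e_hat_s) else float(row.tau_e_hat_s),
                tau_t_hat_s=None if pd.isna(row.tau_t_hat_s) else float(row.tau_t_hat_s),
                censored=bool(row.censored),
                replicate_id=int(row.replicate_id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genome site I/O
# ---------------------------------------------------------------------------


def read_sites(
    path: str | Path,
    genome_length: int,
    *,
    dialect: str | None = None,
    circular: bool = False,
) -> GenomeSites:
    """Read termination and start sites from a BED-like or 1-based TSV file.

    The file holds both site kinds, tagged in the BED name column (or TSV
    second column) as ``term`` or ``start``.  Coordinate dialect must be
    declared, either by a leading ``#dialect=bed`` / ``#dialect=tsv1``
    comment line or the ``dialect`` argument; a file declaring neither is an
    error, never a guess.  BED is 0-based half-open (the interval start is
    the site); TSV positions are 1-based inclusive, the RegulonDB-export
    convention.  Internal representation is always 0-based.
    """
    path = Path(path)
    declared: str | None = None
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#dialect="):
                    value = line.split("=", 1)[1].strip()
                    if declared is not None and declared != value:
                        raise SiteFormatError("conflicting dialect declarations")
                    declared = value
                continue
            rows.append(line.split("\t"))
    if dialect is None:
        dialect = declared
    elif declared is not None and declared != dialect:
        raise SiteFormatError(
            f"dialect argument {dialect!r} conflicts with file declaration {declared!r}"
        )
    if dialect is None:
        raise SiteFormatError("coordinate dialect not declared (bed or tsv1)")
    if dialect not in ("bed", "tsv1"):
        raise SiteFormatError(f"unknown dialect {dialect!r}")

    term: list[tuple[int, str]] = []
    start: list[tuple[int, str]] = []
    for row in rows:
        if dialect == "bed":
            # chrom, chromStart, chromEnd, name, [score, strand]
            if len(row) < 4:
                raise SiteFormatError(f"BED row too short: {row}")
            pos = int(row[1])
            kind = row[3]
            strand = row[5] if len(row) >= 6 else "."
        else:
            # position (1-based), kind, [strand]
            if len(row) < 2:
                raise SiteFormatError(f"TSV row too short: {row}")
            pos = int(row[0]) - 1
            kind = row[1]
            strand = row[2] if len(row) >= 3 else "."
        if pos >= genome_length or pos < 0:
            raise SiteFormatError(
                f"site position {pos} outside genome of length {genome_length}"
            )
        if kind == "term":
            term.append((pos, strand))
        elif kind == "start":
            start.append((pos, strand))
        else:
            raise SiteFormatError(f"unknown site kind {kind!r} (expected term/start)")
    return GenomeSites(
        term_sites=tuple(term),
        start_sites=tuple(start),
        genome_length=genome_length,
        circular=circular,
    )


def write_sites(sites: GenomeSites, path: str | Path, *, dialect: str = "bed") -> None:
    """Write a :class:`GenomeSites` table; round-trips with :func:`read_sites`."""
    if dialect not in ("bed", "tsv1"):
        raise SiteFormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#dialect={dialect}\n")
        for kind, sites_list in (("term", sites.term_sites), ("start", sites.start_sites)):
            for pos, strand in sites_list:
                if dialect == "bed":
                    fh.write(f"genome\t{pos}\t{pos + 1}\t{kind}\t0\t{strand}\n")
                else:
                    fh.write(f"{pos + 1}\t{kind}\t{strand}\n")
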