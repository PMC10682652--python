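"""Reading, segmenting, meshing and averaging physiologic traces.

The loop construction needs one representative pressure beat and one
representative velocity beat on a common uniform time mesh.  This module
takes raw sampled channels (invasive aortic pressure, LVOT Doppler velocity
envelope, optionally ECG) together with R-peak timing and produces
ensemble-averaged beats:

    read_trace / read_digitizer  ->  SampledTrace
    detect_r_peaks               ->  R-peak times (if no annotation file)
    segment_beats                ->  per-beat relative-time segments
    mesh_beat                    ->  uniform mesh, linear interpolation
    average_beats                ->  pointwise mean on the median-duration mesh

Times are seconds throughout; within a beat time is measured from the
beat's R-peak (R-peak = t 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Channel",
    "SampledTrace",
    "Beat",
    "MeshedBeat",
    "TraceParseError",
    "TraceValidationError",
    "read_trace",
    "read_rpeaks",
    "read_digitizer",
    "write_trace",
    "detect_r_peaks",
    "segment_beats",
    "mesh_beat",
    "average_beats",
]

#: minimum R-R interval accepted (refractory period), seconds
MIN_RR_S = 0.2

#: default number of mesh points per beat; resolves 1-2 ms features at
#: typical heart rates
DEFAULT_MESH_POINTS = 256

#: minimum samples for a usable beat / mesh
MIN_BEAT_SAMPLES = 16


class Channel(str, Enum):
    """Physiologic channel identity (units are fixed per channel)."""

    PRESSURE = "pressure"  # mmHg
    VELOCITY = "velocity"  # cm/s, envelope magnitude (non-negative)
    ECG = "ecg"            # arbitrary units


class TraceParseError(ValueError):
    """A trace file contained malformed content."""


class TraceValidationError(ValueError):
    """Trace data violated a structural invariant."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SampledTrace:
    """One sampled physiologic channel with optional R-peak annotations.

    Parameters
    ----------
    channel:
        Channel identity; determines the value units and sign constraints.
    times:
        Sample times in seconds, strictly increasing.
    values:
        Sample values (mmHg for pressure, cm/s for velocity), one per time.
    r_peaks:
        ECG R-peak times in seconds, strictly increasing, all inside the
        sampled interval, consecutive intervals > 0.2 s.
    """

    channel: Channel
    times: np.ndarray
    values: np.ndarray
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "values", _as_float_array(self.values))
        object.__setattr__(self, "r_peaks", _as_float_array(self.r_peaks))
        t, v, r = self.times, self.values, self.r_peaks
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise TraceValidationError(
                "times and values must be 1-D and of equal length"
            )
        if t.size == 0:
            raise TraceValidationError("empty trace")
        if not np.all(np.diff(t) > 0):
            raise TraceValidationError("sample times must be strictly increasing")
        if self.channel is Channel.PRESSURE and not np.all(v > 0):
            raise TraceValidationError("pressure values must be strictly positive")
        if self.channel is Channel.VELOCITY and not np.all(v >= 0):
            raise TraceValidationError(
                "velocity envelope values must be non-negative"
            )
        if r.size:
            if not np.all(np.diff(r) > 0):
                raise TraceValidationError("r_peaks must be strictly increasing")
            if np.any(np.diff(r) <= MIN_RR_S):
                raise TraceValidationError(
                    f"consecutive R-R intervals must exceed {MIN_RR_S} s"
                )
            if r[0] < t[0] or r[-1] > t[-1]:
                raise TraceValidationError(
                    "r_peaks must lie within the sampled time range"
                )

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def with_r_peaks(self, r_peaks: Sequence[float]) -> "SampledTrace":
        return SampledTrace(self.channel, self.times, self.values, r_peaks)


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle with time re-expressed relative to its R-peak."""

    channel: Channel
    rel_times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "rel_times", _as_float_array(self.rel_times))
        object.__setattr__(self, "values", _as_float_array(self.values))
        t, v = self.rel_times, self.values
        if t.size != v.size:
            raise TraceValidationError("rel_times and values length mismatch")
        if t.size < MIN_BEAT_SAMPLES:
            raise TraceValidationError(
                f"a beat needs at least {MIN_BEAT_SAMPLES} samples, got {t.size}"
            )
        if t[0] != 0.0:
            raise TraceValidationError("beat rel_times must start at 0")
        if not np.all(np.diff(t) > 0):
            raise TraceValidationError("beat rel_times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.rel_times[-1])


@dataclass(frozen=True)
class MeshedBeat:
    """A beat resampled onto a uniform relative-time mesh."""

    channel: Channel
    mesh: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "channel", Channel(self.channel))
        object.__setattr__(self, "mesh", _as_float_array(self.mesh))
        object.__setattr__(self, "values", _as_float_array(self.values))
        m, v = self.mesh, self.values
        if m.size != v.size:
            raise TraceValidationError("mesh and values length mismatch")
        if m.size < MIN_BEAT_SAMPLES:
            raise TraceValidationError(f"mesh needs >= {MIN_BEAT_SAMPLES} points")
        steps = np.diff(m)
        if not np.all(steps > 0):
            raise TraceValidationError("mesh must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
            raise TraceValidationError("mesh must be uniform")

    @property
    def duration(self) -> float:
        return float(self.mesh[-1] - self.mesh[0])

    @property
    def n_points(self) -> int:
        return int(self.mesh.size)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    # comma or tab autodetected per line; whitespace tolerated around fields
    if "," in line:
        return [f.strip() for f in line.split(",")]
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return line.split()


def _parse_columns(path, n_cols: int) -> list[tuple[float, ...]]:
    """Parse a delimited numeric table, rejecting malformed rows by line number."""
    rows: list[tuple[float, ...]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < n_cols:
                raise TraceParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append(tuple(float(f) for f in fields[:n_cols]))
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # optional header line
                raise TraceParseError(
                    f"{path}: line {lineno}: non-numeric field in {fields[:n_cols]}"
                ) from None
    if not rows:
        raise TraceParseError(f"{path}: no numeric data rows found")
    return rows


def read_rpeaks(path) -> np.ndarray:
    """Read a one-column R-peak annotation file (seconds)."""
    rows = _parse_columns(path, 1)
    return np.array([r[0] for r in rows])


def read_trace(path, channel: Channel | str, r_peak_path=None) -> SampledTrace:
    """Read a two-column (time_s, value) delimited text file into a trace.

    Comma or tab delimiters are autodetected and a single header line is
    tolerated.  Sample times must already be strictly increasing: files are
    validated, never silently re-sorted.
    """
    rows = _parse_columns(path, 2)
    times = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    r_peaks = read_rpeaks(r_peak_path) if r_peak_path is not None else ()
    return SampledTrace(Channel(channel), times, values, r_peaks)


def read_digitizer(
    path,
    channel: Channel | str,
    x_calibration: tuple[float, float, float, float] | None = None,
    y_calibration: tuple[float, float, float, float] | None = None,
) -> SampledTrace:
    """Read an (x, y) point export from a plot digitizer.

    ``x_calibration = (x0, x1, t0, t1)`` maps digitizer abscissa affinely to
    seconds (x0 -> t0, x1 -> t1); ``y_calibration = (y0, y1, v0, v1)`` maps
    ordinate to channel units.  With no calibration the axes are taken as
    seconds / channel units directly.
    """
    rows = _parse_columns(path, 2)
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if x_calibration is not None:
        x0, x1, t0, t1 = x_calibration
        if x1 == x0:
            raise ValueError("degenerate x calibration (x0 == x1)")
        x = t0 + (x - x0) * (t1 - t0) / (x1 - x0)
    if y_calibration is not None:
        y0, y1, v0, v1 = y_calibration
        if y1 == y0:
            raise ValueError("degenerate y calibration (y0 == y1)")
        y = v0 + (y - y0) * (v1 - v0) / (y1 - y0)
    return SampledTrace(Channel(channel), x, y)


def write_trace(trace: SampledTrace, path, r_peak_path=None) -> None:
    """Write a trace (and optionally its R-peaks) in the two-column format."""
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")
    if r_peak_path is not None:
        with open(r_peak_path, "w") as fh:
            for r in trace.r_peaks:
                fh.write(f"{float(r)!r}\n")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(
    ecg: SampledTrace,
    refractory_s: float = MIN_RR_S,
    threshold_sd: float = 2.5,
    window_s: float = 2.0,
) -> np.ndarray:
    """Detect R-peaks as local maxima above an adaptive amplitude threshold.

    The threshold is mean + ``threshold_sd`` * SD of the rectified signal in a
    sliding window of ``window_s`` seconds; peaks closer than the refractory
    period keep only the larger one.  Intended for clean laboratory or
    synthetic signals; a manual annotation file always overrides detection.
    """
    if ecg.channel is not Channel.ECG:
        raise ValueError("detect_r_peaks expects an ECG channel trace")
    if ecg.duration < 2.0:
        raise ValueError("need at least 2 s of ECG signal")
    dt = float(np.median(np.diff(ecg.times)))
    rect = np.abs(ecg.values - np.median(ecg.values))
    half = max(1, int(round(window_s / 2 / dt)))
    n = rect.size
    csum = np.concatenate([[0.0], np.cumsum(rect)])
    csq = np.concatenate([[0.0], np.cumsum(rect**2)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    cnt = hi - lo
    mean = (csum[hi] - csum[lo]) / cnt
    var = np.maximum((csq[hi] - csq[lo]) / cnt - mean**2, 0.0)
    thresh = mean + threshold_sd * np.sqrt(var)
    distance = max(1, int(round(refractory_s / dt)))
    idx, _ = find_peaks(rect, distance=distance)
    idx = idx[rect[idx] > thresh[idx]]
    if idx.size == 0:
        raise ValueError(
            "no R-peaks detected; supply a manual R-peak annotation file"
        )
    return ecg.times[idx]


# ---------------------------------------------------------------------------
# segmentation, meshing, averaging
# ---------------------------------------------------------------------------

def segment_beats(trace: SampledTrace) -> list[Beat]:
    """Split a trace into per-beat segments, one per R-R interval.

    Each beat covers [R_i, R_{i+1}); the final partial beat after the last
    R-peak is discarded.  If no sample falls exactly on the R-peak the value
    there is linearly interpolated so every beat starts at relative time 0.
    """
    r = trace.r_peaks
    if r.size < 2:
        raise TraceValidationError("segmentation needs at least 2 R-peaks")
    beats = []
    for r0, r1 in zip(r[:-1], r[1:]):
        sel = (trace.times >= r0) & (trace.times < r1)
        t = trace.times[sel] - r0
        v = trace.values[sel]
        if t.size == 0 or t[0] > 0:
            v = np.concatenate([[np.interp(r0, trace.times, trace.values)], v])
            t = np.concatenate([[0.0], t])
        beats.append(Beat(trace.channel, t, v))
    return beats


def mesh_beat(beat: Beat, n_points: int = DEFAULT_MESH_POINTS) -> MeshedBeat:
    """Resample a beat onto ``n_points`` equally spaced relative times.

    Values are linearly interpolated over [0, duration]; the first and last
    sample values are preserved exactly.
    """
    if n_points < MIN_BEAT_SAMPLES:
        raise ValueError(f"n_points must be >= {MIN_BEAT_SAMPLES}")
    if beat.duration <= 0:
        raise TraceValidationError("beat duration must be positive")
    mesh = np.linspace(0.0, beat.duration, n_points)
    values = np.interp(mesh, beat.rel_times, beat.values)
    return MeshedBeat(beat.channel, mesh, values)


def average_beats(beats: Sequence[MeshedBeat], expected_n: int = 20) -> MeshedBeat:
    """Pointwise ensemble average of meshed beats.

    Beats of unequal duration are time-normalized to the median beat duration
    before averaging (sample values are untouched; only the mesh is rescaled),
    then averaged mesh-point by mesh-point.  Fewer than ``expected_n`` beats
    triggers a warning, never an error.
    """
    if len(beats) == 0:
        raise ValueError("need at least one beat to average")
    channels = {b.channel for b in beats}
    if len(channels) > 1:
        raise TraceValidationError(f"mixed channels in average: {channels}")
    sizes = {b.n_points for b in beats}
    if len(sizes) > 1:
        raise TraceValidationError(f"mixed mesh sizes in average: {sizes}")
    if len(beats) < expected_n:
        warnings.warn(
            f"averaging {len(beats)} beats; {expected_n} are customary",
            stacklevel=2,
        )
    duration = float(np.median([b.duration for b in beats]))
    mesh = np.linspace(0.0, duration, beats[0].n_points)
    values = np.mean([b.values for b in beats], axis=0)
    return MeshedBeat(beats[0].channel, mesh, values)
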