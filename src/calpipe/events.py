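"""Baseline estimation and calcium-event calling on single-cell traces.

The baseline is an iteratively reweighted polynomial upper-envelope clip:
fit a low-degree polynomial, replace samples above the fit by the fitted
value, and refit until the coefficients stabilize. Transients bias an
ordinary fit upward; clipping them out leaves the quiescent fluorescence
level. Events are maximal runs of frames whose relative distance to the
baseline, (F - B)/B, exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import CellTrace

__all__ = [
    "Baseline",
    "SignalEvent",
    "estimate_baseline",
    "detect_events",
    "event_frame_labels",
    "events_to_frame",
    "events_from_frame",
]


@dataclass(frozen=True)
class Baseline:
    """Estimated quiescent-fluorescence curve for one trace."""

    B: np.ndarray
    degree: int
    iterations: int
    converged: bool
    method: str = "iterative-polynomial"


@dataclass(frozen=True)
class SignalEvent:
    """A contiguous supra-baseline excursion.

    Frames are 0-based and inclusive; duration is
    ``(end - start + 1) * frame_interval_s``, so a single-frame event at a
    5 s interval has duration 5 s.
    """

    cell_id: int
    start_frame: int
    end_frame: int
    duration_s: float
    peak_rel_amplitude: float

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("event start after end")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def overlaps(self, other: "SignalEvent") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame

    def overlap_frames(self, other: "SignalEvent") -> int:
        return max(
            0, min(self.end_frame, other.end_frame) - max(self.start_frame, other.start_frame) + 1
        )


def estimate_baseline(
    trace: CellTrace, degree: int = 3, max_iter: int = 100, tol: float = 1e-3
) -> Baseline:
    """Iterative polynomial baseline with upper-envelope clipping.

    Each iteration fits a degree-``degree`` polynomial to the working copy
    of the trace, then rebuilds the working copy by clipping the *original*
    trace at the fit plus one standard deviation of the residuals; iteration
    stops when the relative coefficient change falls below ``tol``. The
    residual-scaled clip level keeps quiescent samples in the fit (a plain
    clip-to-fit ratchets the baseline toward the lower noise envelope and
    dips at the trace ends), while transients well above the noise are still
    excluded. A constant trace returns that constant; non-convergence
    returns the last iterate flagged ``converged=False``.
    """
    y = np.asarray(trace.F, dtype=np.float64)
    n = len(y)
    if degree >= n:
        raise ValueError(f"degree {degree} must be < trace length {n}")
    if np.ptp(y) == 0:
        return Baseline(np.full(n, y[0]), degree, 0, True)
    # scaled domain for numerical conditioning
    x = np.linspace(-1.0, 1.0, n)
    work = y.copy()
    coeffs = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_coeffs = np.polynomial.polynomial.polyfit(x, work, degree)
        fitted = np.polynomial.polynomial.polyval(x, new_coeffs)
        dev = float(np.std(work - fitted))
        work = np.minimum(y, fitted + dev)
        if coeffs is not None:
            scale = max(float(np.abs(coeffs).max()), 1e-12)
            if float(np.abs(new_coeffs - coeffs).max()) < tol * scale:
                coeffs = new_coeffs
                converged = True
                break
        coeffs = new_coeffs
    B = np.polynomial.polynomial.polyval(x, coeffs)
    return Baseline(B, degree, it, converged)


def _runs_from_marks(marks: np.ndarray, min_frames: int, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal marked runs, merged across gaps <= merge_gap, then length-filtered."""
    idx = np.flatnonzero(marks)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for k in idx[1:]:
        k = int(k)
        if k - prev - 1 <= merge_gap:
            prev = k
        else:
            runs.append((start, prev))
            start = prev = k
    runs.append((start, prev))
    return [(s, e) for s, e in runs if e - s + 1 >= min_frames]


def detect_events(
    trace: CellTrace,
    baseline: Baseline,
    rel_threshold: float = 0.25,
    min_frames: int = 1,
    merge_gap: int = 0,
) -> list[SignalEvent]:
    """Call events where (F - B)/B strictly exceeds ``rel_threshold``.

    Marked frames are merged across gaps of at most ``merge_gap`` unmarked
    frames; runs shorter than ``min_frames`` are discarded. Durations are
    reported in seconds as exact multiples of the frame interval.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be positive")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    F = np.asarray(trace.F, dtype=np.float64)
    B = np.asarray(baseline.B, dtype=np.float64)
    if len(F) != len(B):
        raise ValueError("trace and baseline lengths differ")
    if np.any(B <= 0):
        raise AssertionError("baseline must be strictly positive after the epsilon floor")
    rel = (F - B) / B
    marks = rel > rel_threshold
    events = []
    for s, e in _runs_from_marks(marks, min_frames, merge_gap):
        events.append(
            SignalEvent(
                cell_id=trace.cell_id,
                start_frame=s,
                end_frame=e,
                duration_s=(e - s + 1) * trace.frame_interval_s,
                peak_rel_amplitude=float(rel[s : e + 1].max()),
            )
        )
    return events


def event_frame_labels(trace_length: int, events: list[SignalEvent]) -> np.ndarray:
    """Boolean per-frame indicator: True exactly inside events."""
    out = np.zeros(trace_length, dtype=bool)
    for ev in sorted(events, key=lambda e: e.start_frame):
        if out[ev.start_frame : ev.end_frame + 1].any():
            raise AssertionError("events overlap")
        out[ev.start_frame : ev.end_frame + 1] = True
    return out


def events_to_frame(events: list[SignalEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.cell_id, e.start_frame, e.end_frame, e.duration_s, e.peak_rel_amplitude)
            for e in events
        ],
        columns=["cell_id", "start_frame", "end_frame", "duration_s", "peak_rel_amplitude"],
    )


def events_from_frame(df: pd.DataFrame) -> list[SignalEvent]:
    return [
        SignalEvent(int(r.cell_id), int(r.start_frame), int(r.end_frame),
                    float(r.duration_s), float(r.peak_rel_amplitude))
        for r in df.itertuples()
    ]
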