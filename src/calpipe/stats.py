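"""Summary analyses: basal-intensity variability, event durations, and
control-based false-discovery-rate estimation.

Basal fluorescence is the per-cell mean over frames outside detected
events; its standard deviation on a log scale is scale-free, so
heterogeneity of a biosensor sample can be compared directly against an
inert-fluorophore control. The control also calibrates the detector: every
event called in an inert fluorophore is a false positive, giving an
empirical false-discovery-rate estimate for the biosensor sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import SignalEvent
from .simulator import TrueEvent
from .traces import CellTrace

__all__ = [
    "BasalSummary",
    "FdrInputs",
    "MatchResult",
    "basal_intensity",
    "log_sd",
    "percent_difference",
    "duration_fractions",
    "estimate_fdr",
    "match_events",
    "basal_summary",
]


class UndefinedStatisticError(ValueError):
    """A statistic's preconditions (non-empty input, positive values) failed."""


@dataclass(frozen=True)
class BasalSummary:
    """Per-sample basal-intensity variability on the log scale."""

    sample: str
    basal_means: np.ndarray
    sigma_log: float
    log_base: str = "natural"


@dataclass(frozen=True)
class FdrInputs:
    """Event and cell counts for control-based FDR estimation."""

    n_control_events: int
    n_control_cells: int
    n_signal_events: int
    n_signal_cells: int

    def __post_init__(self) -> None:
        if self.n_control_cells <= 0 or self.n_signal_cells <= 0:
            raise ValueError("cell counts must be positive")
        if self.n_control_events < 0 or self.n_signal_events < 0:
            raise ValueError("event counts must be non-negative")


@dataclass(frozen=True)
class MatchResult:
    precision: float
    recall: float
    n_true_positive: int
    n_detected: int
    n_truth: int
    precision_defined: bool = True


def basal_intensity(trace: CellTrace, event_indicator: np.ndarray) -> float:
    """Mean fluorescence over frames outside detected events."""
    indicator = np.asarray(event_indicator, dtype=bool)
    if len(indicator) != trace.n_frames:
        raise ValueError("indicator length must match trace length")
    quiet = ~indicator
    if not quiet.any():
        raise UndefinedStatisticError(
            f"cell {trace.cell_id}: every frame lies inside an event; basal undefined"
        )
    return float(np.asarray(trace.F)[quiet].mean())


def log_sd(basal_means: np.ndarray) -> float:
    """Sample standard deviation (n-1) of natural-log basal intensities.

    Scale-free: multiplying all intensities by a constant leaves it
    unchanged, so samples with different expression scales compare directly.
    """
    vals = np.asarray(basal_means, dtype=np.float64)
    if vals.size < 2:
        raise UndefinedStatisticError("need at least 2 basal means")
    bad = np.flatnonzero(vals <= 0)
    if bad.size:
        raise UndefinedStatisticError(f"non-positive basal mean at index {int(bad[0])}")
    return float(np.std(np.log(vals), ddof=1))


def percent_difference(sigma_signal: float, sigma_control: float) -> float:
    """100 * (sigma_signal - sigma_control) / sigma_control, rounded to nearest %."""
    if sigma_control == 0:
        raise UndefinedStatisticError("control sigma is zero")
    return float(round(100.0 * (sigma_signal - sigma_control) / sigma_control))


def duration_fractions(
    events: list[SignalEvent], thresholds_s: list[float], frame_interval_s: float = 5.0
) -> dict:
    """Survival fractions of event durations, plus the single-frame fraction.

    For each threshold d: fraction of events with duration >= d seconds.
    """
    if not events:
        raise UndefinedStatisticError("no events: duration fractions undefined")
    durations = np.array([e.duration_s for e in events])
    fractions = {float(d): float(np.mean(durations >= d)) for d in thresholds_s}
    single = float(np.mean(np.isclose(durations, frame_interval_s)))
    return {"fractions": fractions, "single_frame_fraction": single,
            "n_events": len(events)}


def estimate_fdr(inputs: FdrInputs) -> dict:
    """Control-based FDR: ratio of per-cell event rates, control vs signal.

    Returns the rate-ratio estimate plus the raw event-count ratio as a
    secondary statistic (both coincide when cell counts are equal).
    """
    if inputs.n_signal_events <= 0:
        raise UndefinedStatisticError("zero signal events: FDR undefined")
    control_rate = inputs.n_control_events / inputs.n_control_cells
    signal_rate = inputs.n_signal_events / inputs.n_signal_cells
    fdr = control_rate / signal_rate
    raw = inputs.n_control_events / inputs.n_signal_events
    return {"fdr": float(fdr), "raw_event_ratio": float(raw),
            "control_rate_per_cell": float(control_rate),
            "signal_rate_per_cell": float(signal_rate)}


def _as_interval(ev) -> tuple[int, int, int]:
    if isinstance(ev, SignalEvent):
        return ev.cell_id, ev.start_frame, ev.end_frame
    if isinstance(ev, TrueEvent):
        return ev.cell_id, ev.start_frame, ev.end_frame
    cid, s, e = ev
    return int(cid), int(s), int(e)


def match_events(detected: list, truth: list) -> MatchResult:
    """One-to-one overlap matching of detected against true events.

    A detection matches a same-cell truth interval it overlaps; pairs are
    matched greedily by decreasing overlap length with deterministic
    tie-breaking (earlier truth start, then earlier detection start). With
    no detections, precision is reported as 1 by convention and flagged.
    """
    det = [_as_interval(e) for e in detected]
    tru = [_as_interval(e) for e in truth]
    pairs = []
    for i, (cd, sd, ed) in enumerate(det):
        for j, (ct, st, et) in enumerate(tru):
            if cd != ct:
                continue
            ov = min(ed, et) - max(sd, st) + 1
            if ov > 0:
                pairs.append((ov, st, sd, j, i))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3], p[4]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for ov, st, sd, j, i in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    precision_defined = len(det) > 0
    precision = tp / len(det) if det else 1.0
    recall = tp / len(tru) if tru else 1.0
    return MatchResult(precision, recall, tp, len(det), len(tru), precision_defined)


def map_tracks_to_truth(tracks, truth, max_dist_px: float = 5.0) -> dict[int, int]:
    """Map track ids to simulated cell ids by mean-position proximity.

    Greedy one-to-one assignment by increasing distance; pairs farther than
    ``max_dist_px`` stay unassigned. Used to benchmark detected events
    against ground truth, whose cell ids need not equal track ids.
    """
    truth_centers = truth.positions.mean(axis=1)  # (n_cells, 2)
    pairs = []
    for tr in tracks:
        pos = np.array([[d.row, d.col] for d in tr.detections]).mean(axis=0)
        d = np.hypot(*(truth_centers - pos).T)
        for j in np.argsort(d):
            if d[j] <= max_dist_px:
                pairs.append((float(d[j]), tr.id, int(truth.cell_ids[j])))
    pairs.sort()
    used_tracks: set[int] = set()
    used_cells: set[int] = set()
    mapping: dict[int, int] = {}
    for dist, tid, cid in pairs:
        if tid in used_tracks or cid in used_cells:
            continue
        mapping[tid] = cid
        used_tracks.add(tid)
        used_cells.add(cid)
    return mapping


def relabel_events(events: list, mapping: dict[int, int]) -> list:
    """Rewrite event cell ids through a track→truth mapping, dropping unmapped."""
    out = []
    for e in events:
        cid, s, en = _as_interval(e)
        if cid in mapping:
            out.append((mapping[cid], s, en))
    return out


def basal_summary(
    traces: list[CellTrace], indicators: dict[int, np.ndarray], sample: str
) -> BasalSummary:
    """Per-cell basal means and their log-scale standard deviation."""
    means = np.array(
        [basal_intensity(tr, indicators[tr.cell_id]) for tr in traces]
    )
    return BasalSummary(sample, means, log_sd(means))


def duration_histogram(
    events: list[SignalEvent], frame_interval_s: float = 5.0, max_plot_s: float = 125.0
) -> pd.DataFrame:
    """Duration histogram with bin edges at multiples of the frame interval.

    ``plotted`` marks events within the plotting range; extreme outliers
    beyond ``max_plot_s`` are excluded from plots but retained in statistics.
    """
    durations = np.array([e.duration_s for e in events])
    if durations.size == 0:
        return pd.DataFrame(columns=["duration_s", "count", "plotted"])
    bins = np.arange(frame_interval_s, durations.max() + frame_interval_s, frame_interval_s)
    counts = {b: int(np.sum(np.isclose(durations, b))) for b in bins}
    return pd.DataFrame(
        {
            "duration_s": list(counts),
            "count": list(counts.values()),
            "plotted": [b <= max_plot_s for b in counts],
        }
    )
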