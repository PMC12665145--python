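"""Single-cell fluorescence trace extraction and background correction.

The label masks produced by tracking (one per averaged block) are applied to
the bleach-corrected green channel at raw-frame resolution: raw frame ``t``
uses the mask of block ``floor(t / block)``, so event durations stay
measurable at the acquisition interval. Background is estimated from a
recording with no green fluorophore and subtracted (stray light and
autofluorescence are additive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTrace",
    "TraceExtractionError",
    "extract_traces",
    "estimate_background",
    "subtract_background",
    "traces_to_frame",
    "traces_from_frame",
]

# relative floor applied after background subtraction so downstream
# baseline ratios stay defined
EPS_FLOOR_REL = 1e-6


class TraceExtractionError(RuntimeError):
    """A mask label had no pixels in some block."""


@dataclass
class CellTrace:
    """One cell's green fluorescence over raw frames."""

    cell_id: int
    F: np.ndarray
    frame_interval_s: float
    background_corrected: bool = False
    floored_frames: int = 0

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.F)) * self.frame_interval_s

    @property
    def n_frames(self) -> int:
        return len(self.F)


def extract_traces(green: np.ndarray, masks: np.ndarray, block: int = 5,
                   frame_interval_s: float = 5.0) -> list[CellTrace]:
    """Mean green intensity per labeled cell per raw frame.

    ``F[t]`` averages the pixels labeled with the cell id in the mask of
    block ``floor(t/block)``; raw frames beyond the last full block are
    dropped, mirroring the block averaging of the nuclear channel.
    """
    green = np.asarray(green, dtype=np.float64)
    masks = np.asarray(masks)
    labels = np.unique(masks)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise TraceExtractionError("mask sequence contains no labels")
    n_blocks = masks.shape[0]
    n_frames = min(green.shape[0], n_blocks * block)
    n_frames = (n_frames // block) * block
    out = {int(lab): np.empty(n_frames) for lab in labels}
    for b in range(n_frames // block):
        mask = masks[b]
        present = np.unique(mask)
        for lab in labels:
            if lab not in present:
                raise TraceExtractionError(f"label {int(lab)} has no pixels in block {b}")
        # per-frame labeled means via bincount (fast and exact)
        flat_mask = mask.ravel()
        counts = np.bincount(flat_mask, minlength=int(labels.max()) + 1)
        for t in range(b * block, (b + 1) * block):
            sums = np.bincount(flat_mask, weights=green[t].ravel(),
                               minlength=int(labels.max()) + 1)
            for lab in labels:
                out[int(lab)][t] = sums[lab] / counts[lab]
    return [CellTrace(cid, out[cid], frame_interval_s) for cid in sorted(out)]


def estimate_background(background_green: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-frame spatial mean of a no-fluorophore green stack, plus its time average."""
    stack = np.asarray(background_green, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] == 0 or stack.shape[1] * stack.shape[2] == 0:
        raise ValueError("need a non-empty T×H×W stack")
    per_frame = stack.mean(axis=(1, 2))
    return per_frame, float(per_frame.mean())


def subtract_background(
    traces: list[CellTrace], background: float | np.ndarray
) -> list[CellTrace]:
    """Subtract a scalar or per-frame background, flooring at a small epsilon.

    The floor is ``EPS_FLOOR_REL`` times the trace maximum, keeping
    downstream (F - B)/B ratios defined for cells at background level; the
    number of floored frames is recorded on each trace.
    """
    out = []
    for tr in traces:
        bg = np.asarray(background, dtype=np.float64)
        if bg.ndim == 0:
            bg = np.full(tr.n_frames, float(bg))
        elif len(bg) < tr.n_frames:
            raise ValueError(
                f"background length {len(bg)} < trace length {tr.n_frames}"
            )
        else:
            bg = bg[: tr.n_frames]
        corrected = tr.F - bg
        eps = EPS_FLOOR_REL * max(float(tr.F.max()), 1.0)
        floored = int(np.sum(corrected < eps))
        corrected = np.maximum(corrected, eps)
        out.append(
            CellTrace(tr.cell_id, corrected, tr.frame_interval_s,
                      background_corrected=True, floored_frames=floored)
        )
    return out


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Long-format trace table: cell_id, frame, time_s, F."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "F": tr.F,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(df: pd.DataFrame, frame_interval_s: float | None = None,
                      background_corrected: bool = True) -> list[CellTrace]:
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        dt = frame_interval_s
        if dt is None:
            t = grp["time_s"].to_numpy()
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        out.append(CellTrace(int(cid), grp["F"].to_numpy(dtype=float), dt,
                             background_corrected=background_corrected))
    return out
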