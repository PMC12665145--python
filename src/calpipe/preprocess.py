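"""Photobleaching correction and temporal block averaging.

Photobleaching is modelled on the per-frame spatial mean trace as
``I(t) = A * exp(-t / tau) + C`` and corrected multiplicatively, so the
relative amplitude of calcium transients is preserved. The nuclear channel
is additionally averaged over non-overlapping blocks of frames (default 5)
to raise signal-to-noise before spot detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BleachFit", "BleachFitError", "fit_bleach", "correct_bleach", "block_average",
           "block_index_map"]


class BleachFitError(RuntimeError):
    """Exponential fit failed to converge or produced a non-physical decay."""


@dataclass(frozen=True)
class BleachFit:
    """Fitted exponential photobleaching model for one channel.

    ``identity`` marks degenerate inputs (no measurable decay) for which the
    correction is a no-op.
    """

    amplitude: float
    tau_s: float
    offset: float
    frame_interval_s: float
    n_frames: int
    residual_rms: float
    channel: str = ""
    identity: bool = False

    def factors(self, n_frames: int | None = None) -> np.ndarray:
        """Multiplicative per-frame correction factors (A+C)/(A e^{-t/tau}+C)."""
        n = self.n_frames if n_frames is None else n_frames
        if self.identity:
            return np.ones(n)
        t = np.arange(n) * self.frame_interval_s
        model = self.amplitude * np.exp(-t / self.tau_s) + self.offset
        return (self.amplitude + self.offset) / model

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BleachFit":
        return cls(**json.loads(text))


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_bleach(stack: np.ndarray, frame_interval_s: float, channel: str = "") -> BleachFit:
    """Least-squares exponential fit to the per-frame spatial mean intensity.

    Degenerate stacks (no decay trend, e.g. a constant movie) return a fit
    flagged ``identity=True`` whose correction is a no-op rather than
    raising. A converged fit with non-positive tau raises
    :class:`BleachFitError`.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 4:
        raise ValueError("need a T×H×W stack with at least 4 frames")
    means = stack.mean(axis=(1, 2))
    t = np.arange(len(means)) * frame_interval_s

    total_span = means.max() - means.min()
    if total_span <= 1e-12 * max(abs(means).max(), 1.0):
        # flat movie: nothing to correct
        return BleachFit(0.0, float("inf"), float(means[0]), frame_interval_s,
                         len(means), 0.0, channel, identity=True)

    # initial guess from the endpoints
    c0 = float(means[-5:].mean())
    a0 = float(means[0] - c0)
    if abs(a0) < 1e-12:
        a0 = total_span
    tau0 = t[-1] / 3.0 if t[-1] > 0 else frame_interval_s
    try:
        popt, _ = curve_fit(
            _exp_model, t, means, p0=(a0, tau0, c0),
            bounds=([-np.inf, frame_interval_s * 1e-3, -np.inf],
                    [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise BleachFitError(f"exponential fit did not converge: {exc}") from exc
    a, tau, c = (float(v) for v in popt)
    if tau <= 0:
        raise BleachFitError(f"fitted tau {tau:.3g} s is non-positive")
    resid = means - _exp_model(t, a, tau, c)
    rms = float(np.sqrt(np.mean(resid**2)))
    # decay indistinguishable from flat, or correction would be negligible:
    # treat as identity to avoid amplifying noise
    if abs(a) <= 1e-9 * max(abs(c), 1.0):
        return BleachFit(a, tau, c, frame_interval_s, len(means), rms, channel, identity=True)
    return BleachFit(a, tau, c, frame_interval_s, len(means), rms, channel)


def correct_bleach(stack: np.ndarray, fit: BleachFit) -> np.ndarray:
    """Rescale each frame so the fitted mean stays at its t=0 value.

    Multiplicative correction: frame t is multiplied by
    ``(A + C) / (A exp(-t dt / tau) + C)``; output is clipped at 0 and never
    reorders pixel intensities within a frame.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("need a T×H×W stack")
    if stack.shape[0] != fit.n_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames but fit was made on {fit.n_frames}"
        )
    if fit.identity:
        return stack.copy()
    out = stack * fit.factors()[:, None, None]
    return np.clip(out, 0.0, None)


def block_average(stack: np.ndarray, block: int = 5) -> np.ndarray:
    """Average non-overlapping blocks of consecutive frames.

    Output has ``floor(T/block)`` frames; remainder frames are dropped.
    """
    if block <= 0:
        raise ValueError("block must be a positive integer")
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < block:
        raise ValueError("need a T×H×W stack with T >= block")
    n_blocks = stack.shape[0] // block
    trimmed = stack[: n_blocks * block]
    return trimmed.reshape(n_blocks, block, *stack.shape[1:]).mean(axis=1)


def block_index_map(n_frames: int, block: int = 5) -> np.ndarray:
    """Block index for every raw frame; -1 for dropped remainder frames."""
    if block <= 0:
        raise ValueError("block must be a positive integer")
    idx = np.arange(n_frames) // block
    idx[idx >= n_frames // block] = -1
    return idx


def write_fit(fit: BleachFit, path: str | Path) -> None:
    Path(path).write_text(fit.to_json())
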