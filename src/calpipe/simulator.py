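"""Ground-truthed synthetic two-channel calcium-imaging movies.

Emulates *ex vivo* time-lapse recordings of *Drosophila* lymph gland
prohemocytes carrying a nuclear mCherry marker (red channel) and either an
intensiometric calcium biosensor such as jGCaMP8s (signal mode) or an inert
fluorophore such as EGFP (control mode) in the green channel.

The generated movies contain, per cell, a drifting Gaussian nucleus, a
log-normal expression level, and (in signal mode) sparse boxcar calcium
transients, on top of global exponential photobleaching, an additive
background, and Gaussian pixel noise. Every stochastic choice is recorded in
a :class:`GroundTruth` object so downstream stages can be benchmarked
against known truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TrueEvent",
    "TwoChannelMovie",
    "PlacementError",
    "simulate_movie",
    "simulate_background_movie",
    "write_movie",
    "write_ground_truth",
    "read_ground_truth",
]

UINT16_MAX = 65535


class PlacementError(ValueError):
    """Raised when the requested cell count cannot be placed without overlap."""


@dataclass(frozen=True)
class TwoChannelMovie:
    """Paired red (nuclear marker) and green (biosensor) intensity stacks.

    Both stacks are T×H×W and share dimensions; ``frame_interval_s`` is the
    acquisition interval between consecutive frames.
    """

    red: np.ndarray
    green: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape} vs green {self.green.shape}"
            )
        if self.red.ndim != 3:
            raise ValueError("stacks must be T×H×W")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def image_size(self) -> tuple[int, int]:
        return self.red.shape[1], self.red.shape[2]


@dataclass(frozen=True)
class TrueEvent:
    """One simulated calcium transient: inclusive frame interval + amplitude."""

    cell_id: int
    start_frame: int
    end_frame: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("event start after end")


@dataclass
class GroundTruth:
    """Simulator record used only by tests and benchmarks.

    ``positions`` has shape (n_cells, T, 2) in (row, col) pixel coordinates;
    ``expression`` is the per-cell green intensity multiplier,
    ``red_expression`` the red-channel one.
    """

    cell_ids: np.ndarray
    positions: np.ndarray
    expression: np.ndarray
    red_expression: np.ndarray
    events: list[TrueEvent]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def events_for_cell(self, cell_id: int) -> list[TrueEvent]:
        return [e for e in self.events if e.cell_id == cell_id]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic recording.

    Defaults reproduce the imaging design of the emulated experiment: a
    15-minute movie at 5 s between frames (180 frames), nuclei a few pixels
    across, strong per-cell log-normal expression heterogeneity
    (``expression_log_sd``), and a handful of transients per cell.
    """

    n_cells: int = 20
    frames: int = 180
    frame_interval_s: float = 5.0
    image_size: tuple[int, int] = (256, 256)
    nucleus_radius_px: float = 4.0
    drift_step_px: float = 0.1
    expression_log_mean: float = 7.0
    expression_log_sd: float = 1.7
    red_log_mean: float = 6.0
    red_log_sd: float = 0.2
    event_rate_per_cell_per_movie: float = 3.0
    event_duration_dist: str = "geometric"
    event_duration_params: dict = field(default_factory=lambda: {"p": 0.3})
    event_rel_amplitude: float = 1.0
    bleach_tau_red_s: float = 1800.0
    bleach_tau_green_s: float = 1800.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    control_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.frames <= 0:
            raise ValueError("n_cells and frames must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if self.bleach_tau_red_s <= 0 or self.bleach_tau_green_s <= 0:
            raise ValueError("bleach time constants must be positive (use inf to disable)")
        if self.event_duration_dist not in ("geometric", "fixed"):
            raise ValueError(f"unknown event duration distribution {self.event_duration_dist!r}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)


# footprint of the green (whole-cell) signal relative to the nuclear radius:
# the nuclear trace carries "some surrounding cytoplasmic signal"
GREEN_FOOTPRINT_FACTOR = 1.5
# Gaussian blobs are truncated at this many radii
TRUNCATION_RADII = 3.0
PLACEMENT_JITTER_PX = 1.0
# extra clearance absorbing random-walk drift over a movie
DRIFT_MARGIN_PX = 4.0
# border margin, in nuclear radii: truncation radius plus room for the
# detector's filter support, so edge reflections cannot bias localization
BORDER_MARGIN_RADII = TRUNCATION_RADII + 2.0


def _blob_sigma(radius_px: float) -> float:
    # a Gaussian of std sigma is detected by a scale-normalized LoG at
    # scale sigma; radius = sigma*sqrt(2) matches the detector convention
    return radius_px / math.sqrt(2.0)


def _place_cells(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Place cell centers on a jittered grid with guaranteed clearance."""
    h, w = config.image_size
    margin = BORDER_MARGIN_RADII * config.nucleus_radius_px
    # separation ensuring a neighbor's truncated green footprint can never
    # reach this cell's nucleus-sized measurement region, even after drift:
    # expression spans orders of magnitude, so any bleed-through from a
    # bright neighbor would swamp a dim cell's own signal
    green_trunc = TRUNCATION_RADII * GREEN_FOOTPRINT_FACTOR * config.nucleus_radius_px
    min_sep = green_trunc + config.nucleus_radius_px + DRIFT_MARGIN_PX
    n = config.n_cells
    if n == 1:
        return np.array([[h / 2.0, w / 2.0]])
    per_side = math.ceil(math.sqrt(n))
    lo = margin + PLACEMENT_JITTER_PX
    hi_h = (h - 1) - margin - PLACEMENT_JITTER_PX
    hi_w = (w - 1) - margin - PLACEMENT_JITTER_PX
    spacing = min(hi_h - lo, hi_w - lo) / (per_side - 1)
    if spacing < min_sep + 2 * PLACEMENT_JITTER_PX:
        raise PlacementError(
            f"cannot place {n} cells of radius {config.nucleus_radius_px} px in a "
            f"{h}x{w} image without overlap (grid spacing {spacing:.1f} px < "
            f"required {min_sep + 2 * PLACEMENT_JITTER_PX:.1f} px)"
        )
    rows = lo + spacing * np.arange(per_side)
    cols = lo + spacing * np.arange(per_side)
    grid = np.array([(r, c) for r in rows for c in cols])
    idx = rng.permutation(len(grid))[:n]
    centers = grid[idx]
    centers = centers + rng.uniform(-PLACEMENT_JITTER_PX, PLACEMENT_JITTER_PX, size=centers.shape)
    return centers


def _random_walk(
    centers0: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell Gaussian random walk, reflected at a safety margin."""
    h, w = config.image_size
    margin = BORDER_MARGIN_RADII * config.nucleus_radius_px
    n, t = len(centers0), config.frames
    pos = np.empty((n, t, 2))
    pos[:, 0] = centers0
    steps = rng.normal(0.0, config.drift_step_px, size=(n, t - 1, 2)) if t > 1 else None
    lo = np.array([margin, margin])
    hi = np.array([h - 1 - margin, w - 1 - margin])
    for k in range(1, t):
        nxt = pos[:, k - 1] + steps[:, k - 1]
        # reflect at the margins
        nxt = np.where(nxt < lo, 2 * lo - nxt, nxt)
        nxt = np.where(nxt > hi, 2 * hi - nxt, nxt)
        pos[:, k] = nxt
    return pos


def _draw_duration(config: SimConfig, rng: np.random.Generator) -> int:
    if config.event_duration_dist == "fixed":
        return int(config.event_duration_params["frames"])
    p = float(config.event_duration_params["p"])
    return int(rng.geometric(p))


def _draw_events(config: SimConfig, rng: np.random.Generator) -> list[TrueEvent]:
    """Sparse non-overlapping boxcar transients, uniform start times.

    Events of one cell are kept ≥2 frames apart so they remain distinct at
    the detector's resolution.
    """
    if config.control_mode:
        return []
    events: list[TrueEvent] = []
    for cid in range(1, config.n_cells + 1):
        n_ev = rng.poisson(config.event_rate_per_cell_per_movie)
        occupied: list[tuple[int, int]] = []
        for _ in range(n_ev):
            dur = min(_draw_duration(config, rng), config.frames)
            for _attempt in range(50):
                start = int(rng.integers(0, config.frames - dur + 1))
                end = start + dur - 1
                if all(end < s - 2 or start > e + 2 for s, e in occupied):
                    occupied.append((start, end))
                    events.append(TrueEvent(cid, start, end, config.event_rel_amplitude))
                    break
    events.sort(key=lambda e: (e.cell_id, e.start_frame))
    return events


def _render_blob(
    frame: np.ndarray, center: tuple[float, float], sigma: float, radius: float, amplitude: float
) -> None:
    """Add a truncated isotropic Gaussian to ``frame`` in place."""
    h, w = frame.shape
    r0 = max(int(math.floor(center[0] - radius)), 0)
    r1 = min(int(math.ceil(center[0] + radius)) + 1, h)
    c0 = max(int(math.floor(center[1] - radius)), 0)
    c1 = min(int(math.ceil(center[1] + radius)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - center[0]
    cc = np.arange(c0, c1)[None, :] - center[1]
    d2 = rr * rr + cc * cc
    patch = amplitude * np.exp(-d2 / (2.0 * sigma * sigma))
    patch[d2 > radius * radius] = 0.0
    frame[r0:r1, c0:c1] += patch


def _bleach_factors(config: SimConfig, tau_s: float) -> np.ndarray:
    t = np.arange(config.frames) * config.frame_interval_s
    if math.isinf(tau_s):
        return np.ones(config.frames)
    return np.exp(-t / tau_s)


def _finalize(stack: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(stack), 0, UINT16_MAX).astype(np.uint16)


def _render_movie(
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
    green_expressing: bool,
) -> TwoChannelMovie:
    h, w = config.image_size
    t_frames = config.frames
    sig_n = _blob_sigma(config.nucleus_radius_px)
    trunc_n = TRUNCATION_RADII * config.nucleus_radius_px
    green_radius = GREEN_FOOTPRINT_FACTOR * config.nucleus_radius_px
    sig_g = _blob_sigma(green_radius)
    trunc_g = TRUNCATION_RADII * green_radius

    bleach_r = _bleach_factors(config, config.bleach_tau_red_s)
    bleach_g = _bleach_factors(config, config.bleach_tau_green_s)

    # per cell-frame relative amplitude (0 outside events)
    rel_amp = np.zeros((truth.n_cells, t_frames))
    for ev in truth.events:
        rel_amp[ev.cell_id - 1, ev.start_frame : ev.end_frame + 1] = ev.amplitude

    red = np.empty((t_frames, h, w), dtype=np.float64)
    green = np.empty((t_frames, h, w), dtype=np.float64)
    for t in range(t_frames):
        fr = np.zeros((h, w))
        fg = np.zeros((h, w))
        for i in range(truth.n_cells):
            center = tuple(truth.positions[i, t])
            _render_blob(fr, center, sig_n, trunc_n, truth.red_expression[i])
            if green_expressing:
                _render_blob(
                    fg, center, sig_g, trunc_g, truth.expression[i] * (1.0 + rel_amp[i, t])
                )
        red[t] = (fr + config.background_level) * bleach_r[t]
        green[t] = (fg + config.background_level) * bleach_g[t]

    if config.noise_sd > 0:
        red += rng.normal(0.0, config.noise_sd, size=red.shape)
        green += rng.normal(0.0, config.noise_sd, size=green.shape)

    return TwoChannelMovie(_finalize(red), _finalize(green), config.frame_interval_s)


def _build_truth(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    centers0 = _place_cells(config, rng)
    positions = _random_walk(centers0, config, rng)
    expression = np.exp(rng.normal(config.expression_log_mean, config.expression_log_sd, config.n_cells))
    red_expression = np.exp(rng.normal(config.red_log_mean, config.red_log_sd, config.n_cells))
    events = _draw_events(config, rng)
    return GroundTruth(
        cell_ids=np.arange(1, config.n_cells + 1),
        positions=positions,
        expression=expression,
        red_expression=red_expression,
        events=events,
    )


def render_from_truth(
    config: SimConfig,
    truth: GroundTruth,
    green_expressing: bool = True,
    seed: int | None = None,
) -> TwoChannelMovie:
    """Render a movie from an explicit ground truth (e.g. hand-built events)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _render_movie(config, truth, rng, green_expressing)


def simulate_movie(config: SimConfig) -> tuple[TwoChannelMovie, GroundTruth]:
    """Simulate a two-channel recording plus its ground truth.

    In control mode (inert green fluorophore) the truth event list is empty;
    the green channel still carries per-cell expression, bleaching,
    background and noise. Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config, rng)
    movie = _render_movie(config, truth, rng, green_expressing=True)
    return movie, truth


def simulate_background_movie(config: SimConfig) -> TwoChannelMovie:
    """Simulate a recording whose green channel has no cellular expression.

    Emulates the background-estimation strain: nuclear marker only, so the
    green channel contains only background, bleaching and noise.
    """
    rng = np.random.default_rng(config.seed)
    truth = _build_truth(config.replace(control_mode=True), rng)
    return _render_movie(config, truth, rng, green_expressing=False)


# ---------------------------------------------------------------------------
# file output


def write_movie(movie: TwoChannelMovie, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write each channel as a multi-page 16-bit grayscale TIFF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, stack in (("red", movie.red), ("green", movie.green)):
        p = out / f"{prefix}{name}.tif"
        tifffile.imwrite(p, np.asarray(stack, dtype=np.uint16), photometric="minisblack")
        paths[name] = p
    return paths


def write_ground_truth(truth: GroundTruth, config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write truth tables (cells, events) as CSV and the config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n, t = truth.positions.shape[:2]
    cells = pd.DataFrame(
        {
            "id": np.repeat(truth.cell_ids, t),
            "frame": np.tile(np.arange(t), n),
            "row": truth.positions[:, :, 0].ravel(),
            "col": truth.positions[:, :, 1].ravel(),
            "expression": np.repeat(truth.expression, t),
        }
    )
    events = pd.DataFrame(
        [(e.cell_id, e.start_frame, e.end_frame, e.amplitude) for e in truth.events],
        columns=["cell_id", "start_frame", "end_frame", "amplitude"],
    )
    paths = {
        "cells": out / "truth_cells.csv",
        "events": out / "truth_events.csv",
        "config": out / "sim_config.json",
    }
    cells.to_csv(paths["cells"], index=False)
    events.to_csv(paths["events"], index=False)
    paths["config"].write_text(config.to_json())
    return paths


def read_ground_truth(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, SimConfig]:
    out = Path(out_dir)
    cells = pd.read_csv(out / "truth_cells.csv")
    events = pd.read_csv(out / "truth_events.csv")
    config = SimConfig.from_json((out / "sim_config.json").read_text())
    return cells, events, config
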