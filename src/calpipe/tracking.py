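"""Nucleus detection and tracking on the block-averaged red channel.

Nuclei are detected per averaged frame as local maxima of the
scale-normalized Laplacian-of-Gaussian response at a single fixed scale
(sigma = radius / sqrt(2)), localized to sub-pixel precision by quadratic
interpolation. Detections are linked between consecutive averaged frames by
greedy intersection-over-union matching of their circular footprints (the
"overlap tracker"). Only cells trackable through every averaged frame are
kept, and the result is exported as a sequence of integer label masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Detection",
    "Track",
    "detect_nuclei",
    "disk_iou",
    "link_overlap",
    "filter_complete_tracks",
    "render_label_masks",
    "track_stack",
    "write_masks",
    "tracks_to_frame",
]


@dataclass(frozen=True)
class Detection:
    """One nucleus detection in one averaged frame."""

    block_index: int
    row: float
    col: float
    radius: float
    quality: float

    @property
    def center(self) -> tuple[float, float]:
        return self.row, self.col


@dataclass
class Track:
    """A chain of detections over consecutive averaged frames."""

    id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def first_block(self) -> int:
        return self.detections[0].block_index

    @property
    def last_block(self) -> int:
        return self.detections[-1].block_index

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def is_complete(self, n_blocks: int) -> bool:
        return self.first_block == 0 and len(self.detections) == n_blocks

    def append(self, det: Detection) -> None:
        if self.detections and det.block_index != self.last_block + 1:
            raise ValueError("track detections must cover consecutive blocks")
        self.detections.append(det)


def _log_response(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negative LoG: bright blobs give positive peaks."""
    return -(sigma**2) * ndimage.gaussian_laplace(np.asarray(frame, dtype=np.float64), sigma)


def _subpixel_offset(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """1-D quadratic interpolation of the response peak along each axis."""
    out = []
    for axis, k in ((0, r), (1, c)):
        if k <= 0 or k >= resp.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            ym, y0, yp = resp[k - 1, c], resp[k, c], resp[k + 1, c]
        else:
            ym, y0, yp = resp[r, k - 1], resp[r, k], resp[r, k + 1]
        denom = ym - 2 * y0 + yp
        out.append(0.0 if denom >= 0 else float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5)))
    return out[0], out[1]


def detect_nuclei(
    frame: np.ndarray, radius_px: float, quality_threshold: float
) -> list[Detection]:
    """Detect blob-like nuclei in a single frame.

    Local maxima of the scale-normalized LoG response above
    ``quality_threshold`` are returned; pairs of maxima closer than
    ``radius_px`` are deduplicated keeping the higher quality (ties: smaller
    row, then smaller col). Blank frames yield an empty list.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    sigma = radius_px / math.sqrt(2.0)
    resp = _log_response(frame, sigma)
    # strict local maxima in the 3x3 neighborhood (plateaus keep first pixel)
    footprint = np.ones((3, 3), dtype=bool)
    maxima = (resp == ndimage.maximum_filter(resp, footprint=footprint, mode="nearest")) & (
        resp > quality_threshold
    )
    rows, cols = np.nonzero(maxima)
    cands = sorted(
        ((float(resp[r, c]), int(r), int(c)) for r, c in zip(rows, cols)),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    kept: list[tuple[float, int, int]] = []
    for q, r, c in cands:
        if all((r - rk) ** 2 + (c - ck) ** 2 >= radius_px**2 for _, rk, ck in kept):
            kept.append((q, r, c))
    detections = []
    for q, r, c in kept:
        dr, dc = _subpixel_offset(resp, r, c)
        detections.append(Detection(0, r + dr, c + dc, radius_px, q))
    detections.sort(key=lambda d: (d.row, d.col))
    return detections


def disk_iou(c1: tuple[float, float], r1: float, c2: tuple[float, float], r2: float) -> float:
    """Intersection-over-union of two disks (analytic lens area)."""
    d = math.hypot(c1[0] - c2[0], c1[1] - c2[1])
    if d >= r1 + r2:
        return 0.0
    a1, a2 = math.pi * r1 * r1, math.pi * r2 * r2
    if d <= abs(r1 - r2):
        inter = min(a1, a2)
    else:
        alpha1 = math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
        alpha2 = math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
        inter = (
            r1 * r1 * (alpha1 - math.sin(2 * alpha1) / 2)
            + r2 * r2 * (alpha2 - math.sin(2 * alpha2) / 2)
        )
    return inter / (a1 + a2 - inter)


def link_overlap(
    tracks: list[Track], detections_next: list[Detection], min_iou: float = 0.1
) -> list[Track]:
    """Extend tracks into the next averaged frame by greedy IoU matching.

    Pairs are matched in order of decreasing disk IoU (ties: lower track id,
    then detection order); pairs below ``min_iou`` never match. Unmatched
    detections open new tracks; unmatched tracks simply end.
    """
    if not detections_next:
        return tracks
    next_block = detections_next[0].block_index
    active = [tr for tr in tracks if tr.last_block == next_block - 1]
    pairs = []
    for tr in active:
        last = tr.last
        for j, det in enumerate(detections_next):
            iou = disk_iou(last.center, last.radius, det.center, det.radius)
            if iou >= min_iou and iou > 0:
                pairs.append((iou, tr.id, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    matched_tracks: set[int] = set()
    matched_dets: set[int] = set()
    by_id = {tr.id: tr for tr in active}
    for iou, tid, j in pairs:
        if tid in matched_tracks or j in matched_dets:
            continue
        by_id[tid].append(detections_next[j])
        matched_tracks.add(tid)
        matched_dets.add(j)
    next_id = max((tr.id for tr in tracks), default=0) + 1
    out = list(tracks)
    for j, det in enumerate(detections_next):
        if j not in matched_dets:
            out.append(Track(next_id, [det]))
            next_id += 1
    return out


def filter_complete_tracks(tracks: list[Track], n_blocks: int) -> list[Track]:
    """Keep only cells trackable through the entire movie."""
    return [tr for tr in tracks if tr.is_complete(n_blocks)]


def render_label_masks(
    tracks: list[Track], image_size: tuple[int, int], n_blocks: int | None = None
) -> np.ndarray:
    """Render per-block integer label masks (0 = background).

    Each detection paints a filled disk of its radius valued at its track
    id; contested pixels go to the nearer center (ties: lower id).
    """
    h, w = image_size
    if n_blocks is None:
        n_blocks = max((tr.last_block for tr in tracks), default=-1) + 1
    masks = np.zeros((n_blocks, h, w), dtype=np.uint16)
    # distance of the current owner, for nearest-center tie-breaking
    best_d2 = np.full((n_blocks, h, w), np.inf)
    for tr in sorted(tracks, key=lambda t: t.id):
        for det in tr.detections:
            b = det.block_index
            r0 = max(int(math.floor(det.row - det.radius)), 0)
            r1 = min(int(math.ceil(det.row + det.radius)) + 1, h)
            c0 = max(int(math.floor(det.col - det.radius)), 0)
            c1 = min(int(math.ceil(det.col + det.radius)) + 1, w)
            rr = np.arange(r0, r1)[:, None] - det.row
            cc = np.arange(c0, c1)[None, :] - det.col
            d2 = rr * rr + cc * cc
            inside = d2 <= det.radius**2
            closer = d2 < best_d2[b, r0:r1, c0:c1]
            take = inside & closer
            masks[b, r0:r1, c0:c1][take] = tr.id
            best_d2[b, r0:r1, c0:c1][take] = d2[take]
    return masks


def track_stack(
    averaged: np.ndarray,
    radius_px: float = 4.0,
    quality_threshold: float = 20.0,
    min_iou: float = 0.1,
) -> list[Track]:
    """Detect and link nuclei across every frame of an averaged stack."""
    tracks: list[Track] = []
    for b in range(averaged.shape[0]):
        dets = [
            Detection(b, d.row, d.col, d.radius, d.quality)
            for d in detect_nuclei(averaged[b], radius_px, quality_threshold)
        ]
        if b == 0:
            tracks = [Track(i + 1, [d]) for i, d in enumerate(dets)]
        else:
            tracks = link_overlap(tracks, dets, min_iou)
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (tr.id, d.block_index, d.row, d.col, d.radius, d.quality)
        for tr in tracks
        for d in tr.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "block", "row", "col", "radius", "quality"])


def write_masks(masks: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(masks, dtype=np.uint16), photometric="minisblack")
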