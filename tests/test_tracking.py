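"""LoG detection, IoU overlap linking, complete-track filtering, label masks."""

import math

import numpy as np
import pytest

from calpipe.simulator import SimConfig, simulate_movie
from calpipe.preprocess import block_average
from calpipe.tracking import (
    Detection,
    Track,
    detect_nuclei,
    disk_iou,
    filter_complete_tracks,
    link_overlap,
    render_label_masks,
    track_stack,
)


def gaussian_blob(shape, center, sigma, amplitude=100.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return amplitude * np.exp(-d2 / (2 * sigma**2))


def test_single_blob_detected_within_one_pixel():
    sigma = 4.0
    frame = gaussian_blob((100, 100), (50.0, 50.0), sigma)
    dets = detect_nuclei(frame, radius_px=sigma * math.sqrt(2), quality_threshold=5.0)
    assert len(dets) == 1
    assert abs(dets[0].row - 50.0) < 1.0 and abs(dets[0].col - 50.0) < 1.0


def test_blank_frame_gives_empty_list():
    assert detect_nuclei(np.zeros((50, 50)), 4.0, 1.0) == []


@pytest.mark.parametrize("separation_sigmas", [6.0, 8.0, 10.0])
def test_two_well_separated_blobs_both_localized(separation_sigmas):
    sigma = 3.0
    c1 = (40.0, 30.0)
    c2 = (40.0, 30.0 + separation_sigmas * sigma)
    frame = gaussian_blob((90, 110), c1, sigma) + gaussian_blob((90, 110), c2, sigma)
    dets = detect_nuclei(frame, radius_px=sigma * math.sqrt(2), quality_threshold=5.0)
    assert len(dets) == 2
    centers = sorted((d.row, d.col) for d in dets)
    for found, true in zip(centers, sorted([c1, c2])):
        assert abs(found[0] - true[0]) < 1.0
        assert abs(found[1] - true[1]) < 1.0


def test_subpixel_localization_of_offset_blob():
    frame = gaussian_blob((80, 80), (40.3, 39.6), 4.0)
    dets = detect_nuclei(frame, radius_px=4 * math.sqrt(2), quality_threshold=5.0)
    assert len(dets) == 1
    assert abs(dets[0].row - 40.3) < 0.5
    assert abs(dets[0].col - 39.6) < 0.5


def monte_carlo_iou(c1, r1, c2, r2, n=200_000, seed=0):
    """Independent oracle: IoU by uniform point sampling over the bounding box."""
    rng = np.random.default_rng(seed)
    lo = np.minimum(np.array(c1) - r1, np.array(c2) - r2)
    hi = np.maximum(np.array(c1) + r1, np.array(c2) + r2)
    pts = rng.uniform(lo, hi, size=(n, 2))
    in1 = ((pts - c1) ** 2).sum(axis=1) <= r1**2
    in2 = ((pts - c2) ** 2).sum(axis=1) <= r2**2
    inter = np.mean(in1 & in2)
    union = np.mean(in1 | in2)
    return inter / union


@pytest.mark.parametrize(
    "c2,r2",
    [((0.0, 2.0), 4.0), ((0.0, 0.5), 4.0), ((3.0, 3.0), 2.0), ((0.0, 0.0), 4.0)],
)
def test_disk_iou_matches_monte_carlo(c2, r2):
    analytic = disk_iou((0.0, 0.0), 4.0, c2, r2)
    mc = monte_carlo_iou((0.0, 0.0), 4.0, c2, r2)
    assert abs(analytic - mc) < 0.01


def test_disk_iou_extremes():
    assert disk_iou((0, 0), 3.0, (0, 0), 3.0) == pytest.approx(1.0)
    assert disk_iou((0, 0), 3.0, (0, 6.5), 3.0) == 0.0


def test_identical_detection_links_with_full_overlap():
    t = Track(1, [Detection(0, 10.0, 10.0, 4.0, 5.0)])
    out = link_overlap([t], [Detection(1, 10.0, 10.0, 4.0, 5.0)], min_iou=0.1)
    assert len(out) == 1 and len(out[0].detections) == 2


def test_disjoint_detection_opens_new_track():
    t = Track(1, [Detection(0, 10.0, 10.0, 4.0, 5.0)])
    out = link_overlap([t], [Detection(1, 10.0, 30.0, 4.0, 5.0)], min_iou=0.1)
    assert len(out) == 2
    assert len(out[0].detections) == 1
    assert out[1].id == 2


def test_link_threshold_uses_analytic_lens_iou():
    r = 4.0
    iou_at_half_r = disk_iou((0.0, 0.0), r, (0.0, 0.5 * r), r)
    t = Track(1, [Detection(0, 10.0, 10.0, r, 5.0)])
    nxt = [Detection(1, 10.0, 10.0 + 0.5 * r, r, 5.0)]
    linked = link_overlap([t], nxt, min_iou=iou_at_half_r - 1e-6)
    assert len(linked[0].detections) == 2
    t2 = Track(1, [Detection(0, 10.0, 10.0, r, 5.0)])
    not_linked = link_overlap([t2], nxt, min_iou=iou_at_half_r + 1e-6)
    assert len(not_linked[0].detections) == 1
    assert len(not_linked) == 2


def test_greedy_matching_prefers_higher_overlap_with_deterministic_ties():
    # two tracks compete for one detection: the closer one wins
    t1 = Track(1, [Detection(0, 10.0, 10.0, 4.0, 5.0)])
    t2 = Track(2, [Detection(0, 10.0, 13.0, 4.0, 5.0)])
    det = Detection(1, 10.0, 11.0, 4.0, 5.0)
    out = link_overlap([t1, t2], [det], min_iou=0.05)
    assert len(out[0].detections) == 2  # track 1 is nearer
    assert len(out[1].detections) == 1


def test_filter_complete_tracks():
    full = Track(1, [Detection(b, 5.0, 5.0, 4.0, 1.0) for b in range(36)])
    late = Track(2, [Detection(b, 9.0, 9.0, 4.0, 1.0) for b in range(1, 36)])
    kept = filter_complete_tracks([full, late], 36)
    assert kept == [full]


def test_drift_free_movie_tracks_all_cells_with_subpixel_accuracy():
    cfg = SimConfig(n_cells=20, frames=60, seed=10, drift_step_px=0.0, noise_sd=0.5)
    movie, truth = simulate_movie(cfg)
    avg = block_average(movie.red.astype(float), 5)
    tracks = track_stack(avg, cfg.nucleus_radius_px, 20.0, 0.1)
    complete = filter_complete_tracks(tracks, avg.shape[0])
    assert len(complete) == cfg.n_cells
    true_centers = truth.positions[:, 0, :]
    for tr in complete:
        pos = np.array([[d.row, d.col] for d in tr.detections])
        err = np.hypot(*(true_centers - pos.mean(axis=0)).T).min()
        assert err < 1.0


def test_label_masks_fixed_center_disk():
    tr = Track(1, [Detection(b, 20.0, 20.0, 4.0, 1.0) for b in range(3)])
    masks = render_label_masks([tr], (40, 40), 3)
    assert masks.shape == (3, 40, 40)
    assert np.array_equal(masks[0], masks[1])
    area = (masks[0] == 1).sum()
    assert abs(area - math.pi * 16) < 10  # pi r^2 within discretization


def test_adjacent_masks_partition_deterministically():
    t1 = Track(1, [Detection(0, 20.0, 20.0, 4.0, 1.0)])
    t2 = Track(2, [Detection(0, 20.0, 26.0, 4.0, 1.0)])
    m1 = render_label_masks([t1, t2], (40, 40), 1)
    m2 = render_label_masks([t2, t1], (40, 40), 1)
    assert np.array_equal(m1, m2)
    # no pixel owned by both, contested pixels go to the nearer center
    assert set(np.unique(m1)) == {0, 1, 2}
    rows, cols = np.nonzero(m1[0])
    labels = m1[0][rows, cols]
    d1 = np.hypot(rows - 20.0, cols - 20.0)
    d2 = np.hypot(rows - 20.0, cols - 26.0)
    assert np.all((labels == 1) == (d1 <= d2) | (d1 <= 4.0) & (d2 > 4.0))


def test_masks_recover_simulated_nucleus_pixels():
    cfg = SimConfig(n_cells=10, frames=20, seed=11, drift_step_px=0.0, noise_sd=0.5)
    movie, truth = simulate_movie(cfg)
    avg = block_average(movie.red.astype(float), 5)
    tracks = filter_complete_tracks(
        track_stack(avg, cfg.nucleus_radius_px, 20.0, 0.1), avg.shape[0]
    )
    masks = render_label_masks(tracks, cfg.image_size, avg.shape[0])
    r = cfg.nucleus_radius_px
    rr, cc = np.mgrid[: cfg.image_size[0], : cfg.image_size[1]]
    for i in range(cfg.n_cells):
        cr, ccol = truth.positions[i, 0]
        nucleus = (rr - cr) ** 2 + (cc - ccol) ** 2 <= r**2
        covered = (masks[0] > 0) & nucleus
        assert covered.sum() / nucleus.sum() >= 0.95


def test_track_ids_unique_and_detections_unshared():
    cfg = SimConfig(n_cells=8, frames=30, seed=12)
    movie, _ = simulate_movie(cfg)
    avg = block_average(movie.red.astype(float), 5)
    tracks = track_stack(avg, cfg.nucleus_radius_px, 20.0, 0.1)
    ids = [tr.id for tr in tracks]
    assert len(ids) == len(set(ids))
    seen = set()
    for tr in tracks:
        for d in tr.detections:
            key = (d.block_index, round(d.row, 6), round(d.col, 6))
            assert key not in seen
            seen.add(key)
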