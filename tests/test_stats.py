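"""Basal-intensity variability, duration fractions, FDR, event matching."""

import numpy as np
import pytest

from calpipe.events import SignalEvent
from calpipe.simulator import SimConfig, TrueEvent, simulate_movie
from calpipe.stats import (
    FdrInputs,
    UndefinedStatisticError,
    basal_intensity,
    duration_fractions,
    estimate_fdr,
    log_sd,
    match_events,
    percent_difference,
)
from calpipe.traces import CellTrace


def ev(cid, s, e, dt=5.0):
    return SignalEvent(cid, s, e, (e - s + 1) * dt, 1.0)


# --- basal intensity ---------------------------------------------------------


def test_basal_excludes_event_frames():
    tr = CellTrace(1, np.array([100.0, 100.0, 150.0, 100.0]), 5.0, True)
    ind = np.array([False, False, True, False])
    assert basal_intensity(tr, ind) == pytest.approx(100.0)


def test_basal_without_events_is_plain_mean():
    tr = CellTrace(1, np.array([1.0, 2.0, 3.0]), 5.0, True)
    assert basal_intensity(tr, np.zeros(3, bool)) == pytest.approx(2.0)


def test_basal_undefined_when_every_frame_in_event():
    tr = CellTrace(1, np.ones(3), 5.0, True)
    with pytest.raises(UndefinedStatisticError):
        basal_intensity(tr, np.ones(3, bool))


# --- log-scale variability ---------------------------------------------------


def test_log_sd_zero_for_equal_values():
    assert log_sd(np.full(10, 7.0)) == pytest.approx(0.0, abs=1e-12)


def test_log_sd_scale_invariant():
    vals = 3.0 * 1.5 ** np.arange(8)
    assert log_sd(vals) == pytest.approx(log_sd(100.0 * vals))
    # geometric sequence a*k^i: sd of logs = log(k)*sd(i)
    assert log_sd(vals) == pytest.approx(np.log(1.5) * np.std(np.arange(8), ddof=1))


def test_log_sd_rejects_non_positive():
    with pytest.raises(UndefinedStatisticError):
        log_sd(np.array([1.0, 0.0, 2.0]))


def test_simulated_expression_heterogeneity_recovered():
    cfg = SimConfig(n_cells=260, frames=4, seed=17, image_size=(512, 512),
                    control_mode=True)
    _, truth = simulate_movie(cfg)
    sd = log_sd(truth.expression)
    assert abs(sd - 1.7) / 1.7 < 0.10


# --- percent difference ------------------------------------------------------


def test_percent_difference_of_reported_sigmas_is_six_percent():
    assert percent_difference(1.792, 1.688) == 6


def test_percent_difference_edge_cases():
    assert percent_difference(2.0, 2.0) == 0
    assert percent_difference(4.0, 2.0) == 100
    with pytest.raises(UndefinedStatisticError):
        percent_difference(1.0, 0.0)


# --- duration fractions ------------------------------------------------------


def test_duration_fractions_direct_count():
    events = [ev(1, 0, 0), ev(1, 5, 5), ev(2, 0, 1), ev(2, 10, 13),
              ev(3, 0, 4), ev(3, 20, 31)]
    # durations: 5,5,10,20,25,60
    out = duration_fractions(events, [20.0, 60.0])
    assert out["fractions"][20.0] == pytest.approx(0.5)
    assert out["fractions"][60.0] == pytest.approx(1 / 6)
    assert out["single_frame_fraction"] == pytest.approx(2 / 6)


def test_all_single_frame():
    events = [ev(1, i * 3, i * 3) for i in range(5)]
    out = duration_fractions(events, [20.0])
    assert out["single_frame_fraction"] == 1.0
    assert out["fractions"][20.0] == 0.0


def test_fractions_non_increasing_in_threshold():
    rng = np.random.default_rng(1)
    events = [ev(1, s, s + int(d)) for s, d in
              zip(range(0, 900, 30), rng.geometric(0.3, 30))]
    out = duration_fractions(events, [5.0, 10.0, 20.0, 40.0, 80.0])
    fr = [out["fractions"][t] for t in [5.0, 10.0, 20.0, 40.0, 80.0]]
    assert all(a >= b for a, b in zip(fr, fr[1:]))


def test_empty_events_undefined():
    with pytest.raises(UndefinedStatisticError):
        duration_fractions([], [20.0])


# --- FDR ---------------------------------------------------------------------


def test_fdr_on_published_counts_is_under_5_percent():
    out = estimate_fdr(FdrInputs(40, 250, 812, 245))
    assert out["fdr"] == pytest.approx(0.0483, abs=0.0005)
    assert out["fdr"] < 0.05
    assert out["raw_event_ratio"] == pytest.approx(40 / 812)
    assert out["raw_event_ratio"] < 0.05


def test_fdr_zero_without_control_events():
    assert estimate_fdr(FdrInputs(0, 250, 100, 250))["fdr"] == 0.0


def test_fdr_invariant_under_common_rescaling():
    a = estimate_fdr(FdrInputs(40, 250, 812, 245))["fdr"]
    b = estimate_fdr(FdrInputs(80, 250, 1624, 245))["fdr"]
    c = estimate_fdr(FdrInputs(40, 500, 812, 490))["fdr"]
    assert a == pytest.approx(b)
    assert a == pytest.approx(c)


def test_fdr_undefined_without_signal_events():
    with pytest.raises(UndefinedStatisticError):
        estimate_fdr(FdrInputs(5, 250, 0, 245))


# --- event matching ----------------------------------------------------------


def test_identical_lists_match_perfectly():
    evs = [ev(1, 0, 3), ev(2, 5, 5)]
    truth = [TrueEvent(1, 0, 3, 1.0), TrueEvent(2, 5, 5, 1.0)]
    m = match_events(evs, truth)
    assert m.precision == 1.0 and m.recall == 1.0


def test_empty_detected_conventions():
    truth = [TrueEvent(1, 0, 3, 1.0)]
    m = match_events([], truth)
    assert m.recall == 0.0
    assert m.precision == 1.0
    assert not m.precision_defined


def test_shifted_events_still_overlap_and_match():
    # exhaustive small-case oracle: all 1-frame shifts of a 3-frame event
    truth = [TrueEvent(1, 5, 7, 1.0)]
    for shift in range(-3, 4):
        det = [ev(1, 5 + shift, 7 + shift)]
        m = match_events(det, truth)
        overlaps = max(0, min(7, 7 + shift) - max(5, 5 + shift) + 1) > 0
        assert (m.n_true_positive == 1) == overlaps


def test_cross_cell_events_never_match():
    m = match_events([ev(1, 0, 3)], [TrueEvent(2, 0, 3, 1.0)])
    assert m.n_true_positive == 0


def test_one_to_one_matching_is_greedy_by_overlap():
    # one detection spans two truth events: only one may be matched
    det = [ev(1, 0, 10)]
    truth = [TrueEvent(1, 0, 2, 1.0), TrueEvent(1, 6, 10, 1.0)]
    m = match_events(det, truth)
    assert m.n_true_positive == 1
    assert m.recall == 0.5
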