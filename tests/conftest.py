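import numpy as np
import pytest

from calpipe.simulator import (
    GroundTruth,
    SimConfig,
    TrueEvent,
    render_from_truth,
    simulate_movie,
)


def make_truth(
    centers,
    frames: int,
    expression,
    events=(),
    red_expression=None,
):
    """Hand-built ground truth with stationary cells."""
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    positions = np.repeat(centers[:, None, :], frames, axis=1)
    expression = np.asarray(expression, dtype=float)
    if red_expression is None:
        red_expression = np.full(n, 400.0)
    return GroundTruth(
        cell_ids=np.arange(1, n + 1),
        positions=positions,
        expression=expression,
        red_expression=np.asarray(red_expression, dtype=float),
        events=list(events),
    )


@pytest.fixture
def clean_config():
    """Noiseless, drift-free, bleach-free single-cell configuration."""
    return SimConfig(
        n_cells=1,
        frames=40,
        image_size=(64, 64),
        noise_sd=0.0,
        drift_step_px=0.0,
        bleach_tau_red_s=float("inf"),
        bleach_tau_green_s=float("inf"),
        background_level=0.0,
        seed=0,
    )


@pytest.fixture
def boxcar_movie(clean_config):
    """One stationary cell with a single boxcar event on frames 10-13."""
    truth = make_truth(
        [(32.0, 32.0)], clean_config.frames, expression=[1000.0],
        events=[TrueEvent(1, 10, 13, clean_config.event_rel_amplitude)],
    )
    movie = render_from_truth(clean_config, truth)
    return movie, truth, clean_config


@pytest.fixture(scope="session")
def small_signal_run():
    """A seeded 12-cell signal-mode movie with its ground truth."""
    cfg = SimConfig(n_cells=12, seed=42)
    movie, truth = simulate_movie(cfg)
    return cfg, movie, truth
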