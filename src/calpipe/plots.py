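"""Summary figures: basal-intensity distributions and event-duration
histograms.

Both are renderings of quantities computed by :mod:`calpipe.stats`; extreme
duration outliers (> 125 s by default) are excluded from the histogram
drawing only, never from the statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .events import SignalEvent

__all__ = ["plot_basal_distributions", "plot_duration_histogram"]


def plot_basal_distributions(
    samples: dict[str, np.ndarray], path: str | Path
) -> Path:
    """Log-scale strip/box plot of per-cell basal intensities per sample."""
    fig, ax = plt.subplots(figsize=(1.8 * max(len(samples), 2), 4))
    names = list(samples)
    rng = np.random.default_rng(0)
    for i, name in enumerate(names):
        vals = np.asarray(samples[name], dtype=float)
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.plot(x, vals, ".", alpha=0.4, markersize=3)
        ax.boxplot(
            vals, positions=[i], widths=0.45, showfliers=False,
            medianprops={"color": "red"},
        )
    ax.set_yscale("log")
    ax.set_xticks(range(len(names)))
    sigmas = [np.std(np.log(np.asarray(samples[n], float)), ddof=1) for n in names]
    ax.set_xticklabels([f"{n}\nσ = {s:.3f}" for n, s in zip(names, sigmas)])
    ax.set_ylabel("basal fluorescence (a.u., log scale)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_duration_histogram(
    events_by_sample: dict[str, list[SignalEvent]],
    path: str | Path,
    frame_interval_s: float = 5.0,
    max_plot_s: float = 125.0,
) -> Path:
    """Histogram of event durations; outliers beyond max_plot_s not drawn."""
    fig, ax = plt.subplots(figsize=(6, 4))
    edges = np.arange(
        frame_interval_s / 2, max_plot_s + frame_interval_s, frame_interval_s
    )
    for name, events in events_by_sample.items():
        durations = np.array([e.duration_s for e in events])
        durations = durations[durations <= max_plot_s]
        ax.hist(durations, bins=edges, alpha=0.5, label=name)
    ax.set_xlabel("signal duration (s)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
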