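"""Figures: spectrograms, reaction-time histograms, performance curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .analysis import DetectionResults
from .session import SessionData
from .stimgen import Stimulus

__all__ = [
    "plot_spectrogram",
    "plot_rt_histogram",
    "plot_performance_curves",
    "save_standard_figures",
]


def plot_spectrogram(stim: Stimulus, ax=None, nperseg: int = 1024, noverlap: int = 768):
    """Spectrogram of a rendered stimulus (visual check of the figure window)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.specgram(stim.samples, NFFT=nperseg, noverlap=noverlap, Fs=stim.sample_rate,
                cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_ylim(0, 8000)
    title = stim.spec.condition
    if stim.spec.condition == "figure":
        title += f", coherence {stim.spec.coherence}"
    ax.set_title(title)
    return ax


def plot_rt_histogram(sessions: list[SessionData], bin_width: float = 0.04, ax=None):
    """Histogram of hit reaction times (from figure onset), all coherences pooled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rts = [
        t.response_time - t.figure_onset
        for s in sessions
        for t in s.trials
        if t.outcome == "hit" and not t.excluded and t.response_time is not None
    ]
    if rts:
        bins = np.arange(0.0, max(rts) + bin_width, bin_width)
        ax.hist(rts, bins=bins, color="steelblue", edgecolor="white")
    ax.set_xlabel("reaction time (s)")
    ax.set_ylabel("hit count")
    return ax


def plot_performance_curves(results: DetectionResults, axes=None):
    """Hit rate/FA, d', mean RT and RT variability vs coherence with CIs."""
    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(9, 7))
    axes = np.asarray(axes).ravel()
    names = ["hit_rate", "d_prime", "mean_rt", "rt_variability"]
    labels = ["hit rate", "d-prime", "mean RT (s)", "RT variability (s)"]
    for ax, name, label in zip(axes, names, labels):
        tab = results.by_coherence(name)
        x = tab["coherence"].to_numpy(float)
        y = tab["mean"].to_numpy(float)
        ax.fill_between(x, tab["ci_low"], tab["ci_high"], alpha=0.3)
        ax.plot(x, y, "o", color="k")
        if name in results.poly_fits:
            xs = np.linspace(x.min(), x.max(), 100)
            ax.plot(xs, np.polyval(results.poly_fits[name], xs), "-", color="k")
        if name == "hit_rate":
            ax.axhline(results.fa_rate, ls="--", color="gray", label="FA rate")
            ax.legend(frameon=False)
        ax.set_xlabel("coherence (elements)")
        ax.set_ylabel(label)
        ax.set_xticks(x)
    plt.tight_layout()
    return axes


def save_standard_figures(results: DetectionResults, sessions, out_dir,
                          rt_bin_width: float = 0.04) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    ax = plot_rt_histogram(sessions, bin_width=rt_bin_width)
    p = out_dir / "rt_histogram.png"
    ax.figure.savefig(p, dpi=100)
    plt.close(ax.figure)
    paths.append(p)
    axes = plot_performance_curves(results)
    p = out_dir / "performance_curves.png"
    axes[0].figure.savefig(p, dpi=100)
    plt.close(axes[0].figure)
    paths.append(p)
    return paths
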