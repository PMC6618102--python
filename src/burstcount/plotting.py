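"""Small plotting helpers for the three stage outputs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_spectrum_overlay(result, ax=None):
    """Group-mean normalized amplitude and accuracy against frequency."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    freqs = result.spectral.columns.to_numpy(dtype=float)
    for df, label, color in ((result.spectral_norm, "amplitude", "tab:blue"),
                             (result.behavioural_norm, "performance", "tab:orange")):
        m = df.mean(axis=0).to_numpy()
        sd = df.std(axis=0).to_numpy()
        ax.plot(freqs, m, "-o", ms=3, color=color, label=label)
        ax.fill_between(freqs, m - sd, m + sd, alpha=0.2, color=color)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("normalized value")
    ax.legend(frameon=False)
    return ax


def plot_entrainment(result, ax=None):
    """Matched vs unmatched induced amplitude, mean bar + participant dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.5))
    m = result.table.xs("matched", level="condition").mean(axis=1)
    u = result.table.xs("unmatched", level="condition").mean(axis=1)
    ax.bar([0, 1], [m.mean(), u.mean()], color=["tab:green", "tab:gray"], width=0.6)
    for mv, uv in zip(m, u):
        ax.plot([0, 1], [mv, uv], "k-", alpha=0.25, lw=0.7)
    ax.set_xticks([0, 1], ["matched", "unmatched"])
    ax.set_ylabel("induced amplitude")
    return ax


def plot_cluster_map(cluster_result, frequencies, times, ax=None, alpha=0.05):
    """Statistic map with significant cluster outlines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    extent = [times[0], times[-1], frequencies[0], frequencies[-1]]
    ax.imshow(cluster_result.stat_map, origin="lower", aspect="auto",
              extent=extent, cmap="RdBu_r")
    sig = np.zeros_like(cluster_result.stat_map, dtype=bool)
    for c in cluster_result.significant(alpha):
        for fi, ti in c.bins:
            sig[fi, ti] = True
    if sig.any():
        ax.contour(times, frequencies, sig.astype(float), levels=[0.5],
                   colors="yellow", linewidths=1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    return ax
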