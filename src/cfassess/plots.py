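"""Figures: TFR contrast maps with significant-cluster outlines, Welch
spectra, and accuracy time-courses with significance stars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_tfr_contrast", "plot_welch", "plot_accuracy"]


def plot_tfr_contrast(log_ratio, cluster_result, path) -> Path:
    """Per-channel log power-ratio maps with significant clusters outlined."""
    path = Path(path)
    ch_names = list(cluster_result.channels)
    freqs, times = cluster_result.freqs, cluster_result.times
    fig, axes = plt.subplots(
        1, len(ch_names), figsize=(5 * len(ch_names), 4), squeeze=False
    )
    vmax = np.abs(log_ratio).max() or 1.0
    for ax, ch, data in zip(axes[0], ch_names, log_ratio):
        mesh = ax.pcolormesh(
            times, freqs, data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="nearest"
        )
        mask = np.zeros(data.shape, dtype=float)
        for cl in cluster_result.channels[ch].significant(cluster_result.cluster_alpha):
            mask[cl.cells[:, 0], cl.cells[:, 1]] = 1.0
        if mask.any():
            ax.contour(times, freqs, mask, levels=[0.5], colors="k", linewidths=1.5)
        ax.axvline(0.0, color="k", ls="--", lw=0.8)
        ax.set_title(ch)
        ax.set_xlabel("Time from instruction offset (s)")
        ax.set_ylabel("Frequency (Hz)")
        fig.colorbar(mesh, ax=ax, label="log power ratio vs rest")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_welch(welch: dict, path) -> Path:
    """Condition-wise average spectra (dB), one panel per channel."""
    path = Path(path)
    conditions = list(welch)
    ch_names = list(next(iter(welch.values()))["power_db"])
    fig, axes = plt.subplots(
        1, len(ch_names), figsize=(5 * len(ch_names), 4), squeeze=False, sharey=True
    )
    for ax, ch in zip(axes[0], ch_names):
        for cond in conditions:
            spec = welch[cond]
            ax.plot(spec["freqs_hz"], spec["power_db"][ch], label=cond)
        ax.set_title(ch)
        ax.set_xlabel("Frequency (Hz)")
        ax.set_xlim(0, 45)
    axes[0][0].set_ylabel("Power (dB)")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_accuracy(perm_result, path) -> Path:
    """Smoothed accuracy time-course ±1 SE with significance stars."""
    path = Path(path)
    obs = perm_result.observed
    se = obs.fold_accuracies.std(axis=0, ddof=1) / np.sqrt(len(obs.fold_accuracies))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(obs.times, obs.smoothed, color="C0", label="smoothed accuracy")
    ax.fill_between(
        obs.times, obs.smoothed - se, obs.smoothed + se, alpha=0.3, color="C0"
    )
    ax.axhline(0.5, color="gray", ls=":", lw=0.8)
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    if perm_result.sig_mask.any():
        ax.plot(
            obs.times[perm_result.sig_mask],
            np.full(perm_result.sig_mask.sum(), obs.smoothed.max() + 0.03),
            "k*",
            label=f"p < {perm_result.alpha}",
        )
    ax.set_xlabel("Time from instruction offset (s)")
    ax.set_ylabel("Classification accuracy")
    ax.set_ylim(0.2, 1.0)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
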