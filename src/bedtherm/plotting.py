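"""Bland–Altman and change-curve figures."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def bland_altman_plot(s, y, stats, path) -> None:
    """Scatter of difference vs mean with bias and limits of agreement."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(s) & np.isfinite(y)
    mean = (s[ok] + y[ok]) / 2.0
    diff = s[ok] - y[ok]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=6, alpha=0.4)
    ax.axhline(stats.bias, color="k", lw=1)
    for loa in (stats.lower_loa, stats.upper_loa):
        ax.axhline(loa, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of reference and estimate (°C)")
    ax.set_ylabel("reference − estimate (°C)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def change_curve_plot(mean_estimated, mean_foot, pearson_r, path) -> None:
    """Grand-average change curves from lights-off for estimate and foot."""
    minutes = np.arange(len(mean_estimated))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(minutes, mean_estimated, label="estimated DST")
    ax.plot(minutes, mean_foot, label="foot (measured)")
    ax.set_xlabel("minutes from lights-off")
    ax.set_ylabel("temperature change (°C)")
    ax.set_title(f"Pearson r = {pearson_r:.2f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
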