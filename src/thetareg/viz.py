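"""Minimal plotting helpers: sensor topographies and TFR images."""

from __future__ import annotations

import numpy as np

from .cluster import _azimuthal_projection
from .timefreq import TFR

__all__ = ["plot_topography", "plot_tfr"]


def plot_topography(values, positions, labels=None, highlight=(), ax=None,
                    title=""):
    """Interpolated scalp map of per-channel values (2-D azimuthal view)."""
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    pts = _azimuthal_projection(np.asarray(positions, float))
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xi = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 120)
    yi = np.linspace(pts[:, 1].min(), pts[:, 1].max(), 120)
    grid = griddata(pts, np.asarray(values, float),
                    tuple(np.meshgrid(xi, yi)), method="cubic")
    im = ax.contourf(xi, yi, grid, levels=24, cmap="RdBu_r")
    ax.scatter(pts[:, 0], pts[:, 1], s=6, c="k")
    if labels:
        for i, lab in enumerate(labels):
            if lab in highlight:
                ax.plot(pts[i, 0], pts[i, 1], "x", ms=10, c="k")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(title)
    plt.colorbar(im, ax=ax, shrink=0.7)
    return ax


def plot_tfr(tfr: TFR, channel: str, ax=None, title=""):
    """Time-frequency image for one channel."""
    import matplotlib.pyplot as plt

    idx = tfr.channel_labels.index(channel)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    im = ax.pcolormesh(tfr.times, tfr.freqs, tfr.power[idx], cmap="RdBu_r",
                       shading="nearest")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title or channel)
    plt.colorbar(im, ax=ax)
    return ax
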