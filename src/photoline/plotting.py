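"""Plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_xcorr(xcorr, ax=None, **kwargs):
    """Line plot of a lagged cross-correlation."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.plot(xcorr.lags, xcorr.values, **kwargs)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("cross-correlation")
    return ax


def radial_angle_histogram(angles_deg, labels=None, n_bins: int = 24, ax=None):
    """Radial histogram of PC1/PC2 angles, optionally split by label."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles_deg = np.asarray(angles_deg, dtype=float)
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    width = edges[1] - edges[0]
    if labels is None:
        groups = {"all": angles_deg}
    else:
        labels = np.asarray(labels)
        groups = {str(l): angles_deg[labels == l] for l in np.unique(labels)}
    for name, vals in groups.items():
        counts, _ = np.histogram(np.radians(vals % 360.0), bins=edges)
        ax.bar(edges[:-1] + width / 2, counts, width=width, alpha=0.5,
               label=name)
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_triggered_average(ta, ax=None, **kwargs):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.plot(ta.lags, ta.mean_trace, **kwargs)
    ax.set_xlabel("time from event (s)")
    return ax
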